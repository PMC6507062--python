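"""Discretization methods for a continuous predictor in Cox models.

Four methods are provided:

* ``median`` — single cut at the sample median of x;
* ``q1q3`` — two cuts at the empirical quartiles, middle range as reference;
* ``minp`` — maximally selected log-rank statistic (single cut minimizing the
  naive log-rank p-value over an inner quantile window);
* ``oehr`` — the optimal equal-HR method: among pairs of cut-points with
  (approximately) equal fitted log relative hazard on the P-spline curve,
  pick the pair whose three-group categorical Cox refit minimizes AIC.

All empirical percentiles use the linear-interpolation (type-7) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import _cox
from .datasets import SurvivalDataset
from .spline import SplineCoxFit, diagnose_u_shape, predict_log_relative_hazard

EQUAL_HR_TOL = 0.01          # max |delta log lambda| for a candidate pair
DEFAULT_MIN_GROUP_FRAC = 0.05


@dataclass
class CutpointResult:
    """Cut-point(s) and the induced categorical Cox model summary.

    ``coefficients`` are log hazard ratios of the non-reference groups: for
    two cuts, (low vs middle, high vs middle); for one cut, (high vs low,).
    """

    method: str
    cut1: float
    cut2: float | None = None
    aic: float | None = None
    bic: float | None = None
    loglik: float | None = None
    coefficients: np.ndarray | None = None
    hrs: np.ndarray | None = None
    p_values: np.ndarray | None = None
    group_counts: np.ndarray | None = None
    statistic: float | None = None      # minP: maximal |standardized log-rank|
    naive_p: float | None = None        # minP: uncorrected minimum p-value
    notes: dict = field(default_factory=dict)

    @property
    def cuts(self) -> tuple[float, ...]:
        return (self.cut1,) if self.cut2 is None else (self.cut1, self.cut2)

    def to_dict(self) -> dict:
        def _lst(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "method": self.method,
            "cut1": self.cut1,
            "cut2": self.cut2,
            "aic": self.aic,
            "bic": self.bic,
            "coefficients": _lst(self.coefficients),
            "hrs": _lst(self.hrs),
            "p_values": _lst(self.p_values),
            "group_counts": _lst(self.group_counts),
            "statistic": self.statistic,
            "naive_p": self.naive_p,
            **({"notes": self.notes} if self.notes else {}),
        }


@dataclass(frozen=True)
class CandidatePair:
    """One equal-log-hazard candidate pair from the percentile sweep."""

    x1: float
    x2: float
    loglam1: float
    loglam2: float
    percentile_index: int

    def __post_init__(self):
        if not self.x1 < self.x2:
            raise ValueError("candidate pair must satisfy x1 < x2")
        if abs(self.loglam1 - self.loglam2) > EQUAL_HR_TOL + 1e-12:
            raise ValueError("candidate pair violates the equal-log-hazard constraint")


def categorize(x: np.ndarray, cut1: float, cut2: float | None = None) -> np.ndarray:
    """Group codes: with two cuts 0=low, 1=middle, 2=high; with one, 0=low, 1=high."""
    x = np.asarray(x, dtype=float)
    if cut2 is None:
        return (x >= cut1).astype(int)
    if not cut1 < cut2:
        raise ValueError("require cut1 < cut2")
    return np.where(x < cut1, 0, np.where(x > cut2, 2, 1))


def dummy_design(codes: np.ndarray, two_cuts: bool) -> np.ndarray:
    """Dummy matrix vs reference (middle group for two cuts, low for one)."""
    if two_cuts:
        return np.column_stack([(codes == 0).astype(float), (codes == 2).astype(float)])
    return (codes == 1).astype(float)[:, None]


def median_cutpoint(x) -> CutpointResult:
    """Single cut at the sample median (groups x < median vs x >= median)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; median split undefined")
    return CutpointResult(method="median", cut1=float(np.percentile(x, 50)))


def quartile_cutpoints(x) -> CutpointResult:
    """Cuts at the empirical 25th and 75th percentiles; middle range reference."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least four observations")
    q1, q3 = np.percentile(x, [25, 75])
    if not q1 < q3:
        raise ValueError("degenerate quartiles (q1 == q3)")
    return CutpointResult(method="q1q3", cut1=float(q1), cut2=float(q3))


def logrank_scores(time: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Log-rank (Savage) scores a_i = d_i - Nelson-Aalen cumulative hazard at t_i."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    d = status[order]
    n = len(t)
    tie_first = np.searchsorted(t, t, side="left")
    at_risk = n - tie_first
    # Nelson-Aalen increments per tie block, shared by all rows of the block
    blocks = np.unique(tie_first)
    d_block = np.bincount(np.searchsorted(blocks, tie_first), weights=d)
    na_at_block = np.cumsum(d_block / at_risk[blocks])
    na = na_at_block[np.searchsorted(blocks, tie_first)]
    scores = np.empty(n)
    scores[order] = d - na
    return scores


def _logrank_statistics(data: SurvivalDataset, thresholds: np.ndarray) -> np.ndarray:
    """Maximally-selected log-rank statistic |Z(c)| kernel for splits x <= c.

    The linear rank statistic S(c) = sum of log-rank scores in {x <= c} is
    standardized by its permutational moments,

        Z(c) = (S - m * abar) / sqrt(m (n - m) / (n (n - 1)) * sum (a - abar)^2),

    with m the group size; this is the standard maximally-selected-rank
    convention and reduces to the two-sample log-rank score test up to the
    variance estimate.
    """
    a = logrank_scores(data.time, data.status)
    n = len(a)
    abar = a.mean()
    va = float(((a - abar) ** 2).sum())
    xo = np.argsort(data.x, kind="mergesort")
    prefix = np.concatenate([[0.0], np.cumsum(a[xo])])
    m = np.searchsorted(data.x[xo], thresholds, side="right")
    S = prefix[m]
    with np.errstate(divide="ignore", invalid="ignore"):
        V = m * (n - m) / (n * (n - 1.0)) * va
        z = np.where(V > 0, (S - m * abar) / np.sqrt(V), 0.0)
    return z


def minp_logrank_cutpoint(
    data: SurvivalDataset,
    window: tuple[float, float] = (0.10, 0.90),
) -> CutpointResult:
    """Maximally selected log-rank split of x within an inner quantile window.

    The returned p-value is the naive minimum over all candidate splits; no
    multiplicity correction is applied (flagged in ``notes``).
    """
    if data.n_events < 20:
        raise ValueError("fewer than 20 events; maximally selected split unreliable")
    lo, hi = np.percentile(data.x, [100 * window[0], 100 * window[1]])
    cands = np.unique(data.x[(data.x >= lo) & (data.x <= hi)])
    # splitting at the largest candidate would leave group 'x > c' possibly empty
    cands = cands[cands < data.x.max()]
    if cands.size == 0:
        raise ValueError("no admissible split inside the quantile window")
    z = _logrank_statistics(data, cands)
    best = int(np.argmax(np.abs(z)))
    stat = float(np.abs(z[best]))
    # split is x <= c vs x > c; place the categorization cut just above c
    res = fit_categorical_cox(data, np.nextafter(cands[best], np.inf), None,
                              min_group_frac=0.0, method_label="minp")
    res.cut1 = float(cands[best])
    res.statistic = stat
    res.naive_p = float(2.0 * norm.sf(stat))
    res.notes["p_value_multiplicity"] = "naive minimum p, uncorrected"
    return res


def fit_categorical_cox(
    data: SurvivalDataset,
    cut1: float,
    cut2: float | None = None,
    min_group_frac: float = DEFAULT_MIN_GROUP_FRAC,
    method_label: str = "categorical",
) -> CutpointResult:
    """Cox refit with x discretized at the given cut(s).

    With two cuts the middle range is the reference level and the model has
    two dummies (low, high); adjustment covariates enter linearly.  AIC uses
    the number of estimated coefficients; BIC uses log(number of events).
    """
    codes = categorize(data.x, cut1, cut2)
    two = cut2 is not None
    n_groups = 3 if two else 2
    counts = np.bincount(codes, minlength=n_groups)
    min_size = int(np.ceil(min_group_frac * data.n))
    for g, c in enumerate(counts):
        if c < max(min_size, 1):
            name = (["low", "middle", "high"] if two else ["low", "high"])[g]
            raise ValueError(
                f"group '{name}' has {c} observations (< required {max(min_size, 1)})"
            )
    design = dummy_design(codes, two)
    if data.covariates is not None:
        design = np.hstack([design, data.covariates])
    fit = _cox.fit_cox(design, data.time, data.status)
    k = design.shape[1]
    n_dummies = 2 if two else 1
    coef = fit.beta[:n_dummies]
    pvals = fit.wald_p_values()[:n_dummies]
    return CutpointResult(
        method=method_label,
        cut1=float(cut1),
        cut2=None if cut2 is None else float(cut2),
        aic=-2.0 * fit.loglik + 2.0 * k,
        bic=-2.0 * fit.loglik + np.log(fit.sorted_data.n_events) * k,
        loglik=fit.loglik,
        coefficients=coef,
        hrs=np.exp(coef),
        p_values=pvals,
        group_counts=counts,
    )


def _branch_crossings(grid: np.ndarray, curve: np.ndarray, level: float, imin: int):
    """Innermost crossings of y=level with the two arms of the fitted curve.

    Returns (x_left, x_right) by linear interpolation between bracketing grid
    points, or None on an arm the level does not cross.
    """
    def interp(i, j):
        y0, y1 = curve[i], curve[j]
        if y1 == y0:
            return float(grid[i])
        w = (level - y0) / (y1 - y0)
        return float(grid[i] + w * (grid[j] - grid[i]))

    left = None
    diff = curve[: imin + 1] - level
    sign_change = np.flatnonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)
    exact = np.flatnonzero(diff == 0)
    cands = []
    if sign_change.size:
        cands.append(interp(sign_change[-1], sign_change[-1] + 1))
    if exact.size:
        cands.append(float(grid[exact[-1]]))
    if cands:
        left = max(cands)  # innermost (largest x) crossing on the left arm

    right = None
    diffr = curve[imin:] - level
    sign_change = np.flatnonzero(np.sign(diffr[:-1]) * np.sign(diffr[1:]) < 0)
    exact = np.flatnonzero(diffr == 0)
    cands = []
    if sign_change.size:
        i = imin + sign_change[0]
        cands.append(interp(i, i + 1))
    if exact.size:
        cands.append(float(grid[imin + exact[0]]))
    if cands:
        right = min(cands)  # innermost (smallest x) crossing on the right arm
    return left, right


def candidate_equal_hr_pairs(
    fit: SplineCoxFit,
    data: SurvivalDataset,
    tol: float = EQUAL_HR_TOL,
    grid_size: int = 2001,
    require_u_shape: bool = True,
) -> list[CandidatePair]:
    """Equal-log-hazard candidate pairs from the 5th-95th percentile sweep.

    For each integer percentile k of the n fitted log relative hazards, the
    horizontal line at that level is intersected with the fitted curve; the
    observed x closest to each intersection (on its side of the curve
    minimum) forms the candidate pair.  If the two observations' fitted
    values differ by more than ``tol``, the pair is replaced by points
    linearly interpolated on the curve so both share the level exactly.
    """
    diag = diagnose_u_shape(fit)
    if require_u_shape and not diag.is_u_shaped:
        raise ValueError(
            "fitted curve is not U-shaped; review the diagnostic plot or pass "
            "require_u_shape=False to search anyway"
        )
    yhat = predict_log_relative_hazard(fit, data.x)
    lo, hi = fit.x_range
    grid = np.linspace(lo, hi, grid_size)
    curve = predict_log_relative_hazard(fit, grid)
    imin = int(np.argmin(curve))
    x_min = grid[imin]
    left_obs = np.sort(data.x[data.x <= x_min])
    right_obs = np.sort(data.x[data.x > x_min])
    pairs: list[CandidatePair] = []
    seen: set[tuple[float, float]] = set()
    for k in range(5, 96):
        level = float(np.percentile(yhat, k))
        xl, xr = _branch_crossings(grid, curve, level, imin)
        if xl is None or xr is None:
            continue
        pair = _observation_pair(fit, yhat, data, left_obs, right_obs,
                                 xl, xr, level, tol, k)
        if pair is None:
            continue
        key = (round(pair.x1, 12), round(pair.x2, 12))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(pair)
    if not pairs:
        raise ValueError("no valid equal-log-hazard pair found on the fitted curve")
    return pairs


def _nearest(sorted_x: np.ndarray, target: float, yhat_at, level: float):
    """Observed value nearest in x to target; |fitted - level| breaks ties."""
    if sorted_x.size == 0:
        return None
    i = np.searchsorted(sorted_x, target)
    cand_idx = [j for j in (i - 1, i) if 0 <= j < len(sorted_x)]
    best, best_key = None, None
    for j in cand_idx:
        xv = float(sorted_x[j])
        key = (abs(xv - target), abs(float(yhat_at(xv)) - level))
        if best is None or key < best_key:
            best, best_key = xv, key
    return best


def _observation_pair(fit, yhat, data, left_obs, right_obs, xl, xr, level, tol, k):
    def yhat_at(xv):
        return predict_log_relative_hazard(fit, np.array([xv]))[0]

    x1 = _nearest(left_obs, xl, yhat_at, level)
    x2 = _nearest(right_obs, xr, yhat_at, level)
    if x1 is not None and x2 is not None and x1 < x2:
        y1, y2 = float(yhat_at(x1)), float(yhat_at(x2))
        if abs(y1 - y2) <= tol:
            return CandidatePair(x1, x2, y1, y2, k)
    # constraint violated (or no observation on an arm): interpolate on the curve
    if xl < xr:
        return CandidatePair(float(xl), float(xr), level, level, k)
    return None


def oehr_cutpoints(
    data: SurvivalDataset,
    fit: SplineCoxFit,
    criterion: str = "aic",
    min_group_frac: float = DEFAULT_MIN_GROUP_FRAC,
    require_u_shape: bool = True,
) -> CutpointResult:
    """Optimal equal-HR cut-points: the candidate pair minimizing AIC (or BIC).

    Ties in the criterion are broken toward the pair with more balanced
    induced group sizes.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    pairs = candidate_equal_hr_pairs(fit, data, require_u_shape=require_u_shape)
    best: CutpointResult | None = None
    best_key = None
    n_failed = 0
    for pair in pairs:
        try:
            res = fit_categorical_cox(data, pair.x1, pair.x2,
                                      min_group_frac=min_group_frac,
                                      method_label="oehr")
        except ValueError:
            n_failed += 1
            continue
        crit = res.aic if criterion == "aic" else res.bic
        imbalance = float(np.std(res.group_counts))
        key = (crit, imbalance)
        if best is None or crit < best_key[0] - 1e-9 or (
            abs(crit - best_key[0]) <= 1e-9 and imbalance < best_key[1]
        ):
            best, best_key = res, key
            best.notes["percentile_index"] = pair.percentile_index
    if best is None:
        raise RuntimeError(
            f"all {len(pairs)} candidate pairs failed the categorical refit"
        )
    best.notes["criterion"] = criterion
    best.notes["n_candidates"] = len(pairs)
    best.notes["n_candidates_failed"] = n_failed
    return best
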