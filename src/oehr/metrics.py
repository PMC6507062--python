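"""Predictive-performance measures for fitted Cox models.

Discrimination: Harrell's c-index and the Gönen-Heller concordance
probability estimate (CPE).  Overall performance / explained variation: the
IPCW integrated Brier score (IBS), the Kent-O'Quigley R²_PM, and the
Royston-Sauerbrei R²_D.  A cross-validation wrapper re-estimates cut-points
and the categorical Cox model on training folds only and evaluates all five
measures on the held-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index

from . import _cox, cutpoints as cp
from .datasets import SurvivalDataset

_EV_VAR = np.pi**2 / 6.0  # variance of the extreme-value error in the Cox frame
_KAPPA = np.sqrt(8.0 / np.pi)


def harrell_cindex(times, status, risk_scores) -> float:
    """Harrell's concordance: higher risk should mean shorter survival.

    Pairs are compared where censoring permits ordering; risk ties count 1/2.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    risk = np.asarray(risk_scores, dtype=float)
    if not (len(times) == len(status) == len(risk)):
        raise ValueError("times, status and risk_scores must have equal length")
    if status.sum() == 0:
        raise ValueError("no events: no usable pairs for concordance")
    # lifelines scores 'higher prediction = longer survival', so negate risk
    return float(concordance_index(times, -risk, status))


def gonen_heller_cpe(linear_predictors) -> float:
    """Gönen-Heller concordance probability estimate from Cox linear predictors.

    Model-based concordance: each unordered pair contributes
    1 / (1 + exp(-|lp_i - lp_j|)); depends only on the fitted model, not on
    the censoring distribution.  All-equal predictors return 0.5.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    n = len(lp)
    if n < 2:
        raise ValueError("need at least two subjects")
    diff = np.abs(lp[:, None] - lp[None, :])
    iu = np.triu_indices(n, k=1)
    return float(np.mean(1.0 / (1.0 + np.exp(-diff[iu]))))


def _censoring_km(time: np.ndarray, status: np.ndarray):
    """Kaplan-Meier of the censoring distribution G(t) = P(C > t)."""
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    cens = 1 - status[order]
    uniq = np.unique(t)
    n = len(t)
    at_risk = n - np.searchsorted(t, uniq, side="left")
    d_cens = np.zeros_like(uniq)
    idx = np.searchsorted(uniq, t)
    np.add.at(d_cens, idx, cens)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(at_risk > 0, 1.0 - d_cens / at_risk, 1.0)
    G = np.cumprod(factors)
    return uniq, G

def _km_eval(uniq, G, t, before=False):
    """G at t (right-continuous) or just before t (left limit)."""
    side = "left" if before else "right"
    idx = np.searchsorted(uniq, t, side=side)
    out = np.where(idx == 0, 1.0, G[np.clip(idx - 1, 0, len(G) - 1)])
    return out


def brier_score(
    train: SurvivalDataset,
    test: SurvivalDataset,
    surv_probs: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """IPCW Brier score BS(t) on test data, censoring weights from train.

    ``surv_probs[i, j]`` is the predicted P(T_i > times[j]).
    """
    surv_probs = np.atleast_2d(np.asarray(surv_probs, dtype=float))
    times = np.asarray(times, dtype=float)
    if surv_probs.shape != (test.n, len(times)):
        raise ValueError("surv_probs must be (n_test, n_times)")
    uniq, G = _censoring_km(train.time, train.status)
    Gm = _km_eval(uniq, G, test.time, before=True)   # G(T_i-)
    bs = np.empty(len(times))
    for j, t in enumerate(times):
        Gt = float(_km_eval(uniq, G, np.array([t]))[0])
        s = surv_probs[:, j]
        died = (test.time <= t) & (test.status == 1)
        alive = test.time > t
        w_died = np.where(Gm > 0, died / np.maximum(Gm, 1e-12), 0.0)
        w_alive = alive / max(Gt, 1e-12)
        bs[j] = float(np.mean(w_died * s**2 + w_alive * (1.0 - s) ** 2))
    return bs


def integrated_brier_score(
    train: SurvivalDataset,
    test: SurvivalDataset,
    surv_probs: np.ndarray,
    times: np.ndarray,
) -> float:
    """Trapezoid-integrated Brier score normalized by the grid span."""
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two grid times")
    bs = brier_score(train, test, surv_probs, times)
    return float(np.trapezoid(bs, times) / (times[-1] - times[0]))


def r2_pm(linear_predictors) -> float:
    """Kent-O'Quigley explained variation: var(lp) / (var(lp) + pi^2/6)."""
    lp = np.asarray(linear_predictors, dtype=float)
    v = float(np.var(lp, ddof=1)) if len(lp) > 1 else 0.0
    if v == 0.0:
        return 0.0
    return v / (v + _EV_VAR)


def _rankits(lp: np.ndarray) -> np.ndarray:
    """Blom normal scores of the lp ranks, ties replaced by their mean score."""
    from scipy.stats import norm, rankdata

    n = len(lp)
    order = np.argsort(lp, kind="mergesort")
    scores = norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    rk = np.empty(n)
    rk[order] = scores
    # average within tied lp values
    r = rankdata(lp, method="dense")
    for g in np.unique(r):
        mask = r == g
        rk[mask] = rk[mask].mean()
    return rk


def r2_d(times, status, linear_predictors) -> float:
    """Royston-Sauerbrei explained variation from the D statistic.

    The lp ranks are mapped to scaled normal order statistics z = rankit/kappa
    with kappa = sqrt(8/pi); a Cox fit of (time, status) on z gives D, and
    R²_D = (D²/kappa²) / (D²/kappa² + pi²/6).
    """
    lp = np.asarray(linear_predictors, dtype=float)
    if len(lp) < 10:
        raise ValueError("need at least 10 subjects")
    if np.ptp(lp) == 0:
        return 0.0
    z = _rankits(lp) / _KAPPA
    if np.ptp(z) == 0:
        return 0.0
    fit = _cox.fit_cox(z[:, None], np.asarray(times, float), np.asarray(status, int))
    d = float(fit.beta[0])
    d2k = d**2 / _KAPPA**2
    return d2k / (d2k + _EV_VAR)


@dataclass
class PerformanceReport:
    """Cross-validated predictive performance: mean ± SE per measure."""

    method: str
    means: dict
    ses: dict
    per_fold: pd.DataFrame = field(repr=False, default=None)

    MEASURES = ("cindex", "cpe", "ibs", "r2_pm", "r2_d")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            **{m: self.means.get(m) for m in self.MEASURES},
            **{f"{m}_se": self.ses.get(m) for m in self.MEASURES},
        }


def _stratified_folds(data: SurvivalDataset, n_folds: int, rng) -> list[np.ndarray]:
    """Fold index arrays, stratified by event status.

    Within each stratum rows are keyed by (time, x) before shuffling, so the
    partition is invariant to the storage order of the rows.
    """
    assignments = np.empty(data.n, dtype=int)
    for val in (0, 1):
        idx = np.flatnonzero(data.status == val)
        idx = idx[np.lexsort((data.x[idx], data.time[idx]))]
        idx = idx[rng.permutation(len(idx))]
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            assignments[chunk] = f
    return [np.flatnonzero(assignments == f) for f in range(n_folds)]


def _train_cutpoints(train: SurvivalDataset, method: str, criterion: str):
    from . import spline

    if method == "median":
        r = cp.median_cutpoint(train.x)
    elif method == "q1q3":
        r = cp.quartile_cutpoints(train.x)
    elif method == "minp":
        r = cp.minp_logrank_cutpoint(train)
    elif method == "oehr":
        fit = spline.select_smoothing_by_aic(train)
        r = cp.oehr_cutpoints(train, fit, criterion=criterion,
                              require_u_shape=False)
    else:
        raise ValueError(f"unknown cut-point method '{method}'")
    return r.cut1, r.cut2


def _evaluate_fold(
    train: SurvivalDataset,
    test: SurvivalDataset,
    cut1: float,
    cut2: float | None,
) -> dict:
    codes_tr = cp.categorize(train.x, cut1, cut2)
    codes_te = cp.categorize(test.x, cut1, cut2)
    two = cut2 is not None
    X_tr = cp.dummy_design(codes_tr, two)
    X_te = cp.dummy_design(codes_te, two)
    if train.covariates is not None:
        X_tr = np.hstack([X_tr, train.covariates])
        X_te = np.hstack([X_te, test.covariates])
    sd = _cox.prepare(X_tr, train.time, train.status)
    fit = _cox.newton_fit(sd)
    lp_te = X_te @ fit.beta
    knot_times, H0 = _cox.breslow_baseline(sd, fit.beta)
    t_hi = min(float(np.percentile(train.time, 95)), float(test.time.max()))
    t_lo = float(min(train.time.min(), test.time.min()))
    times = np.linspace(t_lo, t_hi, 50)
    surv = _cox.predict_survival(knot_times, H0, lp_te, times)
    return {
        "cindex": harrell_cindex(test.time, test.status, lp_te),
        "cpe": gonen_heller_cpe(lp_te),
        "ibs": integrated_brier_score(train, test, surv, times),
        "r2_pm": r2_pm(lp_te),
        "r2_d": r2_d(test.time, test.status, lp_te),
    }


def crossvalidated_performance(
    data: SurvivalDataset,
    cutpoint_method: str = "oehr",
    n_folds: int = 2,
    n_repeats: int = 1,
    seed: int = 0,
    criterion: str = "aic",
    max_fold_retries: int = 10,
) -> PerformanceReport:
    """Repeated stratified k-fold cross-validation of a discretization method.

    Cut-points and the categorical Cox model are estimated on the training
    folds only; all five measures are computed on the held-out fold.  The
    report gives means and standard errors across the repeats x folds
    evaluations and is deterministic given the seed.
    """
    if n_folds < 2:
        raise ValueError("need at least two folds")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        for attempt in range(max_fold_retries):
            folds = _stratified_folds(data, n_folds, rng)
            if all(data.status[f].sum() > 0 and data.status[np.setdiff1d(
                    np.arange(data.n), f)].sum() > 0 for f in folds):
                break
        else:
            raise RuntimeError("could not draw folds with events in every split")
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(data.n), test_idx)
            train, test = data.subset(train_idx), data.subset(test_idx)
            cut1, cut2 = _train_cutpoints(train, cutpoint_method, criterion)
            vals = _evaluate_fold(train, test, cut1, cut2)
            rows.append({"repeat": rep, "fold": f, **vals})
    df = pd.DataFrame(rows)
    measures = list(PerformanceReport.MEASURES)
    means = {m: float(df[m].mean()) for m in measures}
    ses = {
        m: float(df[m].std(ddof=1) / np.sqrt(len(df))) if len(df) > 1 else np.nan
        for m in measures
    }
    return PerformanceReport(cutpoint_method, means, ses, df)
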