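"""Penalized B-spline (P-spline) Cox fit for the log relative hazard curve.

The diagnostic step of the equal-HR workflow fits

    h(t | x) = h0(t) * exp(f(x) + gamma' z),

where f is a cubic B-spline expansion on evenly spaced knots with an
Eilers-Marx second-order difference penalty on adjacent coefficients, and z
are optional unpenalized adjustment covariates.  The smoothing weight is
chosen by minimizing AIC = -2 pl + 2 edf with edf the trace-based effective
degrees of freedom.  Because the partial likelihood is invariant to adding a
constant to the linear predictor and the B-spline basis sums to one at every
x, the spline coefficients are estimated in the subspace orthogonal to the
constant vector and the fitted curve is reported centered to mean zero over
the observed predictor values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import eigh, null_space
from scipy.optimize import brentq
from scipy.stats import chi2

from . import _cox
from .datasets import SurvivalDataset

DEFAULT_DEGREE = 3
DEFAULT_N_KNOTS = 22


def _knot_vector(x_min: float, x_max: float, degree: int, n_knots: int) -> np.ndarray:
    # equally spaced knots extended past the range (not clamped), so every
    # basis function is a uniform translate and the difference penalty's null
    # space corresponds to polynomials in x
    step = (x_max - x_min) / (n_knots - 1)
    inner = np.linspace(x_min, x_max, n_knots)
    left = x_min - step * np.arange(degree, 0, -1)
    right = x_max + step * np.arange(1, degree + 1)
    return np.concatenate([left, inner, right])


def bspline_basis(
    x,
    degree: int = DEFAULT_DEGREE,
    n_knots: int = DEFAULT_N_KNOTS,
    x_range: tuple[float, float] | None = None,
):
    """B-spline design matrix on evenly spaced knots spanning the data.

    Returns ``(B, knots)`` with ``B`` of shape (n, n_knots + degree - 1);
    rows sum to one everywhere inside the knot range (partition of unity).
    """
    x = np.asarray(x, dtype=float)
    if n_knots < degree + 2:
        raise ValueError("need at least degree + 2 knots")
    if x_range is None:
        x_range = (float(x.min()), float(x.max()))
    lo, hi = x_range
    if not hi > lo:
        raise ValueError("predictor is constant; spline basis undefined")
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError(f"x outside the basis range [{lo:.6g}, {hi:.6g}]")
    knots = _knot_vector(lo, hi, degree, n_knots)
    # nudge the right boundary inward so the closed right endpoint is included
    xe = np.clip(x, lo, hi - 1e-12 * max(1.0, abs(hi)))
    B = BSpline.design_matrix(xe, knots, degree).toarray()
    return B, knots


def _difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


@dataclass
class SplineCoxFit:
    """Fitted penalized-spline Cox model for one continuous predictor."""

    knots: np.ndarray
    degree: int
    coefficients: np.ndarray            # spline block, identifiable up to a constant
    covariate_coefficients: np.ndarray  # unpenalized adjustment effects
    smoothing: float
    edf: float
    loglik: float                       # unpenalized partial log-likelihood
    center: float                       # mean of B(x_obs) @ coefficients
    x_range: tuple[float, float]
    data: SurvivalDataset
    n_iter: int = 0

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.edf

    def predict(self, x_new) -> np.ndarray:
        return predict_log_relative_hazard(self, x_new)

    def __call__(self, x_new) -> np.ndarray:
        return self.predict(x_new)


def _build_design(data: SurvivalDataset, degree: int, n_knots: int):
    B, knots = bspline_basis(data.x, degree, n_knots)
    p = B.shape[1]
    Z = null_space(np.ones((1, p)))  # (p, p-1), orthonormal complement of 1
    BZ = B @ Z
    if data.covariates is not None:
        design = np.hstack([BZ, data.covariates])
    else:
        design = BZ
    P = _difference_penalty(p)
    Pz = Z.T @ P @ Z
    return B, knots, Z, design, Pz


def _penalty_full(Pz: np.ndarray, n_cov: int, smoothing: float) -> np.ndarray:
    q = Pz.shape[0] + n_cov
    pen = np.zeros((q, q))
    pen[: Pz.shape[0], : Pz.shape[0]] = smoothing * Pz
    return pen


def fit_penalized_cox(
    data: SurvivalDataset,
    smoothing: float,
    degree: int = DEFAULT_DEGREE,
    n_knots: int = DEFAULT_N_KNOTS,
    beta0: np.ndarray | None = None,
) -> SplineCoxFit:
    """Fit the P-spline Cox model at a fixed smoothing weight.

    The effective degrees of freedom are trace((H + s P)^-1 H) with H the
    unpenalized negative Hessian at the solution, computed in the
    identifiable parametrization.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    if data.n_events < 20:
        raise ValueError("fewer than 20 events; spline fit unreliable")
    B, knots, Z, design, Pz = _build_design(data, degree, n_knots)
    n_cov = 0 if data.covariates is None else data.covariates.shape[1]
    pen = _penalty_full(Pz, n_cov, smoothing)
    sd = _cox.prepare(design, data.time, data.status)
    fit = _cox.newton_fit(sd, penalty=pen, beta0=beta0)
    H = fit.neg_hessian
    edf = float(np.trace(np.linalg.solve(H + pen, H)))
    gamma = fit.beta[: Z.shape[1]]
    cov_coef = fit.beta[Z.shape[1]:]
    coef = Z @ gamma
    center = float((B @ coef).mean())
    return SplineCoxFit(
        knots=knots,
        degree=degree,
        coefficients=coef,
        covariate_coefficients=cov_coef,
        smoothing=smoothing,
        edf=edf,
        loglik=fit.loglik,
        center=center,
        x_range=(float(data.x.min()), float(data.x.max())),
        data=data,
        n_iter=fit.n_iter,
    )


def _edf_bounds_grid(
    data: SurvivalDataset,
    degree: int,
    n_knots: int,
    edf_range: tuple[float, float],
    n_grid: int,
) -> np.ndarray:
    """Log-spaced smoothing grid whose endpoints hit the target edf range.

    Uses the generalized eigenvalues of the penalty with respect to the
    Hessian of a pilot fit, for which edf(s) = sum_i 1 / (1 + s * d_i) is a
    cheap, strictly decreasing function of s.
    """
    B, knots, Z, design, Pz = _build_design(data, degree, n_knots)
    n_cov = 0 if data.covariates is None else data.covariates.shape[1]
    sd = _cox.prepare(design, data.time, data.status)
    pilot_pen = _penalty_full(Pz, n_cov, 1.0)
    pilot = _cox.newton_fit(sd, penalty=pilot_pen)
    H = pilot.neg_hessian
    P1 = _penalty_full(Pz, n_cov, 1.0)
    # symmetrize against numerical asymmetry before the generalized eig solve
    H = 0.5 * (H + H.T)
    d = eigh(P1, H + 1e-10 * np.eye(len(H)), eigvals_only=True)
    d = np.clip(d, 0.0, None)

    def edf_of(log_s: float) -> float:
        return float(np.sum(1.0 / (1.0 + np.exp(log_s) * d)))

    lo_target = min(edf_range) + n_cov
    hi_target = max(edf_range) + n_cov
    hi_target = min(hi_target, len(H) - 0.5)

    def solve_for(target: float) -> float:
        f = lambda ls: edf_of(ls) - target
        a, b = -25.0, 25.0
        if f(a) < 0:  # even s -> 0 cannot reach target edf
            return a
        if f(b) > 0:
            return b
        return brentq(f, a, b, xtol=1e-3)

    ls_hi_edf = solve_for(hi_target)  # small smoothing
    ls_lo_edf = solve_for(lo_target)  # large smoothing
    return np.exp(np.linspace(ls_hi_edf, ls_lo_edf, n_grid))


def select_smoothing_by_aic(
    data: SurvivalDataset,
    grid: np.ndarray | None = None,
    degree: int = DEFAULT_DEGREE,
    n_knots: int = DEFAULT_N_KNOTS,
    n_grid: int = 25,
    edf_range: tuple[float, float] = (2.0, 15.0),
) -> SplineCoxFit:
    """Grid-search the smoothing weight by AIC; ties go to the smoother fit."""
    if grid is None:
        grid = _edf_bounds_grid(data, degree, n_knots, edf_range, n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) < 0):
        raise ValueError("smoothing grid must be non-empty, positive and sorted")
    best: SplineCoxFit | None = None
    beta0 = None
    errors = []
    for s in grid:
        try:
            fit = fit_penalized_cox(data, s, degree, n_knots, beta0=beta0)
        except Exception as exc:  # noqa: BLE001 - a failed grid point is skipped
            errors.append((s, exc))
            continue
        # warm-start the next (smoother) grid point
        p = len(fit.coefficients)
        Z = null_space(np.ones((1, p)))
        beta0 = np.concatenate([Z.T @ fit.coefficients, fit.covariate_coefficients])
        # ties broken toward larger smoothing: >= on the increasing grid
        if best is None or fit.aic <= best.aic + 1e-10:
            best = fit
    if best is None:
        raise RuntimeError(f"all smoothing-grid fits failed: {errors[:3]}")
    return best


def predict_log_relative_hazard(fit: SplineCoxFit, x_new) -> np.ndarray:
    """Centered log relative hazard at new predictor values (no extrapolation)."""
    x_new = np.asarray(x_new, dtype=float)
    lo, hi = fit.x_range
    if np.any(x_new < lo) or np.any(x_new > hi):
        raise ValueError(
            f"prediction outside the observed predictor range [{lo:.6g}, {hi:.6g}]"
        )
    B, _ = bspline_basis(
        x_new, fit.degree, len(fit.knots) - 2 * fit.degree, x_range=fit.x_range
    )
    out = B @ fit.coefficients - fit.center
    return float(out) if out.ndim == 0 else out


@dataclass
class UShapeDiagnostic:
    """Shape check of the fitted curve plus a nonlinearity test."""

    is_u_shaped: bool
    x_grid: np.ndarray
    curve: np.ndarray
    minimum: float
    p_nonlinear: float


def diagnose_u_shape(fit: SplineCoxFit, grid_size: int = 200) -> UShapeDiagnostic:
    """Decide whether the fitted curve is U-shaped.

    The curve is sampled on ``grid_size`` points over the central 90% of the
    observed predictor (boundary wiggle of splines is ignored); it is called
    U-shaped iff the first differences change sign exactly once, from
    negative to positive.  The nonlinearity p-value compares the spline fit
    against a linear Cox fit by a chi-square test on 2*(pl_spline - pl_linear)
    with edf_spline - 1 degrees of freedom.
    """
    x = fit.data.x
    lo, hi = np.percentile(x, [5, 95])
    grid = np.linspace(lo, hi, grid_size)
    curve = predict_log_relative_hazard(fit, grid)
    d = np.diff(curve)
    signs = np.sign(d)
    signs = signs[signs != 0]
    changes = np.flatnonzero(np.diff(signs) != 0)
    is_u = len(changes) == 1 and signs[changes[0]] < 0 < signs[changes[0] + 1]
    minimum = float(grid[np.argmin(curve)])

    if fit.data.covariates is not None:
        lin_design = np.column_stack([x, fit.data.covariates])
    else:
        lin_design = x[:, None]
    lin = _cox.fit_cox(lin_design, fit.data.time, fit.data.status)
    lr = max(0.0, 2.0 * (fit.loglik - lin.loglik))
    n_cov = 0 if fit.data.covariates is None else fit.data.covariates.shape[1]
    df = max(fit.edf - n_cov - 1.0, 1e-6)
    p_nonlinear = float(chi2.sf(lr, df))
    return UShapeDiagnostic(bool(is_u), grid, curve, minimum, p_nonlinear)


def export_curve(fit: SplineCoxFit, grid_size: int = 200) -> "pd.DataFrame":
    """Curve samples with pointwise normal-approximation 95% bands."""
    import pandas as pd

    lo, hi = fit.x_range
    grid = np.linspace(lo, hi, grid_size)
    y = predict_log_relative_hazard(fit, grid)
    # refit covariance at the selected smoothing for pointwise bands
    B, knots, Z, design, Pz = _build_design(fit.data, fit.degree,
                                            len(fit.knots) - 2 * fit.degree)
    n_cov = 0 if fit.data.covariates is None else fit.data.covariates.shape[1]
    pen = _penalty_full(Pz, n_cov, fit.smoothing)
    sd = _cox.prepare(design, fit.data.time, fit.data.status)
    refit = _cox.newton_fit(sd, penalty=pen)
    cov = refit.covariance[: Z.shape[1], : Z.shape[1]]
    Bg, _ = bspline_basis(grid, fit.degree, len(fit.knots) - 2 * fit.degree,
                          x_range=fit.x_range)
    A = (Bg - (B.mean(axis=0))[None, :]) @ Z
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", A, cov, A), 0.0))
    return pd.DataFrame({
        "x_grid": grid,
        "log_lambda_hat": y,
        "lower95": y - 1.96 * se,
        "upper95": y + 1.96 * se,
    })
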