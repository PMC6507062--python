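"""Cox partial-likelihood engine (Breslow ties) shared by every fit in the package.

All higher-level fits — the penalized spline fit, the three-group categorical
refits inside the cut-point search, and the rank-based D statistic — reduce to
Newton maximization of the (optionally penalized) Breslow partial
log-likelihood.  Keeping one engine guarantees that AIC values compared across
fits are on the same likelihood scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve
from scipy.stats import norm


class CoxConvergenceError(RuntimeError):
    """Newton iterations failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


@dataclass(frozen=True)
class _SortedData:
    """Design and outcome sorted by ascending observed time."""

    X: np.ndarray          # (n, p) sorted design
    time: np.ndarray       # (n,) sorted observed times
    event: np.ndarray      # (n,) boolean, sorted
    tie_first: np.ndarray  # index of first row of each row's tie block
    order: np.ndarray      # original -> sorted permutation
    n_events: int


def prepare(X: np.ndarray, time: np.ndarray, status: np.ndarray) -> _SortedData:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    tie_first = np.searchsorted(t, t, side="left")
    event = status[order].astype(bool)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in the data; Cox partial likelihood undefined")
    return _SortedData(X[order], t, event, tie_first, order, n_events)


def loglik_grad_hess(sd: _SortedData, beta: np.ndarray, need_hess: bool = True):
    """Breslow partial log-likelihood, score and negative Hessian at ``beta``.

    The linear predictor is shifted by its maximum before exponentiation; the
    partial likelihood is invariant to that shift.
    """
    lp = sd.X @ beta
    lp = lp - lp.max()
    w = np.exp(lp)
    S0 = _revcumsum(w)[sd.tie_first]
    ev = sd.event
    if np.any(S0[ev] <= 0.0):
        # risk-set weights underflowed at an event: treat as an infeasible step
        p = sd.X.shape[1]
        return -np.inf, np.zeros(p), (np.eye(p) if need_hess else None)
    ll = float(lp[ev].sum() - np.log(S0[ev]).sum())
    wX = w[:, None] * sd.X
    S1 = _revcumsum(wX)[sd.tie_first]
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = S1 / S0[:, None]
    xbar[S0 <= 0.0] = 0.0
    grad = (sd.X[ev] - xbar[ev]).sum(axis=0)
    H = None
    if need_hess:
        wXX = wX[:, :, None] * sd.X[:, None, :]
        S2 = _revcumsum(wXX)[sd.tie_first]
        E2 = S2[ev] / S0[ev, None, None]
        xb = xbar[ev]
        H = E2.sum(axis=0) - np.einsum("ij,ik->jk", xb, xb)
    return ll, grad, H


@dataclass
class CoxFit:
    """Result of a (possibly penalized) Newton fit.

    ``loglik`` is the *unpenalized* partial log-likelihood at the solution;
    ``neg_hessian`` the unpenalized negative Hessian there.
    """

    beta: np.ndarray
    loglik: float
    neg_hessian: np.ndarray
    penalty: np.ndarray | None
    n_iter: int
    converged: bool
    sorted_data: _SortedData

    @property
    def covariance(self) -> np.ndarray:
        A = self.neg_hessian if self.penalty is None else self.neg_hessian + self.penalty
        return np.linalg.inv(A)

    def wald_p_values(self) -> np.ndarray:
        se = np.sqrt(np.diag(self.covariance))
        z = self.beta / se
        return 2.0 * norm.sf(np.abs(z))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.beta)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.sorted_data.n_events) * len(self.beta)


def newton_fit(
    sd: _SortedData,
    penalty: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-6,
) -> CoxFit:
    """Maximize pl(beta) - 0.5 * beta' P beta by damped Newton iterations.

    The penalized objective is concave, so Newton with step-halving is
    globally convergent; convergence is declared on the max-norm of the
    penalized score.
    """
    p = sd.X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    trace: list[float] = []

    def penalized(ll: float, b: np.ndarray) -> float:
        if penalty is None:
            return ll
        return ll - 0.5 * float(b @ penalty @ b)

    ll, grad, H = loglik_grad_hess(sd, beta)
    obj = penalized(ll, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g_pen = grad if penalty is None else grad - penalty @ beta
        H_pen = H if penalty is None else H + penalty
        trace.append(obj)
        if np.max(np.abs(g_pen)) < tol:
            converged = True
            break
        try:
            step = solve(H_pen, g_pen, assume_a="pos")
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H_pen, g_pen, rcond=None)[0]
        # step-halving keeps the penalized objective non-decreasing
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_c, grad_c, H_c = loglik_grad_hess(sd, cand)
            obj_c = penalized(ll_c, cand)
            if np.isfinite(obj_c) and obj_c >= obj - 1e-12:
                break
            alpha *= 0.5
        else:
            raise CoxConvergenceError("step-halving failed to improve objective", trace)
        beta, ll, grad, H, obj = cand, ll_c, grad_c, H_c, obj_c
    if not converged:
        raise CoxConvergenceError(
            f"Newton did not converge in {max_iter} iterations", trace
        )
    return CoxFit(beta, ll, H, penalty, it, converged, sd)


def fit_cox(
    X: np.ndarray,
    time: np.ndarray,
    status: np.ndarray,
    penalty: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    **kw,
) -> CoxFit:
    """Convenience wrapper: sort, fit, return the fit in original row order context."""
    sd = prepare(X, time, status)
    return newton_fit(sd, penalty=penalty, beta0=beta0, **kw)


def breslow_baseline(sd: _SortedData, beta: np.ndarray):
    """Breslow estimate of the baseline cumulative hazard.

    Returns (event_times, cumhaz) step-function knots; the estimate refers to
    the baseline at linear predictor 0 in the *uncentered* parametrization of
    ``beta`` and the design stored in ``sd``.
    """
    lp = sd.X @ beta
    w = np.exp(lp)
    S0 = _revcumsum(w)[sd.tie_first]
    ev = sd.event
    # one increment per tie block: (#events in block) / S0(block)
    first = sd.tie_first[ev]
    inc = 1.0 / S0[ev]
    uniq, inv = np.unique(first, return_inverse=True)
    increments = np.bincount(inv, weights=inc)
    return sd.time[uniq], np.cumsum(increments)


def predict_survival(
    knot_times: np.ndarray,
    baseline_cumhaz: np.ndarray,
    lp_new: np.ndarray,
    eval_times: np.ndarray,
) -> np.ndarray:
    """S(t | lp) = exp(-H0(t) * exp(lp)); rows index subjects, columns times."""
    H0 = np.concatenate([[0.0], baseline_cumhaz])
    idx = np.searchsorted(knot_times, eval_times, side="right")
    H0_at = H0[idx]
    return np.exp(-np.outer(np.exp(lp_new), H0_at))
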