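"""Weibull survival-data generator with a V-shaped log relative hazard.

The generator emulates a standard Monte-Carlo design for studying cut-point
selection: a standard-normal predictor x acts on the hazard through a
piecewise-linear, V-shaped log relative hazard

    s(x) = k1 * (x - a)   for x <= a,
           k2 * (x - a)   for x >  a,      k1 < 0 < k2,

so the hazard is U-shaped in x with its minimum at the turning point ``a``.
Event times follow a Weibull baseline via inverse-transform sampling,

    T0 = (-log(U) / (lambda * exp(s(x))))**(1/v),   U ~ Uniform(0, 1),

and censoring times are Uniform(0, r), with r calibrated numerically so the
expected censoring fraction matches a target proportion Pc.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .datasets import SurvivalDataset

#: substream key reserved for the censoring-bound calibration sample
_CALIBRATION_KEY = 999_983


def piecewise_log_hazard(x, k1: float, k2: float, a: float):
    """V-shaped log relative hazard s(x); vectorized over ``x``.

    Continuous at the turning point with s(a) = 0; slope k1 < 0 on the left
    arm and k2 > 0 on the right arm.
    """
    if not (k1 < 0 < k2):
        raise ValueError("require k1 < 0 < k2 for a U-shaped hazard")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite predictor values")
    out = np.where(x <= a, k1 * (x - a), k2 * (x - a))
    return float(out) if out.ndim == 0 else out


def peak_asymmetry_factor(k1: float, k2: float) -> float:
    """|k1| / k2: ratio of arm widths of the V at equal height (1 = symmetric)."""
    if not (k1 < 0 < k2):
        raise ValueError("require k1 < 0 < k2")
    return abs(k1) / k2


def draw_survival_times(s_values, lambda_scale: float, v: float, rng) -> np.ndarray:
    """Inverse-transform Weibull event times given log relative hazards."""
    if lambda_scale <= 0 or v <= 0:
        raise ValueError("lambda_scale and v must be positive")
    s_values = np.asarray(s_values, dtype=float)
    if not np.all(np.isfinite(s_values)):
        raise ValueError("non-finite log-hazard values")
    u = rng.uniform(size=s_values.shape)
    return (-np.log(u) / (lambda_scale * np.exp(s_values))) ** (1.0 / v)


@dataclass
class SimulationScenario:
    """One cell of the simulation design.

    Defaults reflect the study conditions: n = 500 subjects, 100 replicate
    datasets, unit Weibull scale, and a constant baseline hazard (v = 1).
    """

    k1: float
    k2: float
    a: float
    v: float = 1.0
    lambda_scale: float = 1.0
    pc: float = 0.0
    n: int = 500
    reps: int = 100
    seed: int = 0
    _r: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not (self.k1 < 0 < self.k2):
            raise ValueError("require k1 < 0 < k2")
        if self.v <= 0 or self.lambda_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        if not (0 <= self.pc < 1):
            raise ValueError("censoring proportion must lie in [0, 1)")
        if self.n < 2:
            raise ValueError("need at least two subjects")

    @property
    def censoring_bound(self) -> float:
        """Upper bound r of the Uniform(0, r) censoring distribution."""
        if self._r is None:
            self._r = calibrate_censoring_bound(self)
        return self._r

    def to_json(self, path) -> None:
        d = asdict(self)
        d.pop("_r")
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        return cls(**{k: v for k, v in d.items() if not k.startswith("_")})


def calibrate_censoring_bound(
    scenario: SimulationScenario,
    calibration_n: int = 200_000,
    tol: float = 0.005,
) -> float:
    """Find r so the expected censoring fraction equals the target Pc.

    Given a fixed calibration sample of event times T0, the censoring
    probability under C ~ Uniform(0, r) is E[min(T0, r)] / r, a smooth,
    strictly decreasing function of r, solved by bracketing + Brent.  Pc = 0
    returns +inf (no censoring).
    """
    if scenario.pc == 0:
        return np.inf
    rng = np.random.default_rng([scenario.seed, _CALIBRATION_KEY])
    x = rng.standard_normal(calibration_n)
    s = piecewise_log_hazard(x, scenario.k1, scenario.k2, scenario.a)
    t0 = draw_survival_times(s, scenario.lambda_scale, scenario.v, rng)

    def censor_frac(r: float) -> float:
        return float(np.minimum(t0, r).mean() / r)

    lo = 1e-9
    hi = max(1.0, float(np.median(t0)))
    while censor_frac(hi) > scenario.pc:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the censoring bound")
    r = brentq(lambda r: censor_frac(r) - scenario.pc, lo, hi, xtol=1e-10, rtol=1e-12)
    if abs(censor_frac(r) - scenario.pc) > tol:
        raise RuntimeError("censoring calibration did not reach tolerance")
    return float(r)


def generate_dataset(scenario: SimulationScenario, rep_index: int = 0) -> SurvivalDataset:
    """Generate one replicate dataset; reproducible given (seed, rep_index)."""
    if not (0 <= rep_index < scenario.reps):
        raise ValueError(f"replicate index {rep_index} outside [0, {scenario.reps})")
    rng = np.random.default_rng([scenario.seed, rep_index])
    x = rng.standard_normal(scenario.n)
    s = piecewise_log_hazard(x, scenario.k1, scenario.k2, scenario.a)
    t0 = draw_survival_times(s, scenario.lambda_scale, scenario.v, rng)
    if scenario.pc == 0:
        time, status = t0, np.ones(scenario.n, dtype=int)
    else:
        c = rng.uniform(0.0, scenario.censoring_bound, size=scenario.n)
        time = np.minimum(t0, c)
        status = (t0 <= c).astype(int)
    return SurvivalDataset(time, status, x)
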