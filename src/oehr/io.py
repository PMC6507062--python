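"""Analysis configuration and the end-to-end applied workflow.

The applied workflow mirrors how the method is used on real data: fit the
P-spline diagnostic curve, check the U shape, apply the requested
discretization methods, refit the categorical Cox models, and cross-validate
their predictive performance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import cutpoints as cp, metrics, spline
from .datasets import SurvivalDataset, read_dataset

logger = logging.getLogger(__name__)

METHOD_CHOICES = ("median", "q1q3", "minp", "oehr")


@dataclass
class AnalysisConfig:
    """Configuration of one applied analysis run."""

    input_path: str
    time_col: str = "time"
    status_col: str = "status"
    x_col: str = "x"
    covariate_cols: list[str] = field(default_factory=list)
    methods: tuple[str, ...] = METHOD_CHOICES
    criterion: str = "aic"
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0
    out_dir: str = "oehr_results"
    plot: bool = False
    allow_non_u: bool = False

    def __post_init__(self):
        if self.criterion not in ("aic", "bic"):
            raise ValueError("criterion must be 'aic' or 'bic'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        bad = [m for m in self.methods if m not in METHOD_CHOICES]
        if bad:
            raise ValueError(f"unknown methods: {bad}")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


def load_dataset(config: AnalysisConfig) -> SurvivalDataset:
    return read_dataset(
        config.input_path,
        time_col=config.time_col,
        status_col=config.status_col,
        x_col=config.x_col,
        covariate_cols=config.covariate_cols or None,
    )


def run_full_analysis(config: AnalysisConfig, data: SurvivalDataset | None = None) -> dict:
    """Diagnose, cut, refit and cross-validate; write a report bundle.

    Returns the bundle as a dict and writes ``curve.csv``, ``cutpoints.csv``,
    ``performance.csv`` and ``bundle.json`` (plus an optional diagnostic PNG)
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = load_dataset(config)

    fit = spline.select_smoothing_by_aic(data)
    diag = spline.diagnose_u_shape(fit)
    curve = spline.export_curve(fit)
    curve.to_csv(out / "curve.csv", index=False)
    if config.plot:
        _plot_curve(curve, out / "curve.png")

    wants_oehr = "oehr" in config.methods
    if wants_oehr and not diag.is_u_shaped and not config.allow_non_u:
        raise RuntimeError(
            "the fitted log relative hazard curve is not U-shaped; review "
            "curve.csv / the diagnostic plot, or set allow_non_u to force the search"
        )

    cut_rows = []
    for m in config.methods:
        if m == "median":
            res = cp.median_cutpoint(data.x)
            res = cp.fit_categorical_cox(data, res.cut1, None, method_label="median")
        elif m == "q1q3":
            r0 = cp.quartile_cutpoints(data.x)
            res = cp.fit_categorical_cox(data, r0.cut1, r0.cut2, method_label="q1q3")
        elif m == "minp":
            res = cp.minp_logrank_cutpoint(data)
        else:
            res = cp.oehr_cutpoints(data, fit, criterion=config.criterion,
                                    require_u_shape=not config.allow_non_u)
        cut_rows.append(res.to_dict())

    perf_rows = []
    for m in config.methods:
        report = metrics.crossvalidated_performance(
            data, m, n_folds=config.cv_folds, n_repeats=config.cv_repeats,
            seed=config.seed, criterion=config.criterion,
        )
        perf_rows.append(report.to_dict())

    import pandas as pd

    pd.DataFrame(cut_rows).to_csv(out / "cutpoints.csv", index=False)
    pd.DataFrame(perf_rows).to_csv(out / "performance.csv", index=False)
    bundle = {
        "config": asdict(config),
        "n": data.n,
        "n_events": data.n_events,
        "diagnostic": {
            "is_u_shaped": diag.is_u_shaped,
            "minimum": diag.minimum,
            "p_nonlinear": diag.p_nonlinear,
            "edf": fit.edf,
            "smoothing": fit.smoothing,
            "aic": fit.aic,
        },
        "cutpoints": cut_rows,
        "performance": perf_rows,
    }
    with open(out / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    logger.info("analysis bundle written to %s", out)
    return bundle


def _plot_curve(curve, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["x_grid"], curve["log_lambda_hat"], "k-")
    ax.plot(curve["x_grid"], curve["lower95"], "--", color="grey")
    ax.plot(curve["x_grid"], curve["upper95"], "--", color="grey")
    ax.set_xlabel("predictor")
    ax.set_ylabel("log relative hazard")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
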