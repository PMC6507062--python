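"""Monte-Carlo study orchestration.

Sweeps simulation scenarios, applies the four discretization methods to each
replicate dataset, and aggregates cut-point distributions (median / mean /
simulation SE) and, optionally, cross-validated performance distributions in
the layout of the study's summary tables and boxplots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cutpoints as cp, metrics, spline
from .datasets import SurvivalDataset
from .simulate import SimulationScenario, generate_dataset

logger = logging.getLogger(__name__)

ALL_METHODS = ("median", "q1q3", "minp", "oehr")
#: cut-slot labels per method, in table order
_SLOTS = {
    "median": ("median",),
    "q1q3": ("q1q3_1", "q1q3_2"),
    "minp": ("minp",),
    "oehr": ("oehr_1", "oehr_2"),
}


@dataclass
class ScenarioSummary:
    """Aggregated results of one simulation scenario."""

    scenario: SimulationScenario
    cut_summary: pd.DataFrame            # slot, method, median, mean, sim_se
    replicate_cuts: pd.DataFrame         # rep, method, cut1, cut2, aic, bic
    metrics_long: pd.DataFrame | None    # rep, method, measure, value
    n_failures: int = 0
    failures: list = field(default_factory=list)


def _apply_methods(
    data: SurvivalDataset,
    methods,
    criterion: str,
) -> dict[str, cp.CutpointResult]:
    out: dict[str, cp.CutpointResult] = {}
    fit = None
    for m in methods:
        if m == "median":
            out[m] = cp.median_cutpoint(data.x)
        elif m == "q1q3":
            out[m] = cp.quartile_cutpoints(data.x)
        elif m == "minp":
            out[m] = cp.minp_logrank_cutpoint(data)
        elif m == "oehr":
            if fit is None:
                fit = spline.select_smoothing_by_aic(data)
            out[m] = cp.oehr_cutpoints(data, fit, criterion=criterion,
                                       require_u_shape=False)
        else:
            raise ValueError(f"unknown method '{m}'")
    return out


def run_scenario(
    scenario: SimulationScenario,
    methods=ALL_METHODS,
    metrics_on: bool = False,
    cv_folds: int = 2,
    cv_repeats: int = 1,
    criterion: str = "aic",
    max_failure_frac: float = 0.20,
) -> ScenarioSummary:
    """Run all replicates of one scenario and aggregate.

    Per replicate: generate data, find cut-points with each requested method
    and, if ``metrics_on``, evaluate cross-validated performance of the
    induced categorical Cox models.  Replicate failures are recorded and
    tolerated up to ``max_failure_frac`` of the replicates.
    """
    cut_rows, metric_rows, failures = [], [], []
    for rep in range(scenario.reps):
        try:
            data = generate_dataset(scenario, rep)
            results = _apply_methods(data, methods, criterion)
            for m, res in results.items():
                cut_rows.append({
                    "rep": rep, "method": m,
                    "cut1": res.cut1, "cut2": res.cut2,
                    "aic": res.aic, "bic": res.bic,
                })
            if metrics_on:
                for m in methods:
                    rep_seed = int(np.random.default_rng(
                        [scenario.seed, rep, 7]).integers(2**31))
                    report = metrics.crossvalidated_performance(
                        data, m, n_folds=cv_folds, n_repeats=cv_repeats,
                        seed=rep_seed, criterion=criterion,
                    )
                    for meas, val in report.means.items():
                        metric_rows.append({
                            "rep": rep, "method": m,
                            "measure": meas, "value": val,
                        })
        except Exception as exc:  # noqa: BLE001 - replicate failures are recorded
            failures.append((rep, repr(exc)))
            logger.warning("replicate %d failed: %r", rep, exc)
    if len(failures) > max_failure_frac * scenario.reps:
        raise RuntimeError(
            f"{len(failures)}/{scenario.reps} replicates failed; first: {failures[:3]}"
        )
    rep_cuts = pd.DataFrame(cut_rows)
    cut_summary = _summarize_cuts(rep_cuts, methods)
    metrics_long = pd.DataFrame(metric_rows) if metrics_on else None
    return ScenarioSummary(scenario, cut_summary, rep_cuts, metrics_long,
                           n_failures=len(failures), failures=failures)


def _summarize_cuts(rep_cuts: pd.DataFrame, methods) -> pd.DataFrame:
    rows = []
    for m in methods:
        sub = rep_cuts[rep_cuts["method"] == m]
        for j, slot in enumerate(_SLOTS[m]):
            vals = sub["cut1" if j == 0 else "cut2"].dropna().to_numpy(float)
            rows.append({
                "slot": slot,
                "method": m,
                "median": float(np.median(vals)) if vals.size else np.nan,
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "sim_se": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                "n_reps": int(vals.size),
            })
    return pd.DataFrame(rows)


def summarize_tables(summaries: list[ScenarioSummary]):
    """Combine scenario summaries into wide cut-point and long metric tables.

    Returns ``(cutpoints_table, metrics_long)``; the cut-point table has one
    row per (scenario, slot) with median / mean / sim SE columns, matching
    the simulation-table layout.
    """
    if not summaries:
        raise ValueError("no scenario summaries to combine")
    cut_frames, metric_frames = [], []
    for s in summaries:
        tag = _scenario_tag(s.scenario)
        t = s.cut_summary.copy()
        for k, v in tag.items():
            t[k] = v
        cut_frames.append(t)
        if s.metrics_long is not None:
            ml = s.metrics_long.copy()
            for k, v in tag.items():
                ml[k] = v
            metric_frames.append(ml)
    cut_table = pd.concat(cut_frames, ignore_index=True)
    front = ["k1", "k2", "a", "v", "pc", "slot", "method",
             "median", "mean", "sim_se", "n_reps"]
    cut_table = cut_table[front]
    metrics_long = (
        pd.concat(metric_frames, ignore_index=True) if metric_frames else None
    )
    return cut_table, metrics_long


def _scenario_tag(sc: SimulationScenario) -> dict:
    return {"k1": sc.k1, "k2": sc.k2, "a": sc.a, "v": sc.v, "pc": sc.pc}


def boxplot_metrics(metrics_long: pd.DataFrame, out_path, measure_order=None):
    """Boxplots of per-replicate CV performance per method (one panel/measure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measures = measure_order or list(metrics.PerformanceReport.MEASURES)
    fig, axes = plt.subplots(1, len(measures), figsize=(3.2 * len(measures), 3.5))
    if len(measures) == 1:
        axes = [axes]
    for ax, meas in zip(axes, measures):
        sub = metrics_long[metrics_long["measure"] == meas]
        order = [m for m in ALL_METHODS if m in sub["method"].unique()]
        ax.boxplot([sub[sub["method"] == m]["value"] for m in order],
                   tick_labels=order)
        ax.set_title(meas)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
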