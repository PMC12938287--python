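"""End-to-end experiment: simulate -> transfer entropy -> networks -> summary.

Reproduces the full condition grid (stimulus levels x aging presets x
replicates) at configurable scale.  Every run gets a distinct seed derived
from the plan's base seed, each condition's TE matrices feed one pooled edge
criterion, and per-replicate networks yield F/M ratios.  The master table
and all intermediate artefacts are written as plain CSV/TSV/GraphML so that
every reported number can be recomputed from the archive.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import engine, infoflow, networks
from .params import SimulationParams, aging_preset, save_config


class ExperimentPlan(BaseModel):
    """Condition grid and scale of one experiment."""

    stimuli: list[float] = Field(default=[0.0, 0.2, 0.4, 0.8])
    presets: list[str] = Field(default=["N", "A1", "A2"])
    replicates: int = Field(default=10, ge=1)
    base_seed: int = 0
    grid_rows: int = Field(default=100, ge=1)
    grid_cols: int = Field(default=100, ge=1)
    n_iterations: int = Field(default=1000, ge=1)
    bin_count: int = Field(default=infoflow.DEFAULT_BIN_COUNT, ge=2)
    min_samples: int = Field(default=infoflow.DEFAULT_MIN_SAMPLES, ge=1)

    def params_for(self, preset: str, stimulus: float, seed: int) -> SimulationParams:
        return SimulationParams(
            grid_rows=self.grid_rows, grid_cols=self.grid_cols,
            n_iterations=self.n_iterations, stimulus=stimulus,
            aging=aging_preset(preset), seed=seed,
        )


def condition_label(preset: str, stimulus: float) -> str:
    return f"{preset}_S{stimulus:g}"


def run_condition(
    plan: ExperimentPlan, preset: str, stimulus: float, base_seed: int
):
    """Simulate one condition's replicates and analyse them.

    Returns (results, te_matrices, summary-or-None); the summary is None
    when the condition yields too few defined TE values for a criterion
    (e.g. S = 0 with immobility-free but uncoordinated dynamics is fine, but
    a degenerate tiny run may not be).
    """
    params = plan.params_for(preset, stimulus, base_seed)
    results = engine.run_replicates(params, plan.replicates, base_seed)
    te_mats = [
        infoflow.pairwise_te(r.tracks, bin_count=plan.bin_count,
                             min_samples=plan.min_samples)
        for r in results
    ]
    pooled = np.concatenate([tm.defined_values() for tm in te_mats])
    summary = networks.condition_summary(te_mats) if pooled.size >= 4 else None
    return results, te_mats, summary


def run_experiment(plan: ExperimentPlan, out_dir) -> pd.DataFrame:
    """Run every condition of the plan and write the experiment archive.

    Archive layout: one sub-directory per condition holding per-replicate
    run archives, TE matrices, networks (GraphML + edge TSV) and a
    condition summary; plus a machine-readable ``master_table.csv`` with one
    row per (condition, replicate).  A failed condition is recorded in
    ``errors.csv`` and the remaining conditions proceed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, errors = [], []
    run_index = 0
    for preset in plan.presets:
        for stimulus in plan.stimuli:
            label = condition_label(preset, stimulus)
            cond_seed = plan.base_seed + run_index
            run_index += plan.replicates
            cond_dir = out / label
            try:
                results, te_mats, summary = run_condition(plan, preset, stimulus, cond_seed)
                cond_dir.mkdir(parents=True, exist_ok=True)
                save_config(results[0].params, cond_dir / "config.yaml")
                for rep, (res, tm) in enumerate(zip(results, te_mats)):
                    rep_dir = cond_dir / f"rep{rep}"
                    engine.save_result(res, rep_dir)
                    tm.to_frame().to_csv(rep_dir / "te_matrix.csv")
                if summary is not None:
                    _write_summary(summary, cond_dir)
                for rep, (res, tm) in enumerate(zip(results, te_mats)):
                    defined = tm.defined_values()
                    rows.append({
                        "condition": label,
                        "preset": preset,
                        "stimulus": stimulus,
                        "replicate": rep,
                        "seed": res.seed,
                        "final_score": int(res.inflammation_score[-1]),
                        "max_score": int(res.inflammation_score.max()),
                        "mean_te": float(defined.mean()) if defined.size else np.nan,
                        "n_defined_te": int(defined.size),
                        "fm_ratio": float(summary.fm_ratios[rep]) if summary else np.nan,
                    })
            except Exception as exc:  # noqa: BLE001 — per-condition isolation
                errors.append({"condition": label, "error": repr(exc)})
    master = pd.DataFrame(rows)
    master.to_csv(out / "master_table.csv", index=False)
    if errors:
        pd.DataFrame(errors).to_csv(out / "errors.csv", index=False)
    return master


def _write_summary(summary: networks.ConditionSummary, cond_dir: Path) -> None:
    for rep, net in enumerate(summary.networks):
        networks.write_graphml(net, cond_dir / f"rep{rep}" / "network.graphml")
        networks.write_edgelist(net, cond_dir / f"rep{rep}" / "edges.tsv")
    pd.DataFrame({
        "metric": ["criterion_lower", "criterion_upper", "criterion_mode",
                   "mean_fm", "fm_stderr"],
        "value": [summary.criterion.lower, summary.criterion.upper,
                  summary.criterion.mode, summary.mean_fm, summary.fm_stderr],
    }).to_csv(cond_dir / "summary.csv", index=False)
    pd.DataFrame({
        "part": (["macrophage"] * len(summary.macrophage_betweenness)
                 + ["fibroblast"] * len(summary.fibroblast_betweenness)),
        "betweenness": np.concatenate([summary.macrophage_betweenness,
                                       summary.fibroblast_betweenness]),
    }).to_csv(cond_dir / "betweenness.csv", index=False)


def report(archive_dir) -> str:
    """Render a text summary of an experiment archive.

    Tables: inflammation-score course endpoints (mean +/- standard error over
    replicates), mean TE per condition, and F/M per condition.  Every number
    is recomputed from ``master_table.csv``; missing conditions are listed.
    """
    archive = Path(archive_dir)
    master_path = archive / "master_table.csv"
    lines = ["# Experiment report", ""]
    if not master_path.exists() or master_path.stat().st_size == 0:
        return "\n".join(lines + ["WARNING: archive has no master table (empty archive)"])
    master = pd.read_csv(master_path)
    if master.empty:
        return "\n".join(lines + ["WARNING: master table is empty"])

    def se(x):
        x = x.dropna()
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    grouped = master.groupby("condition")
    summary = grouped.agg(
        replicates=("replicate", "count"),
        final_score_mean=("final_score", "mean"),
        final_score_se=("final_score", se),
        max_score_mean=("max_score", "mean"),
        mean_te=("mean_te", "mean"),
        fm_mean=("fm_ratio", "mean"),
        fm_se=("fm_ratio", se),
    ).reset_index()
    lines.append(summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    errors_path = archive / "errors.csv"
    if errors_path.exists():
        lines += ["", "## Failed conditions", pd.read_csv(errors_path).to_string(index=False)]
    return "\n".join(lines)
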