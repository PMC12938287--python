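"""Simulation orchestration: full runs, replicates, tracks and time courses.

One run initialises an all-alive epithelium, places the motile cells on
distinct random sites and (at iteration 0) activates each macrophage with
probability S.  Every iteration then updates agents one at a time in a fresh
random permutation (activation trial, cytokine synthesis, chemotactic
movement), updates the epithelium, advances both cytokine fields, and ages /
repopulates the motile populations.  The run records per-iteration cell
positions (the track table consumed by the information-flow stage), the
inflammation score (dead epithelial site count), grid-mean TNF and TGF, and
the Shannon entropy of the macrophage configuration.

Identical parameters and seed give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fields, infoflow
from .agents import (
    FIBROBLAST,
    MACROPHAGE,
    EpithelialLattice,
    MotileCell,
    Slot,
    chemotaxis_move,
    lifecycle_and_repopulate,
    moore_max,
    synthesise_tgf,
    synthesise_tnf,
    try_activate_fibroblast,
    try_activate_macrophage,
    update_epithelium,
)
from .params import SimulationParams, validate

TRACK_COLUMNS = ["t", "slot_id", "kind", "segment", "row", "col"]


@dataclass
class SimulationResult:
    """Everything one run produces.

    ``tracks`` holds one row per living motile cell per iteration with
    columns (t, slot_id, kind, segment, row, col); ``inflammation_score`` has
    length n_iterations + 1 with score 0 at t = 0.
    """

    tracks: pd.DataFrame
    inflammation_score: np.ndarray
    mean_tnf: np.ndarray
    mean_tgf: np.ndarray
    macrophage_entropy: np.ndarray
    params: SimulationParams
    seed: int
    final_tnf: np.ndarray
    final_tgf: np.ndarray
    final_epithelium: EpithelialLattice


def inflammation_score(lattice: EpithelialLattice) -> int:
    """Number of dead epithelial sites (the injury readout)."""
    return int((lattice.state == 0).sum())


def run(params: SimulationParams) -> SimulationResult:
    """Execute one full simulation with the given parameters."""
    params = validate(params)
    rng = np.random.default_rng(params.seed)
    rows, cols = params.grid_rows, params.grid_cols
    aging = params.aging

    tnf = np.zeros((rows, cols))
    tgf = np.zeros((rows, cols))
    lattice = EpithelialLattice.all_alive((rows, cols))
    occupied = np.zeros((rows, cols), dtype=bool)

    n_cells = params.n_macrophages + params.n_fibroblasts
    sites = rng.choice(rows * cols, size=n_cells, replace=False)
    slots: list[Slot] = []
    for i, flat in enumerate(sites):
        kind = MACROPHAGE if i < params.n_macrophages else FIBROBLAST
        slot_id = i if kind == MACROPHAGE else i - params.n_macrophages
        r, c = divmod(int(flat), cols)
        occupied[r, c] = True
        slots.append(Slot(kind=kind, slot_id=slot_id,
                          cell=MotileCell(kind=kind, slot_id=slot_id, row=r, col=c,
                                          lifespan=params.cell_lifetime)))

    # iteration 0: mechanical stimulus biases initial macrophage activation
    for slot in slots:
        if slot.kind == MACROPHAGE:
            try_activate_macrophage(slot.cell, params.stimulus, 0.0, rng, iteration=0)

    n_iter = params.n_iterations
    score = np.zeros(n_iter + 1, dtype=np.int64)
    mean_tnf = np.zeros(n_iter + 1)
    mean_tgf = np.zeros(n_iter + 1)
    entropy = np.zeros(n_iter + 1)
    col_t: list[int] = []
    col_slot: list[int] = []
    col_kind: list[str] = []
    col_seg: list[int] = []
    col_row: list[int] = []
    col_col: list[int] = []

    def record(t: int) -> None:
        mac_positions = []
        for slot in slots:
            cell = slot.cell
            if cell is None:
                continue
            col_t.append(t)
            col_slot.append(slot.slot_id)
            col_kind.append(slot.kind)
            col_seg.append(slot.segment)
            col_row.append(cell.row)
            col_col.append(cell.col)
            if slot.kind == MACROPHAGE:
                mac_positions.append((cell.row, cell.col))
        score[t] = inflammation_score(lattice)
        mean_tnf[t] = tnf.mean()
        mean_tgf[t] = tgf.mean()
        entropy[t] = infoflow.shannon_entropy(mac_positions)

    record(0)

    for t in range(1, n_iter + 1):
        for idx in rng.permutation(len(slots)):
            slot = slots[idx]
            cell = slot.cell
            if cell is None:
                continue
            if cell.kind == MACROPHAGE:
                if not cell.activated:
                    try_activate_macrophage(
                        cell, params.stimulus, moore_max(tnf, cell.row, cell.col),
                        rng, iteration=t,
                    )
                if cell.activated:
                    tnf[cell.row, cell.col] += synthesise_tnf(
                        cell, tgf[cell.row, cell.col], aging, rng
                    )
                bias = tnf
            else:
                if not cell.activated:
                    try_activate_fibroblast(
                        cell, moore_max(tnf, cell.row, cell.col), rng
                    )
                if cell.activated:
                    tgf[cell.row, cell.col] += synthesise_tgf(
                        cell, tnf[cell.row, cell.col], aging, rng
                    )
                bias = tgf
            if cell.mobile:
                chemotaxis_move(cell, bias, occupied, params.cell_velocity, rng,
                                params.chemotaxis_temperature)

        update_epithelium(lattice, tnf, tgf, aging, rng)
        tnf = fields.step_array(tnf, params.tnf)
        tgf = fields.step_array(tgf, params.tgf)
        lifecycle_and_repopulate(slots, params.repopulation_interval, t, occupied,
                                 rng, params.cell_lifetime)
        record(t)

    tracks = pd.DataFrame({
        "t": np.asarray(col_t, dtype=np.int32),
        "slot_id": np.asarray(col_slot, dtype=np.int32),
        "kind": pd.Categorical(col_kind, categories=[MACROPHAGE, FIBROBLAST]),
        "segment": np.asarray(col_seg, dtype=np.int32),
        "row": np.asarray(col_row, dtype=np.int32),
        "col": np.asarray(col_col, dtype=np.int32),
    })
    return SimulationResult(
        tracks=tracks,
        inflammation_score=score,
        mean_tnf=mean_tnf,
        mean_tgf=mean_tgf,
        macrophage_entropy=entropy,
        params=params,
        seed=params.seed,
        final_tnf=tnf,
        final_tgf=tgf,
        final_epithelium=lattice,
    )


def run_replicates(
    params: SimulationParams, n_replicates: int, base_seed: int
) -> list[SimulationResult]:
    """Run *n_replicates* independent simulations seeded base_seed + i."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    results = []
    for i in range(n_replicates):
        rep = params.model_copy(update={"seed": base_seed + i})
        results.append(run(rep))
    return results


def save_result(result: SimulationResult, out_dir) -> Path:
    """Write a run archive: config, tracks, time courses and final fields."""
    from .params import save_config

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(result.params, out / "config.yaml")
    result.tracks.to_csv(out / "tracks.csv", index=False)
    pd.DataFrame({
        "t": np.arange(len(result.inflammation_score)),
        "score": result.inflammation_score,
        "mean_tnf": result.mean_tnf,
        "mean_tgf": result.mean_tgf,
        "macrophage_entropy": result.macrophage_entropy,
    }).to_csv(out / "scores.csv", index=False)
    np.savetxt(out / "final_tnf.csv", result.final_tnf, delimiter=",")
    np.savetxt(out / "final_tgf.csv", result.final_tgf, delimiter=",")
    np.savetxt(out / "final_epithelium.csv", result.final_epithelium.state,
               delimiter=",", fmt="%d")
    return out


def load_tracks(path) -> pd.DataFrame:
    """Read a track table written by :func:`save_result` (or any CSV with the
    same header)."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table is missing columns {missing}")
    return df[TRACK_COLUMNS]
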