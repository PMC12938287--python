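"""Agent rules: activation, cytokine synthesis, chemotaxis and the epithelium.

Two motile cell kinds walk the lattice.  Macrophages are activated by the
mechanical stimulus S at the start of a run and thereafter by local TNF; once
activated they synthesise TNF (gated by a Beta draw against local TGF) and
remain mobile.  Fibroblasts are activated by local TNF; on activation they
stop migrating, their remaining lifespan drops to 25%, and they synthesise
TGF (gated by a Beta draw against local TNF).  Both kinds perform a biased
random walk: macrophages toward TNF, fibroblasts toward TGF, with collision
avoidance in the Moore neighbourhood.

Epithelial lattice sites die when Moore-neighbourhood TNF exceeds the
apoptosis threshold, accumulate a healing clock under TGF exposure, regrow
with the mitosis probability once the healing time has elapsed (seeding a
fibrosis site in the neighbourhood), and die with probability Nc/9 near
fibrosis, where Nc counts fibrosis sites in the 3x3 block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .params import AgingParams

MACROPHAGE = "macrophage"
FIBROBLAST = "fibroblast"

_MOORE = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_ONES3 = np.ones((3, 3))


@dataclass
class MotileCell:
    """State of one motile agent."""

    kind: str
    slot_id: int
    row: int
    col: int
    lifespan: int
    activated: bool = False
    age: int = 0
    mobile: bool = True


@dataclass
class Slot:
    """A stable population index: a sequence of disjoint cell lifetimes.

    When a cell dies its slot is refilled (at the next repopulation interval)
    by a fresh cell of the same kind; ``segment`` counts these lifetimes so
    that a slot's track is never treated as one continuous path.
    """

    kind: str
    slot_id: int
    cell: Optional[MotileCell]
    segment: int = 0


@dataclass
class EpithelialLattice:
    """Tissue state: alive/dead map, fibrosis counters, healing clocks."""

    state: np.ndarray          # int8: 1 = alive, 0 = dead
    fibrosis: np.ndarray       # int32: remaining fibrosis iterations (0 = none)
    healing_clock: np.ndarray  # int32: accumulated TGF-exposure iterations

    @classmethod
    def all_alive(cls, shape: tuple[int, int]) -> "EpithelialLattice":
        return cls(
            state=np.ones(shape, dtype=np.int8),
            fibrosis=np.zeros(shape, dtype=np.int32),
            healing_clock=np.zeros(shape, dtype=np.int32),
        )


def _conc(field) -> np.ndarray:
    """Accept either a CytokineField or a raw array."""
    return getattr(field, "concentrations", field)


def moore_max(arr: np.ndarray, row: int, col: int) -> float:
    """Maximum over the 3x3 Moore block around a site, clipped to the grid."""
    return float(arr[max(0, row - 1): row + 2, max(0, col - 1): col + 2].max())


def try_activate_macrophage(
    cell: MotileCell,
    stimulus: float,
    local_tnf: float,
    rng: np.random.Generator,
    iteration: int = 0,
) -> MotileCell:
    """Bernoulli activation trial for an unactivated macrophage.

    At iteration 0 the success probability is the mechanical stimulus S;
    thereafter it is min(1, local TNF) so that activation is biased toward
    cytokine-rich neighbourhoods.  Activated macrophages stay mobile.
    """
    prob = stimulus if iteration == 0 else min(1.0, local_tnf)
    if rng.random() < prob:
        cell.activated = True
    return cell


def try_activate_fibroblast(
    cell: MotileCell, local_tnf: float, rng: np.random.Generator
) -> MotileCell:
    """Bernoulli activation trial for an unactivated fibroblast.

    Success probability min(1, local TNF).  On activation the cell settles
    (mobile = False) and its remaining lifespan is cut to 25%.
    """
    if rng.random() < min(1.0, local_tnf):
        cell.activated = True
        cell.mobile = False
        remaining = cell.lifespan - cell.age
        cell.lifespan = cell.age + remaining // 4
    return cell


def synthesise_tnf(
    cell: MotileCell, local_tgf: float, aging: AgingParams, rng: np.random.Generator
) -> float:
    """TNF released by an activated macrophage this iteration (0 or 1).

    A draw u ~ Beta(alpha3, beta3) releases one unit iff u >= local TGF, so
    TGF inhibits TNF synthesis.
    """
    u = rng.beta(aging.tnf_synth_alpha, aging.tnf_synth_beta)
    return 1.0 if u >= local_tgf else 0.0


def synthesise_tgf(
    cell: MotileCell, local_tnf: float, aging: AgingParams, rng: np.random.Generator
) -> float:
    """TGF released by an activated fibroblast this iteration (0 or 1).

    A draw u ~ Beta(alpha4, beta4) releases one unit iff u <= local TNF, so
    TNF promotes TGF synthesis.
    """
    u = rng.beta(aging.tgf_synth_alpha, aging.tgf_synth_beta)
    return 1.0 if u <= local_tnf else 0.0


def chemotaxis_move(
    cell: MotileCell,
    field,
    occupied: np.ndarray,
    velocity: int,
    rng: np.random.Generator,
    temperature: float = 1.0,
) -> tuple[int, int]:
    """Biased random walk: *velocity* single-site Moore sub-steps.

    Each sub-step considers the cell's own site plus the unoccupied in-bounds
    Moore neighbours, and samples one with probability proportional to
    exp(concentration / temperature) (softmax).  When all candidate
    concentrations are equal — in particular on a zero field — this is a
    uniform choice, i.e. a pure random walk.  A fully enclosed cell simply
    stays put.  The occupancy grid is updated between sub-steps.
    """
    conc = _conc(field)
    rows, cols = conc.shape
    for _ in range(velocity):
        r, c = cell.row, cell.col
        cand = [(r, c)]
        for dr, dc in _MOORE:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and not occupied[rr, cc]:
                cand.append((rr, cc))
        weights = np.array([conc[rr, cc] for rr, cc in cand])
        weights = np.exp((weights - weights.max()) / temperature)
        cum = np.cumsum(weights)
        i = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        nr, nc = cand[i]
        occupied[r, c] = False
        occupied[nr, nc] = True
        cell.row, cell.col = nr, nc
    return cell.row, cell.col


def update_epithelium(
    lattice: EpithelialLattice,
    tnf,
    tgf,
    aging: AgingParams,
    rng: np.random.Generator,
) -> EpithelialLattice:
    """One iteration of epithelial dynamics, in place.

    (a) apoptosis: alive sites whose Moore-neighbourhood TNF maximum exceeds
    the apoptosis threshold die; (b) healing: dead sites exposed to TGF in
    their neighbourhood accumulate a healing clock, and once it reaches the
    healing time they regrow with the mitosis probability per iteration,
    seeding one fibrosis site (counter = fibrosis duration) at a random Moore
    neighbour; (c) collagen damage: alive sites near fibrosis die with
    probability Nc/9 where Nc counts fibrosis sites in their 3x3 block;
    fibrosis counters then decrement.
    """
    tnf_arr, tgf_arr = _conc(tnf), _conc(tgf)
    shape = lattice.state.shape
    if tnf_arr.shape != shape or tgf_arr.shape != shape:
        raise ValueError("cytokine fields and epithelial lattice must share one grid shape")

    # (a) apoptosis
    tnf_max = ndimage.maximum_filter(tnf_arr, size=3, mode="constant", cval=0.0)
    apoptose = (lattice.state == 1) & (tnf_max > aging.apoptosis_threshold)
    lattice.state[apoptose] = 0
    lattice.healing_clock[apoptose] = 0

    # (b) healing
    dead = lattice.state == 0
    if dead.any():
        tgf_present = ndimage.maximum_filter(tgf_arr, size=3, mode="constant", cval=0.0) > 0
        lattice.healing_clock[dead & tgf_present] += 1
        ready = dead & (lattice.healing_clock >= aging.healing_time)
        if ready.any():
            heal = ready & (rng.random(shape) < aging.mitosis_prob)
            if heal.any():
                lattice.state[heal] = 1
                lattice.healing_clock[heal] = 0
                rows, cols = shape
                for r, c in np.argwhere(heal):
                    nbrs = [
                        (r + dr, c + dc)
                        for dr, dc in _MOORE
                        if 0 <= r + dr < rows and 0 <= c + dc < cols
                    ]
                    rr, cc = nbrs[int(rng.integers(len(nbrs)))]
                    lattice.fibrosis[rr, cc] = aging.fibrosis_duration

    # (c) collagen damage near fibrosis
    fib = lattice.fibrosis > 0
    if fib.any():
        nc = ndimage.correlate(fib.astype(float), _ONES3, mode="constant", cval=0.0)
        kill = (lattice.state == 1) & (rng.random(shape) < nc / 9.0)
        lattice.state[kill] = 0
        lattice.healing_clock[kill] = 0
        lattice.fibrosis[fib] -= 1

    return lattice


def lifecycle_and_repopulate(
    slots: list[Slot],
    interval: int,
    iteration: int,
    occupied: np.ndarray,
    rng: np.random.Generator,
    cell_lifetime: int,
) -> list[Slot]:
    """Age every cell, remove expired ones, refill empty slots periodically.

    Cells whose age reaches their lifespan are removed and their site freed.
    At every multiple of *interval* iterations, empty slots receive a fresh
    unactivated cell of the slot's kind at a uniformly random unoccupied
    site; the slot's segment counter is bumped so tracks are not bridged
    across lifetimes.  If the grid has too few free sites the refill is
    deferred to the next interval.
    """
    for slot in slots:
        cell = slot.cell
        if cell is None:
            continue
        cell.age += 1
        if cell.age >= cell.lifespan:
            occupied[cell.row, cell.col] = False
            slot.cell = None

    if iteration % interval == 0:
        empty = [s for s in slots if s.cell is None]
        if empty:
            free = np.flatnonzero(~occupied.ravel())
            n_fill = min(len(empty), len(free))
            if n_fill:
                picks = rng.choice(free, size=n_fill, replace=False)
                cols = occupied.shape[1]
                for slot, flat in zip(empty[:n_fill], picks):
                    r, c = divmod(int(flat), cols)
                    slot.segment += 1
                    slot.cell = MotileCell(
                        kind=slot.kind, slot_id=slot.slot_id, row=r, col=c,
                        lifespan=cell_lifetime,
                    )
                    occupied[r, c] = True
    return slots
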