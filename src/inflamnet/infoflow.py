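"""Information-flow estimation from cell migration tracks.

The raw signal is the turning angle of a motile cell: the signed angle
between its consecutive displacement vectors, mapped to [0, 2*pi).  Angles
are discretised into equal bins (20 by default, bin width pi/10) and treated
as symbol series.  Shannon entropy, mutual information, conditional mutual
information and transfer entropy are plain plug-in (histogram) estimates in
bits; no bias correction is applied.

Transfer entropy from a source series Y to a target series X is

    T(Y -> X) = I(X_t ; Y_{t-1} | X_{t-1})

estimated over (X_t, X_{t-1}, Y_{t-1}) triples.  The pipeline's macrophage
-> fibroblast quantity uses the macrophage angle series as source and the
fibroblast series as target, so it measures how much a macrophage's past
direction reduces uncertainty about a fibroblast's next direction beyond the
fibroblast's own past.  Both directions are computable by swapping the
arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import FIBROBLAST, MACROPHAGE

TWO_PI = 2.0 * np.pi

#: Default number of angle bins (bin width pi/10).
DEFAULT_BIN_COUNT = 20
#: Minimum number of (X_t, X_{t-1}, Y_{t-1}) triples below which a pairwise
#: transfer entropy is reported as missing (NaN) rather than as a number.
DEFAULT_MIN_SAMPLES = 50


@dataclass
class AngleSeries:
    """Turning angles of one cell slot, with their iteration indices."""

    slot_id: int
    kind: str
    iterations: np.ndarray  # iteration at which each angle is defined
    values: np.ndarray      # angles in [0, 2*pi)

    def __len__(self) -> int:
        return len(self.values)


def turning_angles(
    positions,
    iterations=None,
    slot_id: int = -1,
    kind: str = "",
) -> AngleSeries:
    """Signed turning angles along one lifetime segment of a track.

    The angle at iteration t is the counter-clockwise rotation from the
    displacement ending at t-1 to the displacement ending at t, mapped to
    [0, 2*pi).  It is defined only where both displacements come from
    consecutive iterations and are nonzero; zero-displacement (resting)
    steps are skipped.  Fewer than three positions give an empty series.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or (len(pos) and pos.shape[1] != 2):
        raise ValueError("positions must be an (n, 2) array")
    n = len(pos)
    it = np.arange(n) if iterations is None else np.asarray(iterations, dtype=int)
    if len(it) != n:
        raise ValueError("iterations must align with positions")
    if n < 3:
        return AngleSeries(slot_id, kind, np.empty(0, dtype=int), np.empty(0))

    disp = pos[1:] - pos[:-1]
    step_ok = (it[1:] - it[:-1] == 1) & (disp != 0).any(axis=1)
    prev, curr = disp[:-1], disp[1:]
    ok = step_ok[:-1] & step_ok[1:]
    cross = prev[:, 0] * curr[:, 1] - prev[:, 1] * curr[:, 0]
    dot = (prev * curr).sum(axis=1)
    theta = np.mod(np.arctan2(cross, dot), TWO_PI)
    return AngleSeries(slot_id, kind, it[2:][ok], theta[ok])


def discretise(values, bin_count: int = DEFAULT_BIN_COUNT) -> np.ndarray:
    """Map angles in [0, 2*pi] to integer symbols in [0, bin_count).

    Equal-width bins of 2*pi / bin_count; the right edge 2*pi falls in the
    last bin.
    """
    if bin_count < 2:
        raise ValueError("bin_count must be >= 2")
    vals = np.asarray(getattr(values, "values", values), dtype=float)
    width = TWO_PI / bin_count
    return np.minimum((vals / width).astype(int), bin_count - 1)


def bin_width(bin_count: int = DEFAULT_BIN_COUNT) -> float:
    """Width of one angle bin in radians (pi/10 for the default 20 bins)."""
    return TWO_PI / bin_count


def shannon_entropy(positions, block_size: int = 10) -> float:
    """Shannon entropy (bits) of a cell configuration over grid blocks.

    The grid is partitioned into block_size x block_size blocks and the
    entropy of the block-occupancy fractions is returned.  All cells in one
    block give 0 bits; an even spread over B blocks gives log2(B) bits.
    """
    pos = np.asarray(positions, dtype=int)
    if pos.size == 0:
        return 0.0
    blocks = pos // block_size
    _, counts = np.unique(blocks, axis=0, return_counts=True)
    return _entropy_bits(counts)


def zscore(series) -> np.ndarray:
    """Standardise a series to mean 0, (population) standard deviation 1."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant series (sigma = 0)")
    return (x - x.mean()) / sd


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _check_aligned(*series) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(s, dtype=int) for s in series]
    lengths = {len(a) for a in arrs}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(len(a) for a in arrs)}")
    return tuple(arrs)


def _code(*arrs: np.ndarray) -> np.ndarray:
    """Pack aligned symbol arrays into one joint code per sample."""
    code = arrs[0].astype(np.int64).copy()
    for a in arrs[1:]:
        code *= int(a.max()) + 1
        code += a
    return code


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X;Y) = H(X) + H(Y) - H(X,Y), in bits."""
    x, y = _check_aligned(x, y)
    if len(x) == 0:
        raise ValueError("empty series")
    hx = _entropy_bits(np.bincount(x))
    hy = _entropy_bits(np.bincount(y))
    hxy = _entropy_bits(np.bincount(_code(x, y)))
    return hx + hy - hxy


def conditional_mutual_information(x, y, z) -> float:
    """Plug-in conditional mutual information I(X;Y|Z), in bits.

    Computed as H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z), which equals the
    z-weighted average of I(X;Y | Z=z) for the empirical distribution; it is
    non-negative up to floating error.
    """
    x, y, z = _check_aligned(x, y, z)
    if len(x) == 0:
        raise ValueError("empty series")
    hxz = _entropy_bits(np.bincount(_code(x, z)))
    hyz = _entropy_bits(np.bincount(_code(y, z)))
    hxyz = _entropy_bits(np.bincount(_code(x, y, z)))
    hz = _entropy_bits(np.bincount(z))
    return hxz + hyz - hxyz - hz


def transfer_entropy(source, target, min_samples: int = DEFAULT_MIN_SAMPLES) -> float:
    """Plug-in transfer entropy T(source -> target) in bits.

    Builds (target_t, target_{t-1}, source_{t-1}) triples from two aligned
    symbol series and returns I(target_t ; source_{t-1} | target_{t-1}).
    With fewer than *min_samples* triples the estimate is unreliable and NaN
    is returned (a missing-value flag, not an error).
    """
    source, target = _check_aligned(source, target)
    if len(target) - 1 < min_samples:
        return float("nan")
    return conditional_mutual_information(target[1:], source[:-1], target[:-1])


@dataclass
class TEMatrix:
    """Pairwise macrophage -> fibroblast transfer entropies for one run.

    ``values[i, j]`` is T(macrophage slot i -> fibroblast slot j) in bits,
    NaN where the pair had fewer aligned triples than the minimum sample
    count; ``counts`` holds the triple counts.
    """

    values: np.ndarray
    counts: np.ndarray
    macrophage_slots: np.ndarray
    fibroblast_slots: np.ndarray
    bin_count: int

    def defined_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.macrophage_slots, name="macrophage_slot"),
                            columns=pd.Index(self.fibroblast_slots, name="fibroblast_slot"))


def _symbols_by_iteration(
    tracks: pd.DataFrame, kind: str, bin_count: int, n_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-slot symbol and segment arrays indexed by iteration (-1 = undefined)."""
    sub = tracks[tracks["kind"] == kind]
    slot_ids = np.sort(sub["slot_id"].unique())
    index = {s: i for i, s in enumerate(slot_ids)}
    sym = np.full((len(slot_ids), n_iter + 1), -1, dtype=np.int32)
    seg = np.full((len(slot_ids), n_iter + 1), -1, dtype=np.int32)
    for (slot, segment), g in sub.groupby(["slot_id", "segment"], observed=True):
        g = g.sort_values("t")
        series = turning_angles(
            g[["row", "col"]].to_numpy(), g["t"].to_numpy(), slot_id=int(slot), kind=kind
        )
        if len(series) == 0:
            continue
        codes = discretise(series.values, bin_count)
        i = index[slot]
        sym[i, series.iterations] = codes
        seg[i, series.iterations] = segment
    return slot_ids, sym, seg


def angle_table(tracks: pd.DataFrame, bin_count: int = DEFAULT_BIN_COUNT) -> pd.DataFrame:
    """Long-format turning-angle table (kind, slot_id, segment, t, angle, symbol)."""
    records = []
    for (kind, slot, segment), g in tracks.groupby(["kind", "slot_id", "segment"],
                                                   observed=True):
        g = g.sort_values("t")
        series = turning_angles(g[["row", "col"]].to_numpy(), g["t"].to_numpy(),
                                slot_id=int(slot), kind=str(kind))
        if len(series) == 0:
            continue
        codes = discretise(series.values, bin_count)
        for t, theta, sym in zip(series.iterations, series.values, codes):
            records.append((str(kind), int(slot), int(segment), int(t),
                            float(theta), int(sym)))
    return pd.DataFrame(records,
                        columns=["kind", "slot_id", "segment", "t", "angle", "symbol"])


def pairwise_te(
    tracks: pd.DataFrame,
    bin_count: int = DEFAULT_BIN_COUNT,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> TEMatrix:
    """Transfer entropy from every macrophage slot to every fibroblast slot.

    For each pair the two angle series are aligned on common iterations;
    triples (F_t, F_{t-1}, M_{t-1}) are pooled across lifetime segments
    (never bridging a segment boundary within the target's pair of
    consecutive angles) and fed to the plug-in estimator.  Pairs with fewer
    than *min_samples* triples are reported missing (NaN).
    """
    n_iter = int(tracks["t"].max())
    m_slots, m_sym, _ = _symbols_by_iteration(tracks, MACROPHAGE, bin_count, n_iter)
    f_slots, f_sym, f_seg = _symbols_by_iteration(tracks, FIBROBLAST, bin_count, n_iter)

    values = np.full((len(m_slots), len(f_slots)), np.nan)
    counts = np.zeros((len(m_slots), len(f_slots)), dtype=np.int64)
    f_t, f_tm1 = f_sym[:, 1:], f_sym[:, :-1]
    f_same_seg = f_seg[:, 1:] == f_seg[:, :-1]
    m_tm1 = m_sym[:, :-1]

    for j in range(len(f_slots)):
        f_ok = (f_t[j] >= 0) & (f_tm1[j] >= 0) & f_same_seg[j]
        if not f_ok.any():
            continue
        for i in range(len(m_slots)):
            ok = f_ok & (m_tm1[i] >= 0)
            n = int(ok.sum())
            counts[i, j] = n
            if n >= min_samples:
                values[i, j] = conditional_mutual_information(
                    f_t[j][ok], m_tm1[i][ok], f_tm1[j][ok]
                )
    return TEMatrix(values=values, counts=counts, macrophage_slots=m_slots,
                    fibroblast_slots=f_slots, bin_count=bin_count)
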