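"""Discrete reaction-diffusion dynamics of the cytokine fields.

Each cytokine species (TNF, TGF) lives on the simulation lattice as a field
of non-negative concentrations evolving by

    dphi/dt = D * laplacian(phi) - K * phi

integrated with explicit forward Euler (dt = 1, dx = 1) and the standard
5-point Laplacian.  Boundaries are no-flux (reflecting): ghost cells copy the
edge value, so diffusion alone conserves total mass.  Decay is applied after
the diffusion half-update; the ordering is a convention with an O(D*K)
effect.  Under the stability bound D <= 1/4 the update preserves
non-negativity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CytokineParams


@dataclass
class CytokineField:
    """A 2-D lattice of non-negative concentrations for one cytokine."""

    concentrations: np.ndarray
    species: str = "TNF"

    def __post_init__(self) -> None:
        arr = np.asarray(self.concentrations, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"concentrations must be 2-D, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("concentrations must be non-negative")
        self.concentrations = arr

    @classmethod
    def zeros(cls, shape: tuple[int, int], species: str = "TNF") -> "CytokineField":
        return cls(np.zeros(shape, dtype=float), species=species)

    @property
    def shape(self) -> tuple[int, int]:
        return self.concentrations.shape


def _laplacian_noflux(arr: np.ndarray) -> np.ndarray:
    # 5-point stencil with edge-replicated ghost cells (no-flux boundary).
    padded = np.pad(arr, 1, mode="edge")
    return (
        padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]
        - 4.0 * arr
    )


def step_array(arr: np.ndarray, params: CytokineParams) -> np.ndarray:
    """One explicit-Euler reaction-diffusion update on a raw array."""
    out = arr + params.diffusion_const * _laplacian_noflux(arr)
    out *= 1.0 - params.degradation_const
    return out


def step(field: CytokineField, params: CytokineParams) -> CytokineField:
    """Advance *field* by one iteration; returns a new field.

    Diffusion (5-point Laplacian, no-flux boundaries) followed by first-order
    decay.  All entries remain non-negative under the stability bound, which
    :class:`~inflamnet.params.CytokineParams` enforces at construction.
    """
    return CytokineField(step_array(field.concentrations, params), species=field.species)


def deposit(field: CytokineField, row: int, col: int, amount: float) -> CytokineField:
    """Add *amount* of cytokine at one lattice site, in place.

    Returns the same field for chaining.  Out-of-bounds indices raise
    ``IndexError`` (negative indices are rejected rather than wrapped).
    """
    rows, cols = field.shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise IndexError(f"site ({row}, {col}) outside {rows}x{cols} grid")
    if amount <= 0:
        raise ValueError("deposit amount must be positive")
    field.concentrations[row, col] += amount
    return field


def total_mass(field: CytokineField) -> float:
    """Sum of all concentrations (conserved by diffusion when K = 0)."""
    return float(field.concentrations.sum())
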