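"""Model parameters, aging presets and run configuration.

The simulator is parameterised by three blocks:

* :class:`AgingParams` — the constants that change between the Normal (``N``)
  and the two inflammaging presets (``A1``, ``A2``): the Beta-distribution
  parameters gating cytokine synthesis, the epithelial apoptosis threshold,
  the mitosis (regrowth) probability, the healing time and the fibrosis
  duration.
* :class:`CytokineParams` — diffusion and first-order degradation constants
  of one cytokine species.
* :class:`SimulationParams` — everything needed for a full run: grid shape,
  iteration count, mechanical stimulus ``S``, the aging block, the two
  cytokine blocks, motile-cell population settings and the RNG seed.

All validation lives here so the engine can assume well-formed input.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

PresetName = Literal["N", "A1", "A2"]

#: Explicit forward-Euler stability bound for the 5-point Laplacian with
#: dt = 1 and dx = 1: D must not exceed 1/4.
STABILITY_BOUND = 0.25


class AgingParams(BaseModel):
    """Aging-condition parameter block.

    The three presets encode progressively severe inflammaging: TNF synthesis
    is encouraged (higher alpha/beta ratio of the synthesis gate), epithelial
    cells apoptose at lower TNF, regeneration slows (lower mitosis
    probability, longer healing time) and fibrosis persists longer.
    """

    model_config = ConfigDict(frozen=True)

    tnf_synth_alpha: float = Field(gt=0, description="alpha of the Beta gate for TNF synthesis")
    tnf_synth_beta: float = Field(gt=0, description="beta of the Beta gate for TNF synthesis")
    tgf_synth_alpha: float = Field(default=2.0, gt=0, description="alpha of the Beta gate for TGF synthesis")
    tgf_synth_beta: float = Field(default=1.0, gt=0, description="beta of the Beta gate for TGF synthesis")
    apoptosis_threshold: float = Field(gt=0, le=1, description="TNF level above which epithelial cells die")
    mitosis_prob: float = Field(ge=0, le=1, description="per-iteration regrowth probability once healing time has elapsed")
    healing_time: int = Field(ge=1, description="iterations of TGF exposure required before regrowth (th)")
    fibrosis_duration: int = Field(ge=1, description="lifetime of a fibrosis site in iterations (Kc)")
    collagen_damage_rule: str = Field(
        default="moore_count/9",
        description="descriptor of the collagen damage probability: Nc/9 with Nc "
        "the number of fibrosis sites in the 3x3 Moore block",
    )


_PRESETS: dict[str, dict[str, float | int]] = {
    "N": dict(tnf_synth_alpha=1.0, tnf_synth_beta=3.0, apoptosis_threshold=0.8,
              mitosis_prob=0.20, healing_time=5, fibrosis_duration=50),
    "A1": dict(tnf_synth_alpha=1.2, tnf_synth_beta=2.5, apoptosis_threshold=0.6,
               mitosis_prob=0.16, healing_time=6, fibrosis_duration=75),
    "A2": dict(tnf_synth_alpha=1.5, tnf_synth_beta=2.0, apoptosis_threshold=0.4,
               mitosis_prob=0.10, healing_time=8, fibrosis_duration=100),
}


def aging_preset(name: str) -> AgingParams:
    """Return the parameter block for one of the named aging conditions.

    Parameters
    ----------
    name
        ``"N"`` (normal), ``"A1"`` or ``"A2"`` (progressively severe aging).

    Raises
    ------
    ValueError
        If *name* is not one of the three preset labels.
    """
    try:
        values = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown aging preset {name!r}; expected one of {sorted(_PRESETS)}"
        ) from None
    return AgingParams(**values)


class CytokineParams(BaseModel):
    """Diffusion/degradation constants for one cytokine species."""

    model_config = ConfigDict(frozen=True)

    diffusion_const: float = Field(ge=0, description="diffusion constant D (lattice units^2 per iteration)")
    degradation_const: float = Field(ge=0, description="first-order degradation constant K (per iteration)")

    @model_validator(mode="after")
    def _stable(self) -> "CytokineParams":
        if self.diffusion_const > STABILITY_BOUND:
            raise ValueError(
                f"diffusion_const={self.diffusion_const} violates the explicit-scheme "
                f"stability bound D*dt <= {STABILITY_BOUND} (dt = 1)"
            )
        if self.degradation_const > 1:
            raise ValueError("degradation_const must not exceed 1 (concentrations would go negative)")
        return self


class SimulationParams(BaseModel):
    """Complete configuration of one simulation run.

    Defaults follow the study conditions: 20 macrophages and 20 fibroblasts
    with lifetime 20 iterations, velocity 3 sites/iteration and repopulation
    every 5 iterations; TNF diffuses with D=0.07, K=1e-3 and TGF with D=0.10,
    K=1e-5.  Grid size and run length are configurable (100x100 and 1000 by
    default — large enough that 40 agents at velocity 3 do not saturate the
    grid).
    """

    grid_rows: int = Field(default=100, ge=1)
    grid_cols: int = Field(default=100, ge=1)
    n_iterations: int = Field(default=1000, ge=1)
    stimulus: float = Field(default=0.0, ge=0, le=1, description="mechanical stimulus S in [0, 1]")
    aging: AgingParams = Field(default_factory=lambda: aging_preset("N"))
    tnf: CytokineParams = Field(default_factory=lambda: CytokineParams(diffusion_const=0.07, degradation_const=1e-3))
    tgf: CytokineParams = Field(default_factory=lambda: CytokineParams(diffusion_const=0.10, degradation_const=1e-5))
    n_macrophages: int = Field(default=20, ge=1)
    n_fibroblasts: int = Field(default=20, ge=1)
    cell_lifetime: int = Field(default=20, ge=1, description="motile-cell lifetime tim in iterations")
    cell_velocity: int = Field(default=3, ge=1, description="Moore sub-steps per iteration")
    repopulation_interval: int = Field(default=5, ge=1, description="iterations between population refills")
    chemotaxis_temperature: float = Field(default=1.0, gt=0, description="softmax temperature of the chemotactic bias")
    seed: int = 0

    @model_validator(mode="after")
    def _consistent(self) -> "SimulationParams":
        n_sites = self.grid_rows * self.grid_cols
        n_cells = self.n_macrophages + self.n_fibroblasts
        if n_cells >= n_sites:
            raise ValueError(
                f"n_macrophages + n_fibroblasts = {n_cells} must be smaller than the "
                f"grid ({self.grid_rows}x{self.grid_cols} = {n_sites} sites)"
            )
        for label, cyt in (("tnf", self.tnf), ("tgf", self.tgf)):
            if cyt.degradation_const > cyt.diffusion_const:
                raise ValueError(
                    f"{label}: degradation_const ({cyt.degradation_const}) exceeds "
                    f"diffusion_const ({cyt.diffusion_const}); D >= K is required"
                )
        return self


def validate(params: SimulationParams) -> SimulationParams:
    """Re-run full validation on *params* and return them unchanged.

    Raises a :class:`pydantic.ValidationError` naming the offending field if
    any invariant is violated.
    """
    return SimulationParams.model_validate(params.model_dump())


def to_yaml(params: SimulationParams) -> str:
    """Serialise *params* to a YAML document (round-trips exactly)."""
    return yaml.safe_dump(params.model_dump(), sort_keys=True)


def from_yaml(text: str) -> SimulationParams:
    """Parse a YAML document produced by :func:`to_yaml`."""
    return SimulationParams.model_validate(yaml.safe_load(text))


def save_config(params: SimulationParams, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_yaml(params))


def load_config(path) -> SimulationParams:
    with open(path) as fh:
        return from_yaml(fh.read())
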