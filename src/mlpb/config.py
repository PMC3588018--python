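"""Run configuration: user-unit parameter blocks, validation, presets.

Configs are YAML key-value documents mirroring the model and solver options
in laboratory units (K, nm^2, nm, Debye, mol/l).  Unknown keys are rejected
by name, values are range-checked on load, and every missing field falls
back to the DPPC gel-phase defaults, so an empty file is a complete,
runnable configuration.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .parameters import ModelParameters
from .solver import SolverOptions

__all__ = ["ParameterBlock", "SolverBlock", "OutputBlock", "RunConfig", "load_config", "PRESETS"]


class ParameterBlock(BaseModel):
    """Physical parameters in user units (defaults: DPPC gel phase)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    t_kelvin: float = Field(default=310.0, gt=0)
    a0_nm2: float = Field(default=0.48, gt=0)
    d_nm: float = Field(default=0.42, gt=0)
    p0_debye: float = Field(default=3.1, gt=0)
    salt_mol_l: float = Field(default=0.1, ge=0)
    water_mol_l: float = Field(default=55.0, gt=0)
    n_refr: float = Field(default=1.33, ge=1)
    alpha: float | None = Field(default=None, gt=0)
    l_nm: float = Field(default=12.0, gt=0)

    @field_validator("t_kelvin")
    @classmethod
    def _plausible_temperature(cls, v: float) -> float:
        if v < 200.0:
            warnings.warn(
                f"temperature {v} K is below any liquid-water regime; "
                "results are extrapolations",
                stacklevel=2,
            )
        return v

    @field_validator("l_nm")
    @classmethod
    def _domain_vs_headgroup(cls, v: float) -> float:
        return v

    def to_model_parameters(self) -> ModelParameters:
        return ModelParameters.from_user_units(
            T=self.t_kelvin,
            a0_nm2=self.a0_nm2,
            d_nm=self.d_nm,
            p0_debye=self.p0_debye,
            salt_mol_l=self.salt_mol_l,
            water_mol_l=self.water_mol_l,
            n_refr=self.n_refr,
            alpha=self.alpha,
            l_nm=self.l_nm,
        )


class SolverBlock(BaseModel):
    """Solver options (see :class:`mlpb.solver.SolverOptions`)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    max_outer_iterations: int = Field(default=10_000, ge=1)
    damping: float = Field(default=0.25, gt=0, le=1)
    tolerance_v: float = Field(default=1e-9, gt=0)
    n_nodes: int = Field(default=4000, ge=100)

    def to_solver_options(self, **overrides) -> SolverOptions:
        return SolverOptions(
            max_outer_iterations=self.max_outer_iterations,
            damping=self.damping,
            tolerance=self.tolerance_v,
            **overrides,
        )


class OutputBlock(BaseModel):
    """Where and what to write."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    directory: str = "."
    profiles: bool = True
    summary: bool = True


class RunConfig(BaseModel):
    """Complete, validated run configuration in user units."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    parameters: ParameterBlock = ParameterBlock()
    solver: SolverBlock = SolverBlock()
    output: OutputBlock = OutputBlock()
    sweep_t_kelvin: list[float] | None = None
    alphas: list[float] | None = None


#: Named parameter sets for one-command reproduction of the model results.
PRESETS: dict[str, ParameterBlock] = {
    "dppc-gel": ParameterBlock(t_kelvin=310.0, a0_nm2=0.48),
    "dppc-liquid": ParameterBlock(t_kelvin=323.0, a0_nm2=0.60),
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty document yields the full DPPC gel default set.  Unknown keys
    are rejected with the offending key named; out-of-range values raise
    validation errors (implausible but legal values only warn).
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.model_validate(raw)
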