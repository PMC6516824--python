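"""Run configuration: a flat, schema-validated parameter record.

One JSON file (or CLI flag set) fully determines a run.  Unknown keys are
rejected, defaults are filled eagerly, and every run writes its fully
resolved configuration next to its outputs so that any result can be
reproduced from the artefacts alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .kinetics import KineticRates, SolverOptions
from .phase import PhaseSeparationSpec, monomer_partition_coefficient

__all__ = ["RunConfig", "load_config", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"


class RunConfig(BaseModel):
    """Flat key-value configuration for a simulation or sweep run.

    Either ``gamma`` (direct monomer partition coefficient) or
    ``delta_chi`` (from which Gamma is derived via the chemical-potential
    balance) must be given for two-compartment models.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # phase-separation geometry
    phi_I: float = 1.0
    phi_II: float = 0.0
    phi_bar: float = 0.1
    delta_chi: Optional[float] = None
    nu_ratio: float = 1.0
    gamma: Optional[float] = None

    # kinetics
    c_tot: float = 1.0
    k1: float = 1e-4
    n1: float = 2.0
    k2: float = 1.0
    n2: float = 2.0
    k_plus: float = 0.5
    k_exchange: float = 0.0

    # model selection and solver
    model: Literal["finite-k", "quasi-equilibrium", "homogeneous"] = "quasi-equilibrium"
    t_end: Optional[float] = None  # None: 500 / kappa
    rtol: float = 1e-8
    atol_factor: float = 1e-12
    n_points: int = Field(default=400, ge=10)
    plateau_tol: float = 1e-3

    # sweep grids (None: module defaults)
    sweep_phi_bar: Optional[list[float]] = None
    sweep_gamma: Optional[list[float]] = None
    sweep_n_phi_bar: int = Field(default=20, ge=1)
    sweep_n_gamma: int = Field(default=20, ge=1)

    # asymptotic-prediction prefactor
    w: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.model != "homogeneous" and self.gamma is None and self.delta_chi is None:
            raise ValueError("gamma: either gamma or delta_chi must be set for two-compartment models")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma: must be > 0")
        # eager geometry validation via the domain type
        self.phase_spec()
        return self

    # -- derived objects ----------------------------------------------------

    def phase_spec(self) -> PhaseSeparationSpec:
        return PhaseSeparationSpec(
            phi_I=self.phi_I,
            phi_II=self.phi_II,
            phi_bar=self.phi_bar,
            delta_chi=self.delta_chi if self.delta_chi is not None else 0.0,
            nu_ratio=self.nu_ratio,
        )

    def resolved_gamma(self) -> float:
        """Gamma: the direct value when given, else from delta_chi."""
        if self.gamma is not None:
            return self.gamma
        return monomer_partition_coefficient(self.phase_spec())

    def kinetic_rates(self) -> KineticRates:
        return KineticRates(
            k1=self.k1,
            n1=self.n1,
            k2=self.k2,
            n2=self.n2,
            k_plus=self.k_plus,
            k_exchange=self.k_exchange,
        )

    def solver_options(self) -> SolverOptions:
        return SolverOptions(
            rtol=self.rtol, atol_factor=self.atol_factor, n_points=self.n_points
        )

    def resolved_dict(self) -> dict:
        d = self.model_dump()
        d["schema_version"] = SCHEMA_VERSION
        return d

    def write_resolved(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.resolved_dict(), indent=2, sort_keys=True) + "\n")


def load_config(path: Path | str) -> RunConfig:
    """Load and validate a JSON configuration file.

    Accepts both bare configs and the resolved configs written next to run
    outputs (whose ``schema_version`` stamp is checked, then dropped).
    """
    raw = json.loads(Path(path).read_text())
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if str(version) != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version {version!r}")
    return RunConfig.model_validate(raw)
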