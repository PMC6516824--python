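"""Equilibrium monomer partitioning between a condensate and its dilute phase.

A binary mixture of a scaffold component A and a solvent-like component B
demixes into a condensed phase I (volume fraction of A equal to ``phi_I``)
and a dilute phase II (``phi_II``).  Aggregation-prone monomers are dilute
clients of this two-phase system: they partition between the phases
according to the relative interaction strength ``delta_chi`` (in units of
kB*T) between the monomer and the A/B components, but are too dilute to
shift the coexisting compositions themselves.

Balancing the monomer chemical potentials across the interface gives the
monomer partition coefficient

    Gamma = c_m^I / c_m^II = exp[ (nu_m/nu) * delta_chi * (phi_I - phi_II) ],

so partitioning grows exponentially with both the interaction strength and
the degree of phase separation ``phi_I - phi_II``, and vanishes (Gamma = 1)
at the critical point where the compositions merge.

The compartment volume follows from the lever rule,
V_I/V = (phi_bar - phi_II)/(phi_I - phi_II), and the partition degree

    xi = 1 / (1 + (Gamma - 1) * V_I/V)

relates the dilute-phase monomer concentration to the total monomer pool:
c_m^II = xi * c_tot and c_m^I = xi * Gamma * c_tot.  For Gamma > 1, xi
decreases from 1 (vanishingly small compartment) to 1/Gamma (the
compartment fills the system).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateSystemError, SpecValidationError

__all__ = [
    "PhaseSeparationSpec",
    "monomer_partition_coefficient",
    "compartment_volume_fraction",
    "partition_degree",
    "split_monomer_pool",
    "symmetric_binodal",
]


@dataclass(frozen=True)
class PhaseSeparationSpec:
    """Thermodynamic state of the two-phase (condensate / dilute) system.

    Parameters
    ----------
    phi_I, phi_II :
        Volume fractions of the A component in the condensed phase I and the
        dilute phase II.  ``phi_I > phi_II`` for a true two-phase system;
        equality is allowed only as the homogeneous reference case.
    phi_bar :
        Mean volume fraction of A in the whole system; together with the
        coexisting compositions it sets the compartment volume by the
        lever rule.
    delta_chi :
        Relative monomer interaction strength (units of kB*T).  Positive
        values favour the condensate.
    nu_ratio :
        Ratio of monomer molecular volume to the A/B molecular volume.
    total_volume :
        System volume V (arbitrary units, default 1).

    Coexisting compositions are direct inputs; no binodal is solved (see
    :func:`symmetric_binodal` for an optional helper).
    """

    phi_I: float
    phi_II: float
    phi_bar: float
    delta_chi: float
    nu_ratio: float = 1.0
    total_volume: float = 1.0

    def __post_init__(self) -> None:
        for name in ("phi_I", "phi_II", "phi_bar", "delta_chi", "nu_ratio", "total_volume"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise SpecValidationError(name, f"must be finite, got {v!r}")
        if not 0.0 <= self.phi_II <= 1.0:
            raise SpecValidationError("phi_II", f"must lie in [0, 1], got {self.phi_II}")
        if not 0.0 <= self.phi_I <= 1.0:
            raise SpecValidationError("phi_I", f"must lie in [0, 1], got {self.phi_I}")
        if self.phi_I < self.phi_II:
            raise SpecValidationError(
                "phi_I", f"must be >= phi_II ({self.phi_II}), got {self.phi_I}"
            )
        if not self.phi_II <= self.phi_bar <= self.phi_I:
            raise SpecValidationError(
                "phi_bar",
                f"must lie in [phi_II, phi_I] = [{self.phi_II}, {self.phi_I}], got {self.phi_bar}",
            )
        if not self.total_volume > 0:
            raise SpecValidationError("total_volume", f"must be > 0, got {self.total_volume}")

    @property
    def is_homogeneous(self) -> bool:
        """True for the degenerate reference case phi_I == phi_II."""
        return self.phi_I == self.phi_II

    @property
    def separation_degree(self) -> float:
        """Degree of phase separation phi_I - phi_II, in [0, 1]."""
        return self.phi_I - self.phi_II


def monomer_partition_coefficient(spec: PhaseSeparationSpec) -> float:
    """Equilibrium monomer partition coefficient Gamma = c_m^I / c_m^II.

    Gamma = exp[nu_ratio * delta_chi * (phi_I - phi_II)].  Gamma > 1 iff
    delta_chi * (phi_I - phi_II) > 0; at the critical point
    (phi_I == phi_II) partitioning vanishes and Gamma = 1.
    """
    return math.exp(spec.nu_ratio * spec.delta_chi * spec.separation_degree)


def compartment_volume_fraction(spec: PhaseSeparationSpec) -> float:
    """Relative compartment volume V_I/V from the lever rule.

    V_I/V = (phi_bar - phi_II) / (phi_I - phi_II); 0 when the mean
    composition sits on the dilute branch and 1 on the condensed branch.

    Raises
    ------
    DegenerateSystemError
        If phi_I == phi_II (no interface); use the homogeneous reference
        path (``simulate_homogeneous``) instead.
    """
    if spec.is_homogeneous:
        raise DegenerateSystemError(
            "phi_I == phi_II: no compartment exists; use the homogeneous "
            "reference (simulate_homogeneous) instead"
        )
    return (spec.phi_bar - spec.phi_II) / (spec.phi_I - spec.phi_II)


def partition_degree(gamma: float, vI_frac: float) -> float:
    """Partition degree xi = c_m^II / c_tot = 1 / (1 + (Gamma-1) V_I/V).

    Lies between min(1, 1/Gamma) and max(1, 1/Gamma); strictly decreasing
    in ``vI_frac`` when Gamma > 1 and identically 1 when Gamma = 1.
    """
    if not gamma > 0:
        raise SpecValidationError("gamma", f"must be > 0, got {gamma}")
    if not 0.0 <= vI_frac <= 1.0:
        raise SpecValidationError("vI_frac", f"must lie in [0, 1], got {vI_frac}")
    return 1.0 / (1.0 + (gamma - 1.0) * vI_frac)


def split_monomer_pool(c_tot: float, gamma: float, xi: float) -> tuple[float, float]:
    """Split the total monomer concentration between the phases.

    Returns ``(c_m_I, c_m_II) = (xi*Gamma*c_tot, xi*c_tot)``.  With the xi
    produced by :func:`partition_degree` the volume-weighted mean
    reconstructs ``c_tot`` exactly.
    """
    if c_tot < 0:
        raise SpecValidationError("c_tot", f"must be >= 0, got {c_tot}")
    return xi * gamma * c_tot, xi * c_tot


def symmetric_binodal(chi: float) -> tuple[float, float]:
    """Coexisting compositions of a symmetric regular-solution mixture.

    Optional convenience: for an A/B interaction parameter ``chi > 2``
    (units of kB*T) solves ln[phi/(1-phi)] = chi*(2*phi - 1) for the
    condensed branch and returns ``(phi_I, phi_II)`` with
    ``phi_II = 1 - phi_I``.  This is plumbing for users who want coexisting
    compositions from a single interaction parameter; the library otherwise
    treats phi_I, phi_II as direct inputs.
    """
    from scipy.optimize import brentq

    if chi <= 2.0:
        raise SpecValidationError("chi", f"must exceed 2 (critical point), got {chi}")

    def g(phi: float) -> float:
        return math.log(phi / (1.0 - phi)) - chi * (2.0 * phi - 1.0)

    # condensed branch lies in (1/2, 1); bracket away from the fixed point 1/2
    phi_I = brentq(g, 0.5 + 1e-12, 1.0 - 1e-15, xtol=1e-15, rtol=8.9e-16)
    return phi_I, 1.0 - phi_I
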