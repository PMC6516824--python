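"""Closed-form scaling laws for long-time aggregate partitioning.

For strong monomer partitioning (large Gamma) the long-time aggregate
number concentrations in the two phases, relative to the homogeneous
reference ca_hom, obey the asymptotic forms

    c_a^I(inf)  / ca_hom  ~  (xi * Gamma)^((n2+1)/2)           (enrichment)
    c_a^II(inf) / ca_hom  ~  (1/w) * xi^((n1-n2+1)/2) * Gamma^(-(n2+1)/2)

where ``w`` is a dimensionless prefactor of order one that cannot be fixed
by the scaling argument; it is exposed as a user parameter (default 1,
see :func:`calibrate_w`).  Dividing the two gives the asymptotic aggregate
partitioning ratio, up to a constant,

    epsilon = c_a^I(inf)/c_a^II(inf)  ~  xi^(n2-n1+1) * Gamma^(n2+1),

whose dependence on compartment volume enters only through the partition
degree xi.  Since xi decreases with compartment volume, the sign of
d(epsilon)/d(phi_bar) is the sign of n1 - n2 - 1: systems dominated by
primary nucleation (n2 < n1 - 1, e.g. fragmenting systems with n2 = 0)
partition best into large compartments, monomer-dependent secondary
nucleation with n2 > n1 - 1 favours small compartments, and on the line
n2 = n1 - 1 the compartment volume drops out entirely.

All formulas here are proportionalities; they are meant to be consumed as
exponents, ratios and signs (where any prefactor cancels), and double as
independent oracles for the numerical kinetics module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import NoCharacteristicScaleError, SpecValidationError
from .kinetics import AsymptoticReadout

__all__ = [
    "ScalingPrediction",
    "enrichment_ratio",
    "depletion_ratio",
    "aggregate_partition_ratio",
    "volume_sensitivity",
    "regime_classify",
    "effective_rate_ratio_exponents",
    "mean_size_scaling",
    "calibrate_w",
    "predict",
]

REGIME_LARGE = "large-compartment-optimal"
REGIME_SMALL = "small-compartment-optimal"
REGIME_FLAT = "volume-independent"


def _check_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise SpecValidationError(name, f"must be > 0, got {v}")


def enrichment_ratio(xi: float, gamma: float, n2: float) -> float:
    """Compartment enrichment c_a^I(inf)/ca_hom ~ (xi*Gamma)^((n2+1)/2)."""
    _check_positive(xi=xi, gamma=gamma)
    return (xi * gamma) ** ((n2 + 1.0) / 2.0)


def depletion_ratio(xi: float, gamma: float, n1: float, n2: float, w: float = 1.0) -> float:
    """Dilute-phase depletion
    c_a^II(inf)/ca_hom ~ (1/w) * xi^((n1-n2+1)/2) * Gamma^(-(n2+1)/2)."""
    _check_positive(xi=xi, gamma=gamma, w=w)
    return xi ** ((n1 - n2 + 1.0) / 2.0) * gamma ** (-(n2 + 1.0) / 2.0) / w


def aggregate_partition_ratio(xi: float, gamma: float, n1: float, n2: float) -> float:
    """Aggregate partitioning ratio epsilon ~ xi^(n2-n1+1) * Gamma^(n2+1)
    (up to a constant prefactor)."""
    _check_positive(xi=xi, gamma=gamma)
    return xi ** (n2 - n1 + 1.0) * gamma ** (n2 + 1.0)


def volume_sensitivity(n1: float, n2: float) -> int:
    """Sign of d(epsilon)/d(phi_bar): sign(n1 - n2 - 1).

    +1: larger compartments increase partitioning; -1: smaller compartments
    do; 0: volume-independent (n2 = n1 - 1).
    """
    d = n1 - n2 - 1.0
    return (d > 0) - (d < 0)


def regime_classify(n1: float, n2: float) -> str:
    """Regime of maximal aggregate partitioning in the (n1, n2) plane.

    The boundary is the line n2 = n1 - 1: above it (n2 > n1 - 1) small
    compartments maximise partitioning, below it large ones do.
    """
    if n1 < 0 or n2 < 0:
        raise SpecValidationError("n1/n2", "reaction orders must be >= 0")
    s = volume_sensitivity(n1, n2)
    return {1: REGIME_LARGE, -1: REGIME_SMALL, 0: REGIME_FLAT}[s]


def effective_rate_ratio_exponents(n1: float, n2: float) -> tuple[float, float]:
    """Exponents of the phase-I/phase-II effective aggregation-rate ratio.

    At early times the ratio scales as Gamma^n1 (primary nucleation sets
    the pace); at late times as Gamma^((n2+1)/2) (secondary processes do).
    Returns ``(n1, (n2+1)/2)``.
    """
    return (n1, (n2 + 1.0) / 2.0)


def mean_size_scaling(k_plus: float, k2: float, m_tot: float, n2: float) -> float:
    """Saturating-regime mean aggregate size, up to a constant:
    sqrt(k_plus/k2) * m_tot^((1-n2)/2).

    Independent of the total monomer mass when n2 = 1, decreasing in it
    when n2 > 1 (more but shorter aggregates).
    """
    if k2 <= 0:
        raise NoCharacteristicScaleError(
            "mean-size scaling requires active secondary nucleation (k2 > 0)"
        )
    _check_positive(m_tot=m_tot)
    return math.sqrt(k_plus / k2) * m_tot ** ((1.0 - n2) / 2.0)


def calibrate_w(
    readout: AsymptoticReadout,
    ca_hom: float,
    xi: float,
    n1: float,
    n2: float,
) -> float:
    """Fit the depletion prefactor w once from a simulation pair.

    Given a converged two-compartment readout and its homogeneous
    reference, inverts the depletion form:
    w = (ca_hom / c_a^II(inf)) * xi^((n1-n2+1)/2) * Gamma^(-(n2+1)/2).
    """
    _check_positive(ca_hom=ca_hom, xi=xi)
    if readout.c_a_II <= 0:
        raise SpecValidationError("c_a_II", "calibration needs c_a_II(inf) > 0")
    gamma = readout.gamma
    return (ca_hom / readout.c_a_II) * xi ** ((n1 - n2 + 1.0) / 2.0) * gamma ** (
        -(n2 + 1.0) / 2.0
    )


@dataclass(frozen=True)
class ScalingPrediction:
    """Bundle of the asymptotic scaling predictions at one (xi, Gamma).

    ``enrichment_I`` and ``depletion_II`` are the predicted ratios to the
    homogeneous aggregate concentration (the latter includes 1/w);
    ``epsilon`` is the partitioning ratio up to its prefactor;
    ``volume_sensitivity_sign`` and ``regime`` encode how epsilon responds
    to compartment volume.
    """

    enrichment_I: float
    depletion_II: float
    epsilon: float
    volume_sensitivity_sign: int
    regime: str
    w: float

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise SpecValidationError("epsilon", "must be > 0")
        expected = {1: REGIME_LARGE, -1: REGIME_SMALL, 0: REGIME_FLAT}[
            self.volume_sensitivity_sign
        ]
        if self.regime != expected:
            raise SpecValidationError(
                "regime", f"{self.regime!r} inconsistent with sign {self.volume_sensitivity_sign}"
            )

    def to_dict(self) -> dict:
        return {
            "enrichment_I": self.enrichment_I,
            "depletion_II": self.depletion_II,
            "epsilon": self.epsilon,
            "volume_sensitivity_sign": self.volume_sensitivity_sign,
            "regime": self.regime,
            "w": self.w,
        }


def predict(xi: float, gamma: float, n1: float, n2: float, w: float = 1.0) -> ScalingPrediction:
    """Evaluate all scaling predictions at one (xi, Gamma, n1, n2)."""
    return ScalingPrediction(
        enrichment_I=enrichment_ratio(xi, gamma, n2),
        depletion_II=depletion_ratio(xi, gamma, n1, n2, w),
        epsilon=aggregate_partition_ratio(xi, gamma, n1, n2),
        volume_sensitivity_sign=volume_sensitivity(n1, n2),
        regime=regime_classify(n1, n2),
        w=w,
    )
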