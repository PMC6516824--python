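"""Two-compartment moment equations for irreversible fibril formation.

The fibril-length distribution is closed at its first two moments: the
aggregate number concentration ``c_a`` and the aggregate mass concentration
``M_a`` (monomer-mass units).  In each phase alpha in {I, II}:

    dc_a/dt = k1 * M_m^n1  +  k2 * M_m^n2 * M_a        (nucleation)
    dM_a/dt = 2 * k_plus * M_m * c_a                   (elongation)
    dM_m/dt = -2 * k_plus * M_m * c_a + J^alpha/V^alpha

Primary nucleation creates aggregates from monomers alone with reaction
order ``n1``; secondary nucleation is aggregate-dependent with monomer
reaction order ``n2`` (``n2 = 0`` is fragmentation).  Elongation adds
monomers at both fibril ends.  The phases are coupled only through the
monomer exchange flux

    J = -k_exchange * (M_m^I - Gamma * M_m^II),   J^I = J,  J^II = -J,

which relaxes the monomer pool back to the partitioning equilibrium
M_m^I = Gamma * M_m^II.  There is no aggregate flux: fibrils stay in the
phase where they nucleated.  Compartment volumes are constant and the total
system volume is normalised to 1, so V^I = vI_frac and V^II = 1 - vI_frac.

Three integration front-ends are provided:

* :func:`simulate` — the full finite-exchange-rate model (6 variables);
* :func:`quasi_equilibrium_simulate` — the fast-exchange limit in which
  M_m^I = Gamma * M_m^II is enforced algebraically (5 variables);
* :func:`simulate_homogeneous` — the single-compartment reference
  (equal phase compositions, Gamma = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    DegenerateSystemError,
    NoCharacteristicScaleError,
    NotConvergedError,
    SolverFailureError,
    SpecValidationError,
)
from .phase import (
    PhaseSeparationSpec,
    compartment_volume_fraction,
    monomer_partition_coefficient,
    partition_degree,
    split_monomer_pool,
)

__all__ = [
    "KineticRates",
    "CompartmentState",
    "SystemState",
    "Trajectory",
    "HomogeneousTrajectory",
    "AsymptoticReadout",
    "SolverOptions",
    "exchange_flux",
    "rhs",
    "simulate",
    "simulate_homogeneous",
    "initial_state_at_partition_equilibrium",
    "quasi_equilibrium_simulate",
    "nondimensionalize",
    "redimensionalize",
    "characteristic_rate",
    "constant_monomer_aggregate_mass",
    "asymptotic_readout",
    "asymptotic_readout_homogeneous",
]

# Relative monomer-exhaustion threshold defining the completion of growth
MONOMER_EXHAUSTION_FRACTION = 1e-6
# Undershoots smaller than this (relative to m_tot) are clipped to zero;
# anything larger aborts the run instead of being masked.
NEGATIVE_CLIP_FRACTION = 1e-14


@dataclass(frozen=True)
class KineticRates:
    """Aggregation rate constants, reaction orders and the exchange rate.

    Units follow the mass-concentration convention (monomer mass set to 1):
    ``k1`` per time per mass-concentration^(n1-1), ``k2`` per time per
    mass-concentration^n2, ``k_plus`` per time per mass-concentration,
    ``k_exchange`` per time.  ``n2 = 0`` encodes monomer-independent
    secondary nucleation (fragmentation).

    ``multipliers_I``/``multipliers_II`` scale (k1, k2, k_plus) per phase;
    the baseline (all 1) assumes both phases share the same reaction rates,
    and deviations implement the sensitivity check on phase-dependent
    aggregation chemistry.
    """

    k1: float
    n1: float
    k2: float
    n2: float
    k_plus: float
    k_exchange: float = 0.0
    multipliers_I: tuple[float, float, float] = (1.0, 1.0, 1.0)
    multipliers_II: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k_plus", "k_exchange"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise SpecValidationError(name, f"must be a finite non-negative rate, got {v!r}")
        for name in ("n1", "n2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise SpecValidationError(name, f"reaction order must be >= 0, got {v!r}")
        for name in ("multipliers_I", "multipliers_II"):
            m = getattr(self, name)
            if len(m) != 3 or any(x < 0 for x in m):
                raise SpecValidationError(name, f"needs 3 non-negative factors, got {m!r}")

    def in_phase(self, phase: str) -> tuple[float, float, float]:
        """Effective (k1, k2, k_plus) in phase ``'I'`` or ``'II'``."""
        m = self.multipliers_I if phase == "I" else self.multipliers_II
        return self.k1 * m[0], self.k2 * m[1], self.k_plus * m[2]


@dataclass(frozen=True)
class CompartmentState:
    """State of one phase: aggregate number ``c_a``, aggregate mass ``M_a``
    and monomer mass ``M_m`` concentrations (monomer-mass units)."""

    c_a: float
    M_a: float
    M_m: float

    def __post_init__(self) -> None:
        for name in ("c_a", "M_a", "M_m"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise SpecValidationError(name, f"must be finite and >= 0, got {v!r}")

    @property
    def mean_aggregate_mass(self) -> float:
        """Average aggregate mass M_a / c_a (requires c_a > 0)."""
        if self.c_a <= 0:
            raise SpecValidationError("c_a", "mean aggregate mass undefined at c_a = 0")
        return self.M_a / self.c_a


@dataclass(frozen=True)
class SystemState:
    """Two-compartment state plus the compartment volume fraction."""

    phase_I: CompartmentState
    phase_II: CompartmentState
    vI_frac: float

    def __post_init__(self) -> None:
        if not 0.0 < self.vI_frac < 1.0:
            raise SpecValidationError(
                "vI_frac", f"must lie strictly in (0, 1) for two-compartment dynamics, got {self.vI_frac}"
            )

    @property
    def total_mass(self) -> float:
        """Volume-weighted total (monomer + aggregate) mass concentration."""
        vI, vII = self.vI_frac, 1.0 - self.vI_frac
        return vI * (self.phase_I.M_m + self.phase_I.M_a) + vII * (
            self.phase_II.M_m + self.phase_II.M_a
        )

    @property
    def total_monomer_mass(self) -> float:
        vI = self.vI_frac
        return vI * self.phase_I.M_m + (1.0 - vI) * self.phase_II.M_m

    def to_array(self) -> np.ndarray:
        p, q = self.phase_I, self.phase_II
        return np.array([p.c_a, p.M_a, p.M_m, q.c_a, q.M_a, q.M_m], dtype=float)


@dataclass
class SolverOptions:
    """Stiff-integrator settings.

    ``rtol`` defaults to 1e-8 and ``atol`` to 1e-12 * m_tot; the positive
    feedback makes the system stiff when k_exchange >> kappa, hence the
    implicit (BDF) default.  Output points are log-spaced (``n_points``,
    default 400) to resolve both the fast exchange transient and the slow
    approach to plateau.
    """

    rtol: float = 1e-8
    atol_factor: float = 1e-12
    n_points: int = 400
    method: str = "BDF"
    first_point_factor: float = 1e-8  # t_eval starts at t_end * this


@dataclass(frozen=True)
class Trajectory:
    """Time course of a two-compartment integration.

    Arrays are aligned with ``times``; ``monomer_exhausted`` records whether
    the run terminated on the monomer-exhaustion criterion (total monomer
    below 1e-6 of its initial value), which defines the completion of
    growth and hence the asymptotic readout point.
    """

    times: np.ndarray
    c_a_I: np.ndarray
    M_a_I: np.ndarray
    M_m_I: np.ndarray
    c_a_II: np.ndarray
    M_a_II: np.ndarray
    M_m_II: np.ndarray
    vI_frac: float
    gamma: float
    conserved_mass: float
    monomer_exhausted: bool
    model: str = "finite-exchange"

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise SpecValidationError("times", "must be strictly increasing")

    @property
    def total_mass(self) -> np.ndarray:
        vI, vII = self.vI_frac, 1.0 - self.vI_frac
        return vI * (self.M_m_I + self.M_a_I) + vII * (self.M_m_II + self.M_a_II)

    @property
    def total_monomer_mass(self) -> np.ndarray:
        vI = self.vI_frac
        return vI * self.M_m_I + (1.0 - vI) * self.M_m_II

    @property
    def mass_residual(self) -> np.ndarray:
        """Relative drift of the conserved volume-weighted total mass."""
        return (self.total_mass - self.conserved_mass) / self.conserved_mass

    def state_at(self, i: int) -> SystemState:
        return SystemState(
            CompartmentState(self.c_a_I[i], self.M_a_I[i], self.M_m_I[i]),
            CompartmentState(self.c_a_II[i], self.M_a_II[i], self.M_m_II[i]),
            self.vI_frac,
        )

    def to_frame(self):
        """Long-format table with the documented trajectory columns."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "c_a_I": self.c_a_I,
                "M_a_I": self.M_a_I,
                "M_m_I": self.M_m_I,
                "c_a_II": self.c_a_II,
                "M_a_II": self.M_a_II,
                "M_m_II": self.M_m_II,
                "mass_residual": self.mass_residual,
            }
        )


@dataclass(frozen=True)
class HomogeneousTrajectory:
    """Time course of the single-compartment reference system."""

    times: np.ndarray
    c_a: np.ndarray
    M_a: np.ndarray
    M_m: np.ndarray
    conserved_mass: float
    monomer_exhausted: bool
    model: str = "homogeneous"

    @property
    def total_mass(self) -> np.ndarray:
        return self.M_m + self.M_a

    @property
    def total_monomer_mass(self) -> np.ndarray:
        return self.M_m

    @property
    def mass_residual(self) -> np.ndarray:
        return (self.total_mass - self.conserved_mass) / self.conserved_mass

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "c_a": self.c_a,
                "M_a": self.M_a,
                "M_m": self.M_m,
                "mass_residual": self.mass_residual,
            }
        )


@dataclass(frozen=True)
class AsymptoticReadout:
    """Plateau (completion-of-growth) values of one integration."""

    c_a_I: float
    M_a_I: float
    c_a_II: float
    M_a_II: float
    vI_frac: float
    gamma: float
    monomer_exhausted: bool
    final_decade_change: float

    @property
    def epsilon(self) -> float:
        """Aggregate partitioning ratio c_a^I(inf) / c_a^II(inf)."""
        return self.c_a_I / self.c_a_II


def exchange_flux(M_m_I: float, M_m_II: float, gamma: float, k_exchange: float) -> float:
    """Monomer exchange flux J = -k*(M_m^I - Gamma*M_m^II).

    Positive J drives monomers into phase I; J vanishes exactly at the
    partitioning equilibrium M_m^I = Gamma * M_m^II.  Sign convention
    J^I = -J^II = J (no aggregation at the interface).
    """
    if M_m_I < 0 or M_m_II < 0:
        raise SpecValidationError("M_m", "monomer masses must be >= 0")
    if not gamma > 0:
        raise SpecValidationError("gamma", f"must be > 0, got {gamma}")
    if k_exchange < 0:
        raise SpecValidationError("k_exchange", f"must be >= 0, got {k_exchange}")
    return -k_exchange * (M_m_I - gamma * M_m_II)


def _rhs_array(y: np.ndarray, rates: KineticRates, gamma: float, vI: float) -> np.ndarray:
    """Right-hand side on the raw state vector
    [c_a_I, M_a_I, M_m_I, c_a_II, M_a_II, M_m_II]."""
    caI, MaI, MmI, caII, MaII, MmII = y
    # powers evaluated on the non-negative part; tiny solver undershoots are
    # checked against the clip threshold after integration
    MmI_p = MmI if MmI > 0 else 0.0
    MmII_p = MmII if MmII > 0 else 0.0

    k1_I, k2_I, kp_I = rates.in_phase("I")
    k1_II, k2_II, kp_II = rates.in_phase("II")

    J = -rates.k_exchange * (MmI - gamma * MmII)

    dcaI = k1_I * MmI_p**rates.n1 + k2_I * MmI_p**rates.n2 * MaI
    dMaI = 2.0 * kp_I * MmI_p * caI
    dMmI = -dMaI + J / vI

    dcaII = k1_II * MmII_p**rates.n1 + k2_II * MmII_p**rates.n2 * MaII
    dMaII = 2.0 * kp_II * MmII_p * caII
    dMmII = -dMaII - J / (1.0 - vI)

    return np.array([dcaI, dMaI, dMmI, dcaII, dMaII, dMmII])


def rhs(state: SystemState, rates: KineticRates, gamma: float) -> np.ndarray:
    """Time derivative of a :class:`SystemState`.

    Returns d/dt of [c_a_I, M_a_I, M_m_I, c_a_II, M_a_II, M_m_II].  The
    volume-weighted sum of the four mass derivatives is zero (the exchange
    flux only moves mass between phases).
    """
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise SolverFailureError("non-finite state passed to rhs")
    return _rhs_array(y, rates, gamma, state.vI_frac)


def characteristic_rate(rates: KineticRates, m_tot: float) -> float:
    """Characteristic aggregation rate.

    kappa = sqrt(2*k_plus*k2*m_tot^(n2+1)) when secondary nucleation is
    active, else the primary-only scale lambda = sqrt(2*k_plus*k1*m_tot^n1).
    """
    if m_tot <= 0:
        raise SpecValidationError("m_tot", f"must be > 0, got {m_tot}")
    if rates.k2 > 0 and rates.k_plus > 0:
        return math.sqrt(2.0 * rates.k_plus * rates.k2 * m_tot ** (rates.n2 + 1.0))
    if rates.k1 > 0 and rates.k_plus > 0:
        return math.sqrt(2.0 * rates.k_plus * rates.k1 * m_tot**rates.n1)
    raise NoCharacteristicScaleError(
        "all nucleation pathways are inactive (k1 = k2 = 0 or k_plus = 0); "
        "no characteristic aggregation time scale exists"
    )


def nondimensionalize(rates: KineticRates, m_tot: float) -> tuple[KineticRates, float]:
    """Rescale rates to units where m_tot = 1 and time is 1/kappa.

    Returns ``(scaled_rates, t_char)`` with ``t_char = 1/kappa`` (or the
    primary-only fallback 1/lambda when k2 = 0).  Round-tripping through
    :func:`redimensionalize` is the identity to machine precision.
    """
    kappa = characteristic_rate(rates, m_tot)
    t_char = 1.0 / kappa
    scaled = replace(
        rates,
        k1=rates.k1 * m_tot ** (rates.n1 - 1.0) / kappa,
        k2=rates.k2 * m_tot**rates.n2 / kappa,
        k_plus=rates.k_plus * m_tot / kappa,
        k_exchange=rates.k_exchange / kappa,
    )
    return scaled, t_char


def redimensionalize(scaled: KineticRates, m_tot: float, t_char: float) -> KineticRates:
    """Inverse of :func:`nondimensionalize`."""
    kappa = 1.0 / t_char
    return replace(
        scaled,
        k1=scaled.k1 * kappa / m_tot ** (scaled.n1 - 1.0),
        k2=scaled.k2 * kappa / m_tot**scaled.n2,
        k_plus=scaled.k_plus * kappa / m_tot,
        k_exchange=scaled.k_exchange * kappa,
    )


def initial_state_at_partition_equilibrium(
    c_tot: float, spec: PhaseSeparationSpec, monomer_mass: float = 1.0
) -> SystemState:
    """Aggregate-free initial state with monomers at partition equilibrium.

    Monomers equilibrate across the interface on the fast diffusive time
    scale before any appreciable aggregation, so the natural initial
    condition has zero aggregates and the monomer pool split according to
    Gamma and the compartment volume.
    """
    gamma = monomer_partition_coefficient(spec)
    vI = compartment_volume_fraction(spec)
    if vI <= 0.0 or vI >= 1.0:
        raise DegenerateSystemError(
            f"compartment volume fraction {vI} leaves a single phase; "
            "use simulate_homogeneous"
        )
    xi = partition_degree(gamma, vI)
    c_m_I, c_m_II = split_monomer_pool(c_tot, gamma, xi)
    return SystemState(
        CompartmentState(0.0, 0.0, c_m_I * monomer_mass),
        CompartmentState(0.0, 0.0, c_m_II * monomer_mass),
        vI,
    )


def _log_t_eval(t_end: float, options: SolverOptions) -> np.ndarray:
    t0 = t_end * options.first_point_factor
    grid = np.geomspace(t0, t_end, options.n_points - 1)
    return np.concatenate(([0.0], grid))


def _run_ivp(fun, y0, t_end, m_ref, monomer_index_weights, options: SolverOptions):
    """Shared solve_ivp driver with monomer-exhaustion termination.

    ``monomer_index_weights``: list of (index, volume weight) defining the
    volume-weighted total monomer mass in the state vector.
    """
    mu0 = sum(w * y0[i] for i, w in monomer_index_weights)
    threshold = MONOMER_EXHAUSTION_FRACTION * mu0 if mu0 > 0 else -1.0

    def exhausted(t, y):
        return sum(w * y[i] for i, w in monomer_index_weights) - threshold

    exhausted.terminal = True
    exhausted.direction = -1

    sol = solve_ivp(
        fun,
        (0.0, t_end),
        y0,
        method=options.method,
        t_eval=_log_t_eval(t_end, options),
        rtol=options.rtol,
        atol=options.atol_factor * max(m_ref, 1e-300),
        events=[exhausted] if mu0 > 0 else None,
        dense_output=False,
    )
    if not sol.success:
        raise SolverFailureError(f"stiff solver failed: {sol.message}", t_fail=sol.t[-1] if len(sol.t) else None)

    t, y = sol.t, sol.y
    hit = sol.status == 1
    if hit and sol.t_events[0].size:
        # append the event point so the readout sits exactly at exhaustion
        te = sol.t_events[0][0]
        if te > t[-1]:
            t = np.append(t, te)
            y = np.hstack([y, sol.y_events[0][0][:, None]])

    # negative-concentration guard: clip only numerical dust, abort otherwise
    floor = -NEGATIVE_CLIP_FRACTION * m_ref
    if y.min() < floor:
        i_bad = np.unravel_index(np.argmin(y), y.shape)
        raise SolverFailureError(
            f"state variable {i_bad[0]} undershot zero by more than the clip "
            f"threshold ({y.min():.3e}); tighten tolerances or rescale",
            t_fail=float(t[i_bad[1]]),
        )
    y = np.clip(y, 0.0, None)
    if not np.all(np.isfinite(y)):
        raise SolverFailureError("non-finite values in solution")
    return t, y, hit


def simulate(
    initial: SystemState,
    rates: KineticRates,
    gamma: float,
    t_end: float,
    solver_options: SolverOptions | None = None,
) -> Trajectory:
    """Integrate the finite-exchange-rate two-compartment model.

    Terminates early (flagged on the returned trajectory) once the
    volume-weighted total monomer mass falls below 1e-6 of its initial
    value — the completion of the growth phase at which asymptotic
    quantities are read out.
    """
    if not gamma > 0:
        raise SpecValidationError("gamma", f"must be > 0, got {gamma}")
    if not t_end > 0:
        raise SpecValidationError("t_end", f"must be > 0, got {t_end}")
    options = solver_options or SolverOptions()
    vI = initial.vI_frac
    y0 = initial.to_array()
    m_tot = initial.total_mass

    def fun(t, y):
        return _rhs_array(y, rates, gamma, vI)

    t, y, hit = _run_ivp(
        fun, y0, t_end, m_tot, [(2, vI), (5, 1.0 - vI)], options
    )
    drop0 = t[0] == 0.0 and t.size > 1
    sl = slice(1, None) if drop0 else slice(None)
    return Trajectory(
        times=t[sl],
        c_a_I=y[0, sl],
        M_a_I=y[1, sl],
        M_m_I=y[2, sl],
        c_a_II=y[3, sl],
        M_a_II=y[4, sl],
        M_m_II=y[5, sl],
        vI_frac=vI,
        gamma=gamma,
        conserved_mass=m_tot,
        monomer_exhausted=hit,
        model="finite-exchange",
    )


def quasi_equilibrium_simulate(
    initial: SystemState,
    rates: KineticRates,
    gamma: float,
    t_end: float,
    solver_options: SolverOptions | None = None,
) -> Trajectory:
    """Integrate the fast-exchange (quasi-equilibrium) reduced model.

    The monomer pool is slaved to the partitioning equilibrium,
    M_m^I = Gamma * M_m^II, at every instant; the reduced state is
    (c_a^I, M_a^I, c_a^II, M_a^II, mu) with mu the volume-weighted total
    monomer mass.  This is the k_exchange -> infinity limit of
    :func:`simulate`.
    """
    if not gamma > 0:
        raise SpecValidationError("gamma", f"must be > 0, got {gamma}")
    if not t_end > 0:
        raise SpecValidationError("t_end", f"must be > 0, got {t_end}")
    options = solver_options or SolverOptions()
    vI = initial.vI_frac
    xi_v = partition_degree(gamma, vI)  # M_m^II = xi_v * mu, M_m^I = Gamma * xi_v * mu
    mu0 = initial.total_monomer_mass
    m_tot = initial.total_mass
    y0 = np.array(
        [initial.phase_I.c_a, initial.phase_I.M_a, initial.phase_II.c_a, initial.phase_II.M_a, mu0]
    )

    k1_I, k2_I, kp_I = rates.in_phase("I")
    k1_II, k2_II, kp_II = rates.in_phase("II")
    n1, n2 = rates.n1, rates.n2

    def fun(t, y):
        caI, MaI, caII, MaII, mu = y
        mu_p = mu if mu > 0 else 0.0
        MmII = xi_v * mu_p
        MmI = gamma * MmII
        dcaI = k1_I * MmI**n1 + k2_I * MmI**n2 * MaI
        dMaI = 2.0 * kp_I * MmI * caI
        dcaII = k1_II * MmII**n1 + k2_II * MmII**n2 * MaII
        dMaII = 2.0 * kp_II * MmII * caII
        dmu = -(vI * dMaI + (1.0 - vI) * dMaII)
        return np.array([dcaI, dMaI, dcaII, dMaII, dmu])

    t, y, hit = _run_ivp(fun, y0, t_end, m_tot, [(4, 1.0)], options)
    drop0 = t[0] == 0.0 and t.size > 1
    sl = slice(1, None) if drop0 else slice(None)
    mu = y[4, sl]
    MmII = xi_v * mu
    return Trajectory(
        times=t[sl],
        c_a_I=y[0, sl],
        M_a_I=y[1, sl],
        M_m_I=gamma * MmII,
        c_a_II=y[2, sl],
        M_a_II=y[3, sl],
        M_m_II=MmII,
        vI_frac=vI,
        gamma=gamma,
        conserved_mass=m_tot,
        monomer_exhausted=hit,
        model="quasi-equilibrium",
    )


def simulate_homogeneous(
    c_tot: float,
    rates: KineticRates,
    t_end: float,
    solver_options: SolverOptions | None = None,
    monomer_mass: float = 1.0,
    freeze_monomer: bool = False,
) -> HomogeneousTrajectory:
    """Integrate the homogeneous (single-compartment) reference system.

    This is the equal-composition case phi_I = phi_II (Gamma = 1), against
    which enrichment and depletion are measured.  With
    ``freeze_monomer=True`` monomer depletion is switched off
    (dM_m/dt = 0), which linearises the moment equations; the aggregate
    mass then follows the closed form of
    :func:`constant_monomer_aggregate_mass`.
    """
    if c_tot < 0:
        raise SpecValidationError("c_tot", f"must be >= 0, got {c_tot}")
    if not t_end > 0:
        raise SpecValidationError("t_end", f"must be > 0, got {t_end}")
    options = solver_options or SolverOptions()
    m0 = c_tot * monomer_mass
    y0 = np.array([0.0, 0.0, m0])
    k1, n1, k2, n2, kp = rates.k1, rates.n1, rates.k2, rates.n2, rates.k_plus

    def fun(t, y):
        ca, Ma, Mm = y
        Mm_p = Mm if Mm > 0 else 0.0
        dca = k1 * Mm_p**n1 + k2 * Mm_p**n2 * Ma
        dMa = 2.0 * kp * Mm_p * ca
        dMm = 0.0 if freeze_monomer else -dMa
        return np.array([dca, dMa, dMm])

    monomer_weights = [] if freeze_monomer else [(2, 1.0)]
    if m0 == 0.0:
        monomer_weights = []
    t, y, hit = _run_ivp(fun, y0, t_end, max(m0, 1.0), monomer_weights or [(2, 0.0)], options)
    drop0 = t[0] == 0.0 and t.size > 1
    sl = slice(1, None) if drop0 else slice(None)
    return HomogeneousTrajectory(
        times=t[sl],
        c_a=y[0, sl],
        M_a=y[1, sl],
        M_m=y[2, sl],
        conserved_mass=m0 if m0 > 0 else 1.0,
        monomer_exhausted=hit,
    )


def constant_monomer_aggregate_mass(
    t: np.ndarray | float, rates: KineticRates, M_m: float
) -> np.ndarray | float:
    """Closed-form aggregate mass at fixed monomer concentration.

    With monomer depletion frozen the moment equations linearise to
    d^2 M_a/dt^2 = alpha + kappa^2 * M_a with
    alpha = 2*k_plus*k1*M_m^(n1+1) and kappa^2 = 2*k_plus*k2*M_m^(n2+1),
    giving M_a(t) = (alpha/kappa^2) * (cosh(kappa*t) - 1) from an
    aggregate-free start.
    """
    alpha = 2.0 * rates.k_plus * rates.k1 * M_m ** (rates.n1 + 1.0)
    kappa2 = 2.0 * rates.k_plus * rates.k2 * M_m ** (rates.n2 + 1.0)
    if kappa2 <= 0:
        # pure primary nucleation: M_a = alpha * t^2 / 2
        return alpha * np.asarray(t, dtype=float) ** 2 / 2.0
    kappa = math.sqrt(kappa2)
    return (alpha / kappa2) * (np.cosh(kappa * np.asarray(t, dtype=float)) - 1.0)


def _final_decade_change(times: np.ndarray, values: np.ndarray) -> float:
    """Relative change of ``values`` over the final decade of time."""
    t_end = times[-1]
    t_ref = t_end / 10.0
    v_end = values[-1]
    v_ref = np.interp(t_ref, times, values)
    scale = max(abs(v_end), 1e-300)
    return abs(v_end - v_ref) / scale if v_end != 0.0 or v_ref != 0.0 else 0.0


def asymptotic_readout(traj: Trajectory, plateau_tol: float = 1e-3) -> AsymptoticReadout:
    """Plateau values c_a(inf), M_a(inf) per phase, with a convergence
    certificate.

    A trajectory counts as converged if it terminated on monomer
    exhaustion (the completion of growth — required for fragmentation-like
    n2 = 0, where aggregate number keeps growing slowly afterwards), or if
    the relative change of c_a over the final decade of time is below
    ``plateau_tol`` in both phases.

    Raises
    ------
    NotConvergedError
        If neither certificate holds; transients are never returned.
    """
    change = max(
        _final_decade_change(traj.times, traj.c_a_I),
        _final_decade_change(traj.times, traj.c_a_II),
    )
    if not (traj.monomer_exhausted or change < plateau_tol):
        raise NotConvergedError(
            f"trajectory not at plateau: monomer not exhausted and c_a changed "
            f"by {change:.3e} (> {plateau_tol:.1e}) over the final decade of "
            f"time; increase t_end"
        )
    return AsymptoticReadout(
        c_a_I=float(traj.c_a_I[-1]),
        M_a_I=float(traj.M_a_I[-1]),
        c_a_II=float(traj.c_a_II[-1]),
        M_a_II=float(traj.M_a_II[-1]),
        vI_frac=traj.vI_frac,
        gamma=traj.gamma,
        monomer_exhausted=traj.monomer_exhausted,
        final_decade_change=change,
    )


def asymptotic_readout_homogeneous(
    traj: HomogeneousTrajectory, plateau_tol: float = 1e-3
) -> tuple[float, float]:
    """Plateau (c_a(inf), M_a(inf)) of the homogeneous reference."""
    change = _final_decade_change(traj.times, traj.c_a)
    if not (traj.monomer_exhausted or change < plateau_tol):
        raise NotConvergedError(
            f"homogeneous trajectory not at plateau (final-decade change "
            f"{change:.3e} > {plateau_tol:.1e}); increase t_end"
        )
    return float(traj.c_a[-1]), float(traj.M_a[-1])
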