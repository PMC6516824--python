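"""Parameter sweeps and regime diagrams over (phi_bar, Gamma, n1, n2).

Maps out how the long-time aggregate partitioning ratio epsilon and the
relative asymptotic aggregate concentration

    C(phi_bar, Gamma) = (ca_tot - ca_hom) / ca_hom,
    ca_tot = (c_a^I(inf) * V_I + c_a^II(inf) * V_II) / V,

respond to compartment volume (via phi_bar) and monomer partitioning
Gamma.  C > 0 means the compartmentalised system produces more (and, at
fixed total monomer mass, shorter) aggregates than the homogeneous one;
C < 0 means fewer but larger aggregates.  For secondary reaction orders
n2 < 1 the compartment always suppresses the total aggregate number
(C < 0 everywhere); for n2 > 1 the sign flips as Gamma grows, and
:func:`extract_sign_boundary` traces the zero-level curve in the
(phi_bar, Gamma) plane.

Sweeps default to the quasi-equilibrium kinetics (the model's regime of
validity is fast monomer exchange); points are independent, so evaluation
order never affects results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .errors import IncompleteRowError, NotConvergedError, SolverFailureError, SpecValidationError
from .kinetics import (
    AsymptoticReadout,
    CompartmentState,
    KineticRates,
    SolverOptions,
    SystemState,
    asymptotic_readout,
    asymptotic_readout_homogeneous,
    characteristic_rate,
    quasi_equilibrium_simulate,
    simulate,
    simulate_homogeneous,
)
from .phase import (
    PhaseSeparationSpec,
    compartment_volume_fraction,
    partition_degree,
    split_monomer_pool,
)
from .scaling import regime_classify

__all__ = [
    "SweepResult",
    "total_asymptotic_concentration",
    "relative_asymptotic_concentration",
    "default_gamma_grid",
    "default_phi_bar_grid",
    "sweep",
    "extract_sign_boundary",
    "load_literature_table",
    "classify_literature_systems",
]

# Fast-exchange default used when a finite-k sweep is requested without an
# explicit exchange rate: separation of time scales k_exchange >> kappa.
FAST_EXCHANGE_FACTOR = 1e3


def total_asymptotic_concentration(readout: AsymptoticReadout, vI_frac: float | None = None) -> float:
    """Volume-weighted total aggregate number concentration
    ca_tot = c_a^I(inf)*V_I/V + c_a^II(inf)*V_II/V."""
    vI = readout.vI_frac if vI_frac is None else vI_frac
    return vI * readout.c_a_I + (1.0 - vI) * readout.c_a_II


def relative_asymptotic_concentration(ca_tot: float, ca_hom: float) -> float:
    """Relative asymptotic aggregate concentration
    C = (ca_tot - ca_hom)/ca_hom; positive for an enlarged aggregate pool."""
    if not ca_hom > 0:
        raise SpecValidationError("ca_hom", f"must be > 0, got {ca_hom}")
    return (ca_tot - ca_hom) / ca_hom


def default_gamma_grid(n: int = 20) -> np.ndarray:
    """Log-spaced monomer-partitioning grid covering weak to strong
    partitioning, Gamma in [1.1, 30]."""
    return np.geomspace(1.1, 30.0, n)


def default_phi_bar_grid(spec: PhaseSeparationSpec, n: int = 20) -> np.ndarray:
    """Linear phi_bar grid mapping to V_I/V in [0.01, 0.9]."""
    lo = spec.phi_II + 0.01 * (spec.phi_I - spec.phi_II)
    hi = spec.phi_II + 0.9 * (spec.phi_I - spec.phi_II)
    return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class SweepResult:
    """Grid evaluation of the two-compartment asymptotics.

    2-D arrays are indexed ``[i_phi_bar, j_gamma]``.  ``boundary`` is the
    interpolated zero-level curve of C (possibly empty).  Every value
    carries a convergence flag; failed points hold NaN and are never
    silently dropped.
    """

    phi_bar_grid: np.ndarray
    gamma_grid: np.ndarray
    vI_grid: np.ndarray
    epsilon_grid: np.ndarray
    C_grid: np.ndarray
    ca_tot_grid: np.ndarray
    convergence_flags: np.ndarray
    ca_hom: float
    rates: KineticRates
    model: str

    def __post_init__(self) -> None:
        shape = (len(self.phi_bar_grid), len(self.gamma_grid))
        for name in ("epsilon_grid", "C_grid", "ca_tot_grid", "convergence_flags"):
            if getattr(self, name).shape != shape:
                raise SpecValidationError(name, f"shape mismatch: expected {shape}")

    @property
    def boundary(self) -> np.ndarray:
        """Zero-level curve of C, as (phi_bar, gamma) points."""
        return extract_sign_boundary(self.C_grid, self.phi_bar_grid, self.gamma_grid)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (phi_bar, gamma, vI_frac, epsilon, C, ca_tot,
        converged), row-major over the grid."""
        pb, g = np.meshgrid(self.phi_bar_grid, self.gamma_grid, indexing="ij")
        vI = np.broadcast_to(self.vI_grid[:, None], pb.shape)
        return pd.DataFrame(
            {
                "phi_bar": pb.ravel(),
                "gamma": g.ravel(),
                "vI_frac": vI.ravel(),
                "epsilon": self.epsilon_grid.ravel(),
                "C": self.C_grid.ravel(),
                "ca_tot": self.ca_tot_grid.ravel(),
                "converged": self.convergence_flags.ravel(),
            }
        )

    def metadata(self) -> dict:
        from . import __version__

        return {
            "schema_version": "1",
            "package_version": __version__,
            "model": self.model,
            "phi_bar_grid": self.phi_bar_grid.tolist(),
            "gamma_grid": self.gamma_grid.tolist(),
            "ca_hom": self.ca_hom,
            "rates": {
                "k1": self.rates.k1,
                "n1": self.rates.n1,
                "k2": self.rates.k2,
                "n2": self.rates.n2,
                "k_plus": self.rates.k_plus,
                "k_exchange": self.rates.k_exchange,
            },
        }


def _two_compartment_initial(c_tot: float, gamma: float, vI: float) -> SystemState:
    xi = partition_degree(gamma, vI)
    c_m_I, c_m_II = split_monomer_pool(c_tot, gamma, xi)
    return SystemState(
        CompartmentState(0.0, 0.0, c_m_I),
        CompartmentState(0.0, 0.0, c_m_II),
        vI,
    )


def sweep(
    phi_bar_grid: np.ndarray,
    gamma_grid: np.ndarray,
    rates: KineticRates,
    spec_template: PhaseSeparationSpec,
    c_tot: float = 1.0,
    model: str = "quasi-equilibrium",
    t_end: float | None = None,
    solver_options: SolverOptions | None = None,
    plateau_tol: float = 1e-3,
) -> SweepResult:
    """Evaluate epsilon, ca_tot and C on a (phi_bar, Gamma) grid.

    ``spec_template`` supplies the coexisting compositions used to map
    phi_bar to the compartment volume fraction; Gamma is swept directly
    (experimentally it would be tuned via delta_chi at fixed geometry).
    ``model`` is ``"quasi-equilibrium"`` (default, fast-exchange limit) or
    ``"finite-k"``; in the latter case ``rates.k_exchange`` is used if
    positive, else the fast-exchange default 1e3*kappa.  Deterministic:
    identical inputs give identical results, independent of evaluation
    order.
    """
    phi_bar_grid = np.asarray(phi_bar_grid, dtype=float)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if model not in ("quasi-equilibrium", "finite-k"):
        raise SpecValidationError("model", f"unknown sweep model {model!r}")
    kappa = characteristic_rate(rates, c_tot)
    if t_end is None:
        t_end = 500.0 / kappa
    options = solver_options or SolverOptions()

    # single homogeneous reference: independent of Gamma and phi_bar
    hom = simulate_homogeneous(c_tot, rates, t_end, options)
    ca_hom, _ = asymptotic_readout_homogeneous(hom, plateau_tol)

    n_p, n_g = len(phi_bar_grid), len(gamma_grid)
    vI_grid = np.empty(n_p)
    eps = np.full((n_p, n_g), np.nan)
    ca_tot = np.full((n_p, n_g), np.nan)
    C = np.full((n_p, n_g), np.nan)
    flags = np.zeros((n_p, n_g), dtype=bool)

    run_rates = rates
    if model == "finite-k" and rates.k_exchange <= 0:
        run_rates = replace(rates, k_exchange=FAST_EXCHANGE_FACTOR * kappa)

    for i, pb in enumerate(phi_bar_grid):
        spec = replace(spec_template, phi_bar=pb)
        vI = compartment_volume_fraction(spec)
        vI_grid[i] = vI
        for j, gamma in enumerate(gamma_grid):
            initial = _two_compartment_initial(c_tot, gamma, vI)
            try:
                if model == "quasi-equilibrium":
                    traj = quasi_equilibrium_simulate(initial, run_rates, gamma, t_end, options)
                else:
                    traj = simulate(initial, run_rates, gamma, t_end, options)
                ro = asymptotic_readout(traj, plateau_tol)
            except (NotConvergedError, SolverFailureError):
                continue  # flag stays False, values stay NaN
            eps[i, j] = ro.epsilon
            ca_tot[i, j] = total_asymptotic_concentration(ro)
            C[i, j] = relative_asymptotic_concentration(ca_tot[i, j], ca_hom)
            flags[i, j] = True

    return SweepResult(
        phi_bar_grid=phi_bar_grid,
        gamma_grid=gamma_grid,
        vI_grid=vI_grid,
        epsilon_grid=eps,
        C_grid=C,
        ca_tot_grid=ca_tot,
        convergence_flags=flags,
        ca_hom=ca_hom,
        rates=run_rates,
        model=model,
    )


def extract_sign_boundary(
    C_grid: np.ndarray, phi_bar_grid: np.ndarray, gamma_grid: np.ndarray
) -> np.ndarray:
    """Zero crossings of C along the Gamma axis, one scan per phi_bar.

    Linear interpolation between adjacent grid points of opposite sign.
    Returns an (n, 2) array of (phi_bar, gamma_zero) points; empty when C
    has a single sign on the grid (a valid result, e.g. n2 < 1).
    """
    points: list[tuple[float, float]] = []
    for i, pb in enumerate(np.asarray(phi_bar_grid, dtype=float)):
        row = np.asarray(C_grid[i], dtype=float)
        for j in range(len(row) - 1):
            a, b = row[j], row[j + 1]
            if not (np.isfinite(a) and np.isfinite(b)):
                continue
            if a == 0.0:
                points.append((pb, float(gamma_grid[j])))
            elif a * b < 0.0:
                frac = a / (a - b)
                g0 = gamma_grid[j] + frac * (gamma_grid[j + 1] - gamma_grid[j])
                points.append((pb, float(g0)))
        if len(row) and row[-1] == 0.0:
            points.append((pb, float(gamma_grid[-1])))
    return np.array(points).reshape(-1, 2)


def load_literature_table() -> pd.DataFrame:
    """Bundled table of literature aggregating systems.

    Lists named systems (Tau, Ure2p, IAPP, Amyloid-beta40, Amyloid-beta42)
    with their late-stage proliferation mechanism.  The measured reaction
    orders are deliberately left blank — they are experimental inputs the
    user must supply before classification, not package constants.
    """
    path = resources.files("condkin") / "_data" / "literature_systems.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def classify_literature_systems(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the optimal-compartment-size regime to each system row.

    ``table`` needs columns (name, mechanism, n1, n2).  Rows with missing
    reaction orders raise :class:`IncompleteRowError` naming the system.
    """
    for col in ("name", "mechanism", "n1", "n2"):
        if col not in table.columns:
            raise SpecValidationError("table", f"missing column {col!r}")
    out = table.copy()
    regimes = []
    for _, row in out.iterrows():
        if pd.isna(row["n1"]) or pd.isna(row["n2"]):
            raise IncompleteRowError(
                f"system {row['name']!r}: reaction orders n1/n2 missing; supply "
                "measured values before classification"
            )
        regimes.append(regime_classify(float(row["n1"]), float(row["n2"])))
    out["regime"] = regimes
    return out
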