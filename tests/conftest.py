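import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from condkin import (
    CompartmentState,
    KineticRates,
    SystemState,
    asymptotic_readout,
    partition_degree,
    quasi_equilibrium_simulate,
    simulate,
    split_monomer_pool,
)

# secondary-dominated baseline: kappa = sqrt(2*k_plus*k2) = 1
AMYLOID_RATES = dict(k1=1e-4, n1=2, k2=1.0, n2=2, k_plus=0.5)


@pytest.fixture
def amyloid_rates() -> KineticRates:
    return KineticRates(**AMYLOID_RATES)


def two_compartment_initial(gamma: float, vI: float, c_tot: float = 1.0) -> SystemState:
    """Aggregate-free state with the monomer pool at partition equilibrium."""
    xi = partition_degree(gamma, vI)
    c_m_I, c_m_II = split_monomer_pool(c_tot, gamma, xi)
    return SystemState(
        CompartmentState(0.0, 0.0, c_m_I), CompartmentState(0.0, 0.0, c_m_II), vI
    )


def run_to_plateau(
    rates: KineticRates,
    gamma: float,
    vI: float,
    c_tot: float = 1.0,
    t_end: float = 2000.0,
    model: str = "quasi",
    options=None,
):
    init = two_compartment_initial(gamma, vI, c_tot)
    integrate = quasi_equilibrium_simulate if model == "quasi" else simulate
    traj = integrate(init, rates, gamma, t_end, options)
    return asymptotic_readout(traj)


def loglog_slope(x, y) -> float:
    return float(np.polyfit(np.log(np.asarray(x)), np.log(np.asarray(y)), 1)[0])
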