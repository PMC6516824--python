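"""Fibril formation coupled to a liquid compartment: the positive feedback.

Integrates the two-compartment moment equations for a weakly partitioning
system (Gamma = 3, secondary-dominated nucleation, n1 = n2 = 2) and prints
the long-time aggregate concentrations in each phase.  Even this weak
monomer partitioning is amplified into an aggregate enrichment of several
orders of magnitude, because the exchange flux keeps feeding the
compartment with monomers as its aggregates grow.
"""

import numpy as np

from condkin import (
    CompartmentState,
    KineticRates,
    SystemState,
    asymptotic_readout,
    partition_degree,
    quasi_equilibrium_simulate,
    split_monomer_pool,
)

gamma, vI = 3.0, 0.1
rates = KineticRates(k1=1e-4, n1=2, k2=1.0, n2=2, k_plus=0.5)  # kappa = 1

xi = partition_degree(gamma, vI)
c_m_I, c_m_II = split_monomer_pool(1.0, gamma, xi)
initial = SystemState(
    CompartmentState(0.0, 0.0, c_m_I), CompartmentState(0.0, 0.0, c_m_II), vI
)

traj = quasi_equilibrium_simulate(initial, rates, gamma, t_end=500.0)
ro = asymptotic_readout(traj)

print(f"monomer partitioning Gamma       = {gamma}")
print(f"aggregate number c_a^I(inf)      = {ro.c_a_I:.4f}")
print(f"aggregate number c_a^II(inf)     = {ro.c_a_II:.3e}")
print(f"aggregate partitioning epsilon   = {ro.epsilon:.1f}")
print(f"worst relative mass residual     = {np.abs(traj.mass_residual).max():.2e}")
# epsilon >> Gamma: a 3-fold monomer preference became a ~1e4-fold
# aggregate enrichment inside the compartment.
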