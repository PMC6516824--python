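"""Two-compartment moment kinetics: flux, conservation, closed forms, limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condkin import (
    CompartmentState,
    KineticRates,
    NoCharacteristicScaleError,
    NotConvergedError,
    PhaseSeparationSpec,
    SolverOptions,
    SpecValidationError,
    SystemState,
    asymptotic_readout,
    characteristic_rate,
    constant_monomer_aggregate_mass,
    exchange_flux,
    initial_state_at_partition_equilibrium,
    nondimensionalize,
    quasi_equilibrium_simulate,
    redimensionalize,
    rhs,
    simulate,
    simulate_homogeneous,
)
from conftest import two_compartment_initial


class TestExchangeFlux:
    @pytest.mark.parametrize(
        "MmI,MmII,gamma,k,expected",
        [
            (3.0, 1.0, 3.0, 5.0, 0.0),  # at partitioning equilibrium
            (1.0, 1.0, 1.0, 7.0, 0.0),
            (1.0, 1.0, 3.0, 2.0, 4.0),  # -2*(1-3): monomers pulled into phase I
            (2.0, 0.5, 1.0, 1.0, -1.5),
        ],
    )
    def test_values(self, MmI, MmII, gamma, k, expected):
        assert exchange_flux(MmI, MmII, gamma, k) == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(SpecValidationError):
            exchange_flux(-1.0, 1.0, 2.0, 1.0)
        with pytest.raises(SpecValidationError, match="gamma"):
            exchange_flux(1.0, 1.0, 0.0, 1.0)


class TestRhs:
    def test_absorbing_zero_state(self, amyloid_rates):
        state = SystemState(CompartmentState(0, 0, 0), CompartmentState(0, 0, 0), 0.4)
        assert np.all(rhs(state, amyloid_rates, 2.0) == 0.0)

    def test_symmetric_phases_give_symmetric_derivatives(self, amyloid_rates):
        state = SystemState(
            CompartmentState(0.1, 0.2, 0.7), CompartmentState(0.1, 0.2, 0.7), 0.5
        )
        d = rhs(state, amyloid_rates, 1.0)
        assert d[:3] == pytest.approx(d[3:])

    def test_volume_weighted_mass_conservation(self, amyloid_rates):
        """Exchange flux moves mass between phases without creating any."""
        vI = 0.3
        state = SystemState(
            CompartmentState(0.05, 0.4, 1.2), CompartmentState(0.01, 0.1, 0.3), vI
        )
        rates = KineticRates(**{**amyloid_rates.__dict__, "k_exchange": 10.0,
                                "multipliers_I": (1, 1, 1), "multipliers_II": (1, 1, 1)})
        d = rhs(state, rates, 2.5)
        # mass terms: M_a and M_m in each phase
        total = vI * (d[1] + d[2]) + (1 - vI) * (d[4] + d[5])
        assert total == pytest.approx(0.0, abs=1e-14)

    def test_phase_multipliers_scale_rates(self):
        base = KineticRates(k1=1e-3, n1=2, k2=1.0, n2=2, k_plus=0.5)
        boosted = KineticRates(
            k1=1e-3, n1=2, k2=1.0, n2=2, k_plus=0.5, multipliers_I=(2.0, 3.0, 4.0)
        )
        state = SystemState(
            CompartmentState(0.1, 0.2, 0.5), CompartmentState(0.1, 0.2, 0.5), 0.5
        )
        d0, d1 = rhs(state, base, 1.0), rhs(state, boosted, 1.0)
        # phase II untouched
        assert d1[3:] == pytest.approx(d0[3:])
        assert d1[1] == pytest.approx(4.0 * d0[1])  # elongation scaled by k_plus factor


class TestHomogeneous:
    def test_mass_conservation_and_positivity(self, amyloid_rates):
        traj = simulate_homogeneous(1.0, amyloid_rates, 50.0)
        assert np.abs(traj.mass_residual).max() < 1e-10
        assert traj.c_a.min() >= 0 and traj.M_m.min() >= 0
        assert np.all(np.diff(traj.c_a) >= -1e-12)

    def test_early_time_primary_only_linear_growth(self):
        """With k2=0 the aggregate number initially grows as k1*Mm(0)^n1*t."""
        rates = KineticRates(k1=1e-3, n1=2, k2=0.0, n2=0, k_plus=0.5)
        traj = simulate_homogeneous(2.0, rates, 0.5)
        early = traj.times < 0.01
        expected = rates.k1 * 2.0**2 * traj.times[early]
        assert traj.c_a[early] == pytest.approx(expected, rel=1e-3)

    def test_zero_monomer_is_identically_zero(self, amyloid_rates):
        traj = simulate_homogeneous(0.0, amyloid_rates, 10.0)
        assert traj.c_a.max() == 0.0 and traj.M_a.max() == 0.0

    def test_frozen_monomer_matches_cosh_closed_form(self, amyloid_rates):
        opts = SolverOptions(rtol=1e-10, atol_factor=1e-20, first_point_factor=1e-4)
        traj = simulate_homogeneous(1.0, amyloid_rates, 3.0, opts, freeze_monomer=True)
        exact = constant_monomer_aggregate_mass(traj.times, amyloid_rates, 1.0)
        assert traj.M_a == pytest.approx(exact, rel=1e-6)


class TestTwoCompartment:
    def test_no_nucleation_only_reequilibrates(self):
        rates = KineticRates(k1=0.0, n1=2, k2=0.0, n2=2, k_plus=0.5, k_exchange=5.0)
        init = SystemState(
            CompartmentState(0, 0, 1.0), CompartmentState(0, 0, 1.0), 0.25
        )
        traj = simulate(init, rates, 4.0, 10.0)
        assert traj.c_a_I.max() == 0.0 and traj.M_a_II.max() == 0.0
        # monomers relax to M_m^I = Gamma * M_m^II
        assert traj.M_m_I[-1] / traj.M_m_II[-1] == pytest.approx(4.0, rel=1e-6)
        assert np.abs(traj.mass_residual).max() < 1e-9

    def test_gamma_one_equals_homogeneous(self, amyloid_rates):
        """Equal compositions reduce the coupled system to the reference."""
        rates = KineticRates(**{**amyloid_rates.__dict__, "k_exchange": 3.0})
        init = SystemState(
            CompartmentState(0, 0, 1.0), CompartmentState(0, 0, 1.0), 0.3
        )
        traj = simulate(init, rates, 1.0, 30.0)
        hom = simulate_homogeneous(1.0, rates, 30.0)
        n = min(len(traj.times), len(hom.times))
        assert traj.times[:n] == pytest.approx(hom.times[:n])
        for a, b in [
            (traj.c_a_I, hom.c_a),
            (traj.c_a_II, hom.c_a),
            (traj.M_a_I, hom.M_a),
            (traj.M_m_II, hom.M_m),
        ]:
            assert a[:n] == pytest.approx(b[:n], rel=1e-6)

    def test_conservation_and_positivity(self, amyloid_rates):
        rates = KineticRates(**{**amyloid_rates.__dict__, "k_exchange": 100.0})
        init = two_compartment_initial(3.0, 0.2)
        traj = simulate(init, rates, 3.0, 100.0)
        assert np.abs(traj.mass_residual).max() < 1e-6
        for arr in (traj.c_a_I, traj.M_a_I, traj.M_m_I, traj.c_a_II, traj.M_a_II, traj.M_m_II):
            assert arr.min() >= 0.0
        assert np.all(np.diff(traj.c_a_I) >= -1e-12)
        assert np.all(np.diff(traj.c_a_II) >= -1e-12)
        # total monomer mass never increases
        assert np.all(np.diff(traj.total_monomer_mass) <= 1e-12)

    def test_quasi_equilibrium_enforces_monomer_ratio(self, amyloid_rates):
        gamma = 3.0
        traj = quasi_equilibrium_simulate(
            two_compartment_initial(gamma, 0.3), amyloid_rates, gamma, 50.0
        )
        mask = traj.M_m_II > 0
        assert traj.M_m_I[mask] / traj.M_m_II[mask] == pytest.approx(gamma)

    def test_fast_exchange_converges_to_quasi_equilibrium(self, amyloid_rates):
        gamma, vI = 3.0, 0.3
        init = two_compartment_initial(gamma, vI)
        q = quasi_equilibrium_simulate(init, amyloid_rates, gamma, 40.0)
        devs = []
        for ke in (1e1, 1e2, 1e3, 1e4):
            rates = KineticRates(**{**amyloid_rates.__dict__, "k_exchange": ke})
            f = simulate(init, rates, gamma, 40.0)
            tgrid = q.times[q.times <= min(q.times[-1], f.times[-1])]
            dev = max(
                np.max(np.abs(np.interp(tgrid, q.times, qa) - np.interp(tgrid, f.times, fa)))
                / np.max(np.abs(qa))
                for qa, fa in [
                    (q.c_a_I, f.c_a_I),
                    (q.c_a_II, f.c_a_II),
                    (q.M_a_I, f.M_a_I),
                    (q.M_a_II, f.M_a_II),
                ]
            )
            devs.append(dev)
        assert all(b < a for a, b in zip(devs, devs[1:]))
        assert devs[-1] < 0.01


class TestInitialState:
    def test_equilibrium_split(self):
        spec = PhaseSeparationSpec(1.0, 0.0, 0.5, np.log(3.0))
        state = initial_state_at_partition_equilibrium(1.0, spec)
        assert state.vI_frac == pytest.approx(0.5)
        assert (state.phase_I.M_m, state.phase_II.M_m) == (
            pytest.approx(1.5),
            pytest.approx(0.5),
        )
        assert state.total_mass == pytest.approx(1.0)
        assert state.phase_I.c_a == 0.0

    def test_gamma_one_splits_equally(self):
        spec = PhaseSeparationSpec(0.8, 0.2, 0.5, 0.0)
        state = initial_state_at_partition_equilibrium(2.0, spec)
        assert state.phase_I.M_m == pytest.approx(state.phase_II.M_m) == pytest.approx(2.0)

    def test_single_phase_volume_directs_to_homogeneous(self):
        spec = PhaseSeparationSpec(0.9, 0.1, 0.1, 1.0)  # phi_bar on the dilute branch
        with pytest.raises(Exception, match="homogeneous|simulate_homogeneous"):
            initial_state_at_partition_equilibrium(1.0, spec)


class TestNondimensionalize:
    @given(
        k1=st.floats(1e-6, 1e2),
        k2=st.floats(1e-4, 1e2),
        kp=st.floats(1e-3, 1e3),
        m=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, k1, k2, kp, m):
        rates = KineticRates(k1=k1, n1=2, k2=k2, n2=2, k_plus=kp, k_exchange=3.0)
        scaled, t_char = nondimensionalize(rates, m)
        back = redimensionalize(scaled, m, t_char)
        for f in ("k1", "k2", "k_plus", "k_exchange"):
            assert getattr(back, f) == pytest.approx(getattr(rates, f), rel=1e-12)
        assert characteristic_rate(scaled, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_kappa_square_root_dependence(self):
        r = KineticRates(k1=0.0, n1=2, k2=1.0, n2=2, k_plus=1.0)
        r4 = KineticRates(k1=0.0, n1=2, k2=1.0, n2=2, k_plus=4.0)
        assert characteristic_rate(r4, 1.0) == pytest.approx(2 * characteristic_rate(r, 1.0))

    def test_primary_only_fallback_scale(self):
        r = KineticRates(k1=2.0, n1=2, k2=0.0, n2=0, k_plus=0.5)
        assert characteristic_rate(r, 1.0) == pytest.approx(np.sqrt(2 * 0.5 * 2.0))

    def test_no_scale_error(self):
        r = KineticRates(k1=0.0, n1=2, k2=0.0, n2=0, k_plus=0.5)
        with pytest.raises(NoCharacteristicScaleError):
            nondimensionalize(r, 1.0)


class TestAsymptoticReadout:
    def test_converged_run_stable_under_longer_integration(self, amyloid_rates):
        init = two_compartment_initial(3.0, 0.3)
        r1 = asymptotic_readout(quasi_equilibrium_simulate(init, amyloid_rates, 3.0, 100.0))
        r2 = asymptotic_readout(quasi_equilibrium_simulate(init, amyloid_rates, 3.0, 200.0))
        assert r1.c_a_I == pytest.approx(r2.c_a_I, rel=1e-3)
        assert r1.c_a_II == pytest.approx(r2.c_a_II, rel=1e-3)

    def test_monomer_exhaustion_completes_aggregation(self, amyloid_rates):
        init = two_compartment_initial(3.0, 0.3)
        traj = quasi_equilibrium_simulate(init, amyloid_rates, 3.0, 200.0)
        ro = asymptotic_readout(traj)
        assert ro.monomer_exhausted
        total_Ma = 0.3 * ro.M_a_I + 0.7 * ro.M_a_II
        assert total_Ma == pytest.approx(1.0, rel=1e-5)

    def test_transient_raises_not_converged(self, amyloid_rates):
        init = two_compartment_initial(3.0, 0.3)
        traj = quasi_equilibrium_simulate(init, amyloid_rates, 3.0, 1.0)
        with pytest.raises(NotConvergedError, match="plateau"):
            asymptotic_readout(traj)

    def test_no_nucleation_reads_zero(self):
        rates = KineticRates(k1=0.0, n1=2, k2=0.0, n2=2, k_plus=0.5, k_exchange=5.0)
        init = two_compartment_initial(2.0, 0.4)
        traj = simulate(init, rates, 2.0, 50.0)
        ro = asymptotic_readout(traj)
        assert ro.c_a_I == 0.0 and ro.c_a_II == 0.0
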