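"""State-model partition function: limits, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermogate import (
    AllostericModel,
    ModelII,
    ModelIII,
    ThermoTransition,
    enumerate_states,
    equilibrium_constant,
    fraction_na_bound,
    open_probability,
    open_probability_model_ii,
    open_probability_model_iii,
)
from thermogate.constants import R_KCAL

from conftest import random_model


class TestEquilibriumConstant:
    def test_null_transition_is_unity(self):
        tr = ThermoTransition(dH0=0.0, dS0=0.0)
        for T in (250.0, 295.15, 330.0):
            assert equilibrium_constant(tr, T) == 1.0

    def test_scalar_value_matches_high_precision_evaluation(self):
        # exp(-(45 - 310*0.133)/(R*310)) evaluated with 40-digit arithmetic
        tr = ThermoTransition(dH0=45.0, dS0=0.133)
        expected = 0.002198869404364621363690279835789332500366
        assert equilibrium_constant(tr, 310.0) == pytest.approx(
            expected, rel=1e-12)

    def test_vant_hoff_linearity_in_inverse_temperature(self):
        tr = ThermoTransition(dH0=20.0, dS0=0.06)
        T = np.linspace(260, 340, 50)
        lnJ = np.log(equilibrium_constant(tr, T))
        slope, intercept = np.polyfit(1.0 / T, lnJ, 1)
        assert np.allclose(lnJ, intercept + slope / T, atol=1e-10)
        assert slope == pytest.approx(-tr.dH0 / R_KCAL, rel=1e-9)

    def test_heat_capacity_form_with_zero_dh_is_entropy_only_at_dcp_zero(self):
        # the printed dCp expression at dCp -> 0 is exp(dS0/R) at every T
        tr_limit = ThermoTransition(dH0=0.0, dS0=0.05, dCp=1e-300, T0=300.0)
        T = np.array([270.0, 300.0, 330.0])
        assert np.allclose(equilibrium_constant(tr_limit, T),
                           np.exp(0.05 / R_KCAL), rtol=1e-12)

    def test_heat_capacity_form_continuous_and_positive(self):
        tr = ThermoTransition(dH0=0.0, dS0=0.02, dCp=-0.5, T0=300.0)
        T = np.linspace(260, 340, 500)
        J = equilibrium_constant(tr, T)
        assert np.all(J > 0)
        assert np.max(np.abs(np.diff(np.log(J)))) < 0.1

    def test_nonpositive_temperature_rejected(self):
        tr = ThermoTransition(dH0=10.0, dS0=0.03)
        with pytest.raises(ValueError):
            equilibrium_constant(tr, 0.0)
        with pytest.raises(ValueError):
            equilibrium_constant(tr, -5.0)

    def test_dcp_requires_reference_temperature(self):
        with pytest.raises(ValueError):
            ThermoTransition(dH0=0.0, dS0=0.0, dCp=-0.3)


class TestStateEnumeration:
    def test_neutral_model_has_six_unit_weights(self):
        m = AllostericModel(L=1.0, J1=ThermoTransition(0, 0),
                            J2=ThermoTransition(0, 0))
        states = enumerate_states(m, 300.0, na=0.0)
        assert len(states) == 12
        unbound = [s for s in states if not s.na_bound]
        assert all(s.weight == 1.0 for s in unbound)
        assert all(s.weight == 0.0 for s in states if s.na_bound)

    def test_reference_state_weight_is_one(self, model_i):
        states = enumerate_states(model_i, 295.15, na=0.05)
        ref = [s for s in states
               if s.sensor_step == 0 and s.pore == "closed"
               and not s.na_bound and not s.caps_bound]
        assert len(ref) == 1 and ref[0].weight == 1.0

    def test_zero_ligand_states_have_zero_weight(self, model_i):
        states = enumerate_states(model_i, 300.0, na=0.0)
        assert all(s.weight == 0.0 for s in states if s.na_bound)

    def test_na_bound_weights_scale_with_binding_term(self, model_i):
        # before the cooperativity exponent the binding term is linear in
        # [Na]; with coop = 1.5 weights scale as [Na]^1.5
        s1 = enumerate_states(model_i, 300.0, na=0.01)
        s2 = enumerate_states(model_i, 300.0, na=0.02)
        for a, b in zip(s1, s2):
            if a.na_bound:
                assert b.weight / a.weight == pytest.approx(2.0 ** 1.5)

    def test_capsaicin_extension_has_24_states(self, rng):
        m = random_model(rng, with_caps=True)
        assert len(enumerate_states(m, 300.0, na=0.05, caps=1e-6)) == 24

    def test_caps_concentration_requires_caps_model(self, model_i):
        with pytest.raises(ValueError):
            open_probability(model_i, 300.0, na=0.0, caps=1e-6)


class TestOpenProbability:
    def test_decoupled_limit_is_l_over_one_plus_l(self):
        m = AllostericModel(L=0.25, J1=ThermoTransition(30, 0.1),
                            J2=ThermoTransition(60, 0.2),
                            K1_prime=100.0)  # all couplings neutral
        for T in (260.0, 300.0, 340.0):
            for na in (0.0, 0.05, 1.0):
                assert open_probability(m, T, na) == pytest.approx(
                    0.2, abs=1e-12)

    def test_high_temperature_limit(self, model_i):
        # with positive entropies both sensor steps saturate as T -> inf,
        # leaving the fully-coupled opening equilibrium D*E*L
        lim = model_i.D * model_i.E * model_i.L
        assert open_probability(model_i, 1e6, na=0.0) == pytest.approx(
            lim / (1 + lim), rel=1e-6)

    def test_partition_function_matches_enumeration_oracle(self, rng):
        """Vectorised P_o equals brute-force state-weight summation
        to 1e-12 over 1000 random parameter/condition draws."""
        for k in range(1000):
            with_caps = k % 2 == 1
            m = random_model(rng, with_caps=with_caps)
            T = rng.uniform(255, 345)
            na = rng.uniform(0, 0.3)
            caps = rng.uniform(0, 2e-5) if with_caps else 0.0
            states = enumerate_states(m, T, na, caps)
            tot = sum(s.weight for s in states)
            po_enum = sum(s.weight for s in states if s.pore == "open") / tot
            fna_enum = sum(s.weight for s in states if s.na_bound) / tot
            assert open_probability(m, T, na, caps) == pytest.approx(
                po_enum, abs=1e-12, rel=1e-12)
            assert fraction_na_bound(m, T, na, caps) == pytest.approx(
                fna_enum, abs=1e-12, rel=1e-12)

    def test_occupancies_normalise(self, rng):
        for _ in range(200):
            m = random_model(rng, with_caps=True)
            states = enumerate_states(m, rng.uniform(260, 340),
                                      rng.uniform(0, 0.3),
                                      rng.uniform(0, 1e-5))
            tot = sum(s.weight for s in states)
            occ = [s.weight / tot for s in states]
            assert abs(sum(occ) - 1.0) < 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(T=st.floats(255, 345), na=st.floats(0, 0.5),
           logL=st.floats(-6, 2))
    def test_po_bounded_and_finite(self, T, na, logL):
        m = AllostericModel(L=float(np.exp(logL)),
                            J1=ThermoTransition(30, 0.105),
                            J2=ThermoTransition(80, 0.25),
                            D=50, E=1000, K1_prime=143, F=0.1, G=0.01)
        po = open_probability(m, T, na)
        assert 0.0 <= po <= 1.0 and np.isfinite(po)

    def test_na_monotonicity_with_inhibitory_couplings(self, rng):
        """With F, G, H <= 1 and D, E >= 1, P_o is non-increasing in
        [Na] at fixed temperature."""
        for _ in range(50):
            m = AllostericModel(
                L=float(np.exp(rng.uniform(-6, 1))),
                J1=ThermoTransition(rng.uniform(0, 60), rng.uniform(0, 0.2)),
                J2=ThermoTransition(rng.uniform(0, 60), rng.uniform(0, 0.2)),
                D=float(np.exp(rng.uniform(0, 6))),
                E=float(np.exp(rng.uniform(0, 6))),
                K1_prime=float(np.exp(rng.uniform(0, 6))),
                F=float(np.exp(rng.uniform(-5, 0))),
                G=float(np.exp(rng.uniform(-5, 0))),
                H=float(np.exp(rng.uniform(-5, 0))))
            T = rng.uniform(260, 340)
            na_grid = np.linspace(0, 0.3, 31)
            po = np.array([open_probability(m, T, na) for na in na_grid])
            assert np.all(np.diff(po) <= 1e-12)

    def test_plateau_between_well_separated_sensor_steps(self):
        """With sensor midpoints far apart the P_o-T curve has an
        intermediate region where the slope is <1% of its peak."""
        m = AllostericModel(L=0.01, J1=ThermoTransition(40, 40 / 270.0),
                            J2=ThermoTransition(80, 80 / 325.0),
                            D=50, E=1000)
        T = np.linspace(255, 340, 1000)
        po = open_probability(m, T, 0.0)
        dpo = np.gradient(po, T)
        plateau = (T > 280) & (T < 310)
        assert np.min(np.abs(dpo[plateau])) < 0.01 * np.max(np.abs(dpo))

    def test_smooth_in_temperature(self, model_i):
        T = np.linspace(260, 340, 2000)
        po = open_probability(model_i, T, 0.065)
        assert np.max(np.abs(np.diff(po))) < 0.01


class TestFractionNaBound:
    def test_zero_na_gives_zero(self, model_i):
        assert fraction_na_bound(model_i, 300.0, 0.0) == 0.0

    def test_saturation_at_high_na(self, model_i):
        assert fraction_na_bound(model_i, 300.0, 1e6) == pytest.approx(
            1.0, abs=1e-6)

    def test_half_occupancy_at_unit_binding_term(self):
        # K1'*[Na] = 1 with neutral couplings: every state pairs with an
        # equally-weighted Na-bound copy, so F_Na = 1/2 exactly
        m = AllostericModel(L=0.3, J1=ThermoTransition(30, 0.1),
                            J2=ThermoTransition(60, 0.2),
                            K1_prime=1 / 0.007)
        assert fraction_na_bound(m, 300.0, 0.007) == pytest.approx(
            0.5, abs=1e-12)

    def test_monotone_in_na(self, model_i):
        na = np.linspace(0, 0.3, 50)
        f = np.array([fraction_na_bound(model_i, 295.15, x) for x in na])
        assert np.all(np.diff(f) >= -1e-12)


class TestModelII:
    @staticmethod
    def _enumerate(p, T, na):
        J1 = equilibrium_constant(p.J1, T)
        J2 = equilibrium_constant(p.J2, T)
        J3 = equilibrium_constant(p.J3, T)
        K1 = (p.K1_prime * na) ** p.coop_exponent if na > 0 else 0.0
        weights = {
            "Ca": 1.0, "Cb": J1, "Oa": J1 * p.L, "Ob": J1 * p.L * J2,
            "CaNa": K1, "CbNa": K1 * p.G * J1,
            "OaNa": K1 * p.G * J1 * J3, "ObNa": K1 * p.G * J1 * J3 * J2,
        }
        tot = sum(weights.values())
        return sum(w for k, w in weights.items() if k.startswith("O")) / tot

    def test_opening_limit_without_na(self):
        p = ModelII(L=0.5, J1=ThermoTransition(-30, 0),   # J1 >> 1
                    J2=ThermoTransition(100, 0),          # J2 -> 0
                    J3=ThermoTransition(10, 0.03))
        assert open_probability_model_ii(p, 300.0, 0.0) == pytest.approx(
            0.5 / 1.5, rel=1e-8)

    def test_neutral_parameters_constant_po(self):
        p = ModelII(L=0.2, J1=ThermoTransition(0, 0), J2=ThermoTransition(0, 0),
                    J3=ThermoTransition(0, 0))
        po = [open_probability_model_ii(p, T, 0.0) for T in (260, 300, 340)]
        assert np.allclose(po, po[0], atol=1e-14)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(300):
            p = ModelII(
                L=float(np.exp(rng.uniform(-5, 2))),
                J1=ThermoTransition(rng.uniform(-40, 70), rng.uniform(-0.1, 0.25)),
                J2=ThermoTransition(rng.uniform(-40, 70), rng.uniform(-0.1, 0.25)),
                J3=ThermoTransition(rng.uniform(-40, 70), rng.uniform(-0.1, 0.25)),
                G=float(np.exp(rng.uniform(-5, 2))),
                K1_prime=float(np.exp(rng.uniform(0, 6))))
            T, na = rng.uniform(260, 340), rng.uniform(0, 0.3)
            assert open_probability_model_ii(p, T, na) == pytest.approx(
                self._enumerate(p, T, na), abs=1e-12, rel=1e-12)


class TestModelIII:
    def test_decoupled_limit(self):
        p = ModelIII(L=0.5, J1=ThermoTransition(30, 0.1), K1_prime=10.0)
        for T in (260.0, 300.0, 340.0):
            assert open_probability_model_iii(p, T, 0.1) == pytest.approx(
                1 / 3, abs=1e-12)

    def test_equals_model_i_with_second_sensor_step_disabled(self, rng):
        """The single-sensor scheme is the two-step scheme with the
        second transition's weight driven to zero (E = H = 1)."""
        for _ in range(100):
            J1 = ThermoTransition(rng.uniform(0, 60), rng.uniform(0, 0.2))
            L = float(np.exp(rng.uniform(-5, 1)))
            D = float(np.exp(rng.uniform(0, 5)))
            F = float(np.exp(rng.uniform(-4, 0)))
            G = float(np.exp(rng.uniform(-4, 0)))
            K1p = float(np.exp(rng.uniform(0, 5)))
            p3 = ModelIII(L=L, J1=J1, D=D, K1_prime=K1p, F=F, G=G)
            m1 = AllostericModel(L=L, J1=J1,
                                 J2=ThermoTransition(dH0=2000.0, dS0=0.0),
                                 D=D, E=1.0, K1_prime=K1p, F=F, G=G, H=1.0)
            T, na = rng.uniform(260, 340), rng.uniform(0, 0.2)
            assert open_probability_model_iii(p3, T, na) == pytest.approx(
                open_probability(m1, T, na), abs=1e-12, rel=1e-10)

    def test_po_increases_with_temperature_for_activating_coupling(self):
        p = ModelIII(L=0.01, J1=ThermoTransition(40, 40 / 300.0), D=200.0)
        T = np.linspace(260, 340, 200)
        po = open_probability_model_iii(p, T, 0.0)
        assert np.all(np.diff(po) > 0)


class TestHeatCapacityIndistinguishability:
    """Within the experimental temperature window, a model whose sensor
    steps derive their temperature dependence from a heat-capacity change
    can be matched by a plain van 't Hoff parameterisation: refitting the
    dH/dS pairs to the dCp-generated P_o-T family leaves residuals below
    experimental resolution, and the match becomes exact as dCp -> 0."""

    WINDOW = np.linspace(280.0, 315.0, 200)
    NA_FAMILY = (0.0, 0.03, 0.13)

    @staticmethod
    def _dcp_transition(dCp, T_mid, dH_eff):
        # dCp-driven transition with apparent enthalpy dH_eff and J = 1
        # at T_mid (so dH(T0) = 0 with T0 = T_mid - dH_eff/dCp)
        T0 = T_mid - dH_eff / dCp
        dS0 = dH_eff / T_mid - dCp * np.log(T_mid / T0)
        return ThermoTransition(dH0=0.0, dS0=dS0, dCp=dCp, T0=T0)

    def _max_po_difference(self, dCp):
        from scipy.optimize import least_squares

        def mk(J1, J2):
            return AllostericModel(L=0.005, J1=J1, J2=J2, D=50, E=1000,
                                   K1_prime=143, F=0.12, G=0.01)

        m_cp = mk(self._dcp_transition(dCp, 278.0, 30.0),
                  self._dcp_transition(dCp, 318.0, 80.0))
        targets = [open_probability(m_cp, self.WINDOW, na)
                   for na in self.NA_FAMILY]

        def resid(x):
            m = mk(ThermoTransition(x[0], x[1]), ThermoTransition(x[2], x[3]))
            return np.concatenate([
                open_probability(m, self.WINDOW, na) - t
                for na, t in zip(self.NA_FAMILY, targets)])

        sol = least_squares(resid, [30, 30 / 278, 80, 80 / 318], method="lm")
        return np.abs(sol.fun).max()

    def test_moderate_heat_capacity_indistinguishable_in_window(self):
        # dCp = -0.5 kcal/(mol K): J(T) curves diverge far outside the
        # window but the refit P_o-T family matches within it
        assert self._max_po_difference(-0.5) < 0.02

    def test_difference_vanishes_with_heat_capacity(self):
        assert self._max_po_difference(-0.05) < 2e-3
        assert self._max_po_difference(-0.005) < 2e-4
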