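"""Forward model, transformations, rCO2 equations and normalization algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlw import (
    DomainError,
    DosePrep,
    KineticParams,
    PhysioParams,
    core,
)
from dlw.constants import ModelConstants


class TestEnrichment:
    def test_closed_form_value(self):
        # intercept above basal 300 ‰, k = 0.1/day, basal -50 ‰, t = 10 days
        N = 80.0 * 250.0 * 300.0 / (18.02 * 300.0 * 1.0)  # amplitude of 300 ‰
        dose = DosePrep(D=80.0, d=1.0, T=250.0, delta_dd=250.0, delta_T=-50.0)
        val = core.enrichment_at(10.0, dose, N, 0.1, -50.0)
        assert val == pytest.approx(300.0 * np.exp(-1.0) - 50.0, rel=1e-12)
        assert val == pytest.approx(60.3638, abs=1e-3)

    def test_strictly_decreasing_and_converges_to_basal(self, dose):
        t = np.linspace(0.0, 200.0, 500)
        y = core.enrichment_at(t, dose, 2500.0, 0.1, -50.0)
        assert np.all(np.diff(y) < 0)
        assert y[-1] == pytest.approx(-50.0, abs=1e-6)

    def test_zero_rate_stays_at_intercept(self, dose):
        y = core.enrichment_at(np.array([0.0, 5.0, 10.0]), dose, 2500.0, 0.0, -50.0)
        assert np.ptp(y) == 0.0

    def test_invalid_inputs_raise(self, dose):
        with pytest.raises(DomainError):
            core.enrichment_at(1.0, dose, -5.0, 0.1, -50.0)
        with pytest.raises(DomainError):
            core.enrichment_at(-1.0, dose, 2500.0, 0.1, -50.0)

    def test_amplitude_pool_inversion(self, dose):
        A = core.dose_amplitude(dose, 2500.0)
        assert core.pool_from_amplitude(dose, A) == pytest.approx(2500.0, rel=1e-14)


class TestTransformations:
    def test_table_space_ratio(self, constants):
        kin = KineticParams(N_H=2526.0, N_O=2446.0, k_H=0.0838, k_O=0.1098)
        phys = core.physio_from_kinetic(kin, 70.0, constants)
        assert phys.S == pytest.approx(1.0327, abs=5e-4)
        assert round(phys.S, 3) == 1.033

    def test_schoeller_alpha_reproduces_published_rco2(self, constants):
        # normalized exponential-fit kinetics; printed value 25.21 (input rounding)
        phys = core.physio_from_kinetic(
            KineticParams(N_H=2520.0, N_O=2437.0, k_H=0.0834, k_O=0.1088), 70.0, constants
        )
        assert phys.rCO2 == pytest.approx(25.23, abs=0.02)
        assert phys.rCO2 == pytest.approx(25.21, rel=0.003)

    def test_equal_pools_give_unit_ratio(self, constants):
        kin = KineticParams(N_H=2400.0, N_O=2400.0, k_H=0.08, k_O=0.11)
        assert core.physio_from_kinetic(kin, 70.0, constants).S == 1.0

    def test_inverse_matches_symbolic_oracle(self, constants):
        # frozen from an exact rational-arithmetic evaluation of the inverse
        phys = PhysioParams(rCO2=25.0, S=1.035, R_W=400.0, F=0.30)
        kin = core.kinetic_from_physio(phys, 70.0, constants)
        assert kin.N_H == pytest.approx(2073.30202476820, rel=1e-12)
        assert kin.k_H == pytest.approx(0.192928958357970, rel=1e-12)
        assert kin.N_O == pytest.approx(2003.19036209488, rel=1e-12)
        assert kin.k_O == pytest.approx(0.226875592354948, rel=1e-12)

    def test_round_trip_identity_over_prior_support(self, constants):
        rng = np.random.default_rng(12345)
        n_ok = 0
        for _ in range(1000):
            phys = PhysioParams(
                rCO2=rng.uniform(5.0, 40.0),
                S=rng.normal(1.035, 0.01),
                R_W=rng.uniform(80.0, 400.0),
                F=rng.uniform(0.1, 0.6),
            )
            W = rng.uniform(45.0, 120.0)
            kin = core.kinetic_from_physio(phys, W, constants)
            back = core.physio_from_kinetic(kin, W, constants)
            for a, b in zip(
                (phys.rCO2, phys.S, phys.R_W, phys.F),
                (back.rCO2, back.S, back.R_W, back.F),
            ):
                assert b == pytest.approx(a, rel=1e-10)
            assert kin.N_H / kin.N_O == pytest.approx(phys.S, rel=1e-14)
            n_ok += 1
        assert n_ok == 1000

    @given(
        rco2=st.floats(5.0, 40.0),
        s=st.floats(1.01, 1.07),
        rw=st.floats(80.0, 400.0),
        f=st.floats(0.08, 0.6),
        w=st.floats(45.0, 120.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_property(self, rco2, s, rw, f, w):
        c = ModelConstants()
        phys = PhysioParams(rCO2=rco2, S=s, R_W=rw, F=f)
        back = core.physio_from_kinetic(core.kinetic_from_physio(phys, w, c), w, c)
        assert back.rCO2 == pytest.approx(rco2, rel=1e-9, abs=1e-9)
        assert back.S == pytest.approx(s, rel=1e-9)

    def test_coward_model_round_trip(self):
        c = ModelConstants.coward()
        assert c.alpha2 < 0
        phys = PhysioParams(rCO2=22.0, S=1.04, R_W=200.0, F=0.35)
        back = core.physio_from_kinetic(core.kinetic_from_physio(phys, 80.0, c), 80.0, c)
        assert back.rCO2 == pytest.approx(22.0, rel=1e-10)


class TestRco2Equations:
    def test_coward_reproduces_published_natural_value(self, constants):
        kin = KineticParams(N_H=2519.0, N_O=2438.0, k_H=0.0834, k_O=0.1088)
        assert core.rco2_coward(kin, constants) == pytest.approx(25.27, abs=0.005)
        assert core.rco2_coward(kin, constants) == pytest.approx(25.23, rel=0.003)

    def test_schoeller_reproduces_published_normalized_value(self, constants):
        kin = KineticParams(N_H=2520.0, N_O=2437.0, k_H=0.0834, k_O=0.1088)
        assert core.rco2_schoeller(kin, constants) == pytest.approx(25.23, abs=0.005)
        assert core.rco2_schoeller(kin, constants) == pytest.approx(25.21, rel=0.003)

    def test_schoeller_denominator_constant(self, constants):
        assert constants.schoeller_denominator == pytest.approx(2.179, rel=1e-12)

    def test_zero_flux_difference(self, constants):
        kin = KineticParams(N_H=2500.0, N_O=2500.0 * 0.08 / 0.1, k_H=0.08, k_O=0.1)
        assert core.rco2_schoeller(kin, constants) == pytest.approx(0.0, abs=1e-12)
        expected = -27.3 * (constants.f2 - constants.f1) / constants.coward_denominator
        assert core.rco2_coward(kin, constants) == pytest.approx(expected, rel=1e-12)

    def test_coward_below_schoeller_when_fluxes_equal(self, constants):
        """At equal isotope effluxes the Coward offset term pulls rCO2 below zero."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            N_H = rng.uniform(1500, 3000)
            k_H = rng.uniform(0.05, 0.1)
            N_O = rng.uniform(1500, 3000)
            kin = KineticParams(N_H=N_H, N_O=N_O, k_H=k_H, k_O=k_H * N_H / N_O)
            assert core.rco2_schoeller(kin, constants) == pytest.approx(0.0, abs=1e-10)
            assert core.rco2_coward(kin, constants) < core.rco2_schoeller(kin, constants)


class TestWeir:
    def test_factor_rounds_to_532(self, constants):
        assert round(constants.weir_factor) == 532

    def test_published_tee_from_posterior_mean(self, constants):
        tee = core.weir_tee(25.99, 0.85, constants)
        assert tee == pytest.approx(13830, rel=1e-3)

    def test_linear_in_rco2_and_decreasing_in_rq(self, constants):
        assert core.weir_tee(0.0, 0.85) == 0.0
        assert core.weir_tee(20.0, 0.85) == pytest.approx(2 * core.weir_tee(10.0, 0.85))
        assert core.weir_tee(20.0, 0.75) > core.weir_tee(20.0, 0.85) > core.weir_tee(20.0, 0.95)

    def test_rq_out_of_range_raises(self):
        with pytest.raises(DomainError):
            core.weir_tee(20.0, 1.2)


class TestNormalization:
    @pytest.mark.parametrize("nh,no", [(2600.0, 2500.0), (1800.0, 1700.0), (3000.0, 2999.0)])
    def test_schoeller_fixes_ratio_exactly(self, nh, no):
        ch, co = core.normalize_spaces_schoeller(nh, no)
        assert ch / co == pytest.approx(1.03, rel=1e-14)

    def test_schoeller_hand_arithmetic(self):
        ch, co = core.normalize_spaces_schoeller(2600.0, 2500.0)
        assert ch == pytest.approx(2587.5, rel=1e-12)
        assert co == pytest.approx(2512.135922330097, rel=1e-12)

    def test_schoeller_fixed_point(self):
        ch, co = core.normalize_spaces_schoeller(1.03 * 2400.0, 2400.0)
        assert ch == pytest.approx(1.03 * 2400.0, rel=1e-12)
        assert co == pytest.approx(2400.0, rel=1e-12)

    @pytest.mark.parametrize("nh,no", [(2600.0, 2500.0), (2000.0, 1900.0)])
    def test_iaea_ratio_rounds_to_1034(self, nh, no):
        ch, co = core.normalize_spaces_iaea(nh, no)
        assert ch / co == pytest.approx(1.041 / 1.007, rel=1e-14)
        assert round(ch / co, 3) == 1.034

    def test_iaea_hand_arithmetic(self):
        ch, co = core.normalize_spaces_iaea(2600.0, 2500.0)
        assert ch == pytest.approx(2592.204568023833, rel=1e-12)
        assert co == pytest.approx(2507.540826128722, rel=1e-12)

    def test_iaea_fixed_point(self):
        ch, co = core.normalize_spaces_iaea(1.041 * 2400.0, 1.007 * 2400.0)
        assert ch == pytest.approx(1.041 * 2400.0, rel=1e-12)
        assert co == pytest.approx(1.007 * 2400.0, rel=1e-12)


class TestNormalizationShift:
    def test_zero_shift_at_natural_target(self, textbook_kin):
        S = textbook_kin.space_ratio
        assert core.normalization_tee_shift(textbook_kin, S) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_equals_direct_recomputation(self, constants):
        rng = np.random.default_rng(99)
        for _ in range(200):
            kin = KineticParams(
                N_H=rng.uniform(1500, 3000), N_O=rng.uniform(1500, 3000),
                k_H=rng.uniform(0.05, 0.12), k_O=rng.uniform(0.08, 0.16),
            )
            target = rng.uniform(1.02, 1.05)
            shift = core.normalization_tee_shift(kin, target, constants)
            no_prime = core.normalized_oxygen_space(kin.N_O, kin.space_ratio, target)
            kin_norm = KineticParams(
                N_H=target * no_prime, N_O=no_prime, k_H=kin.k_H, k_O=kin.k_O
            )
            direct = core.tee_from_fluxes(kin_norm, constants) - core.tee_from_fluxes(kin, constants)
            assert shift == pytest.approx(direct, rel=1e-12, abs=1e-9)

    def test_shift_sign_follows_ratio_vs_target(self, constants):
        low_S = KineticParams(N_H=1.015 * 2400.0, N_O=2400.0, k_H=0.08, k_O=0.11)
        high_S = KineticParams(N_H=1.055 * 2400.0, N_O=2400.0, k_H=0.08, k_O=0.11)
        assert core.normalization_tee_shift(low_S, 1.035, constants) < 0
        assert core.normalization_tee_shift(high_S, 1.035, constants) > 0
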