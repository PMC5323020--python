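"""Unit and property tests for the steady-state decoding model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ugadecode import (
    KineticParameters,
    ModelVariant,
    NMDParameters,
    mixture_half_life,
    nmd_alphas,
    predict_gfp,
    predict_proteins,
    rate_ratio_from_slope,
    resolve_state,
    sec_trna_pool,
    solve_free_mrna,
    uga_sec_fraction,
)
from conftest import random_valid_params


def bisect_free_mrna(params, m_total, Se):
    """Independent root of the conservation balance.

    Solves m_f·(1+kF) + k1·m_f·SeT_total/(1+k1·m_f) = m_total by
    bracketing on [0, m_total]; never uses the closed form.
    """
    if m_total == 0:
        return 0.0
    S = params.k3 * Se * params.T_total / (1.0 + params.k3 * Se)

    def residual(m_f):
        return m_f * (1.0 + params.kF) + params.k1 * m_f * S / (1.0 + params.k1 * m_f) - m_total

    return brentq(residual, 0.0, m_total, xtol=1e-14, rtol=1e-14)


class TestChargedPool:
    def test_zero_selenium_gives_empty_pool(self, demo_params):
        assert sec_trna_pool(demo_params, 0.0) == 0.0

    def test_saturates_at_total_pool(self):
        p = KineticParameters(k1=1, kF=1, k3=1, T_total=500, rho=1)
        assert sec_trna_pool(p, 100.0) == pytest.approx(500.0, rel=0.01)

    def test_closed_form_value(self, demo_params):
        # k3=10, T_total=500, Se=1 -> 10*500/(1+10) = 5000/11
        assert sec_trna_pool(demo_params, 1.0) == pytest.approx(5000 / 11, rel=1e-12)

    def test_monotone_in_selenium(self, demo_params):
        se = np.linspace(0, 50, 200)
        pool = sec_trna_pool(demo_params, se)
        assert np.all(np.diff(pool) >= 0)
        assert np.all(pool <= demo_params.T_total)

    def test_negative_selenium_rejected(self, demo_params):
        with pytest.raises(ValueError):
            sec_trna_pool(demo_params, -1.0)


class TestFreeMrna:
    def test_no_mrna(self, demo_params):
        assert solve_free_mrna(demo_params, 0.0, 1.0) == 0.0

    def test_small_k1_limit_is_rf_only_balance(self):
        p = KineticParameters(k1=1e-12, kF=0.5, k3=1, T_total=100, rho=1)
        m_f = solve_free_mrna(p, 900.0, 1.0)
        assert m_f == pytest.approx(900.0 / 1.5, rel=1e-6)

    def test_matches_bisection_oracle(self, demo_params):
        m_f = solve_free_mrna(demo_params, 1000.0, 1.0)
        oracle = bisect_free_mrna(demo_params, 1000.0, 1.0)
        assert m_f == pytest.approx(oracle, rel=1e-8)

    def test_oracle_agreement_over_random_tuples(self, rng):
        for p in random_valid_params(rng, 200):
            m_total = 10.0 ** rng.uniform(0, 3.7)
            Se = 10.0 ** rng.uniform(-1, 3)
            closed = solve_free_mrna(p, m_total, Se)
            oracle = bisect_free_mrna(p, m_total, Se)
            assert closed == pytest.approx(oracle, rel=1e-8, abs=1e-12)

    def test_monotone_in_m_total(self, demo_params):
        m = np.linspace(0, 4000, 400)
        m_f = solve_free_mrna(demo_params, m, 1.0)
        assert np.all(np.diff(m_f) >= 0)
        assert np.all(m_f <= m)

    def test_nonfinite_rejected(self, demo_params):
        with pytest.raises(ValueError):
            solve_free_mrna(demo_params, float("nan"), 1.0)

    def test_strict_printed_quadratic_mode(self, demo_params):
        # The as-printed form replaces the saturating pool with Se*T_total;
        # it must solve its own quadratic but differ from the default.
        m_default = solve_free_mrna(demo_params, 1000.0, 1.0)
        m_strict = solve_free_mrna(demo_params, 1000.0, 1.0, strict_eq16=True)
        assert m_strict != pytest.approx(m_default, rel=1e-3)
        p, S = demo_params, 1.0 * demo_params.T_total
        resid = (
            p.k1 * (1 + p.kF) * m_strict**2
            + ((1 + p.kF) + p.k1 * (S - 1000.0)) * m_strict
            - 1000.0
        )
        assert resid == pytest.approx(0.0, abs=1e-6)


class TestConservation:
    def test_conservation_on_random_states(self, rng):
        for p in random_valid_params(rng, 300):
            m_total = 10.0 ** rng.uniform(0, 3.7)
            Se = 10.0 ** rng.uniform(-2, 3)
            st_ = resolve_state(p, m_total, Se)
            assert st_.m_f + st_.m_SeT + st_.m_RF == pytest.approx(m_total, rel=1e-9)
            assert st_.SeT_f + st_.m_SeT == pytest.approx(st_.SeT_total, rel=1e-9)
            assert st_.T_uncharged + st_.SeT_total == pytest.approx(p.T_total, rel=1e-9)
            for field in ("m_f", "m_SeT", "m_RF", "SeT_f", "T_uncharged", "P_L", "P_S"):
                assert getattr(st_, field) >= 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        logk1=st.floats(-2, 2),
        logkF=st.floats(-2, 4),
        logk3=st.floats(-2, 2),
        logT=st.floats(1, 3),
        logm=st.floats(0, 3.6),
        logse=st.floats(-2, 3),
    )
    def test_conservation_property(self, logk1, logkF, logk3, logT, logm, logse):
        p = KineticParameters(
            k1=10.0**logk1, kF=10.0**logkF, k3=10.0**logk3,
            T_total=10.0**logT, rho=10.0,
        )
        st_ = resolve_state(p, 10.0**logm, 10.0**logse)
        assert st_.m_f + st_.m_SeT + st_.m_RF == pytest.approx(st_.m_total, rel=1e-9)


class TestProteins:
    def test_zero_selenium_collapse(self, demo_params):
        P_L, P_S = predict_proteins(demo_params, 1000.0, 0.0)
        assert P_L == 0.0
        expected = demo_params.rho * demo_params.SP_S * 1000.0
        assert P_S == pytest.approx(expected, rel=1e-9)

    def test_ratio_monotone_in_mrna_and_selenium(self, demo_params):
        m = np.linspace(1, 4000, 100)
        P_L, P_S = predict_proteins(demo_params, m, 1.0)
        ratio = P_L / P_S
        assert np.all(np.diff(ratio) <= 1e-12)
        se = np.linspace(0.01, 10, 100)
        P_L, P_S = predict_proteins(demo_params, 1000.0, se)
        assert np.all(np.diff(P_L / P_S) >= -1e-12)

    def test_none_variant_linear_in_mrna(self, demo_params):
        m = np.linspace(1, 4000, 50)
        P_L, P_S = predict_proteins(demo_params, m, 2.0, variant="none")
        for arr in (P_L, P_S):
            per_m = arr / m
            assert np.allclose(per_m, per_m[0], rtol=1e-12)

    def test_saturation_limit_matches_full_pool_substitution(self, demo_params):
        # As Se -> inf the charged pool tends to T_total; P_L must approach
        # the value obtained by substituting SeT_total = T_total directly.
        p = demo_params
        P_L_inf, _ = predict_proteins(p, 500.0, 1e8)
        S = p.T_total
        # direct substitution: quadratic with the saturated pool
        a = p.k1 * (1 + p.kF)
        b = (1 + p.kF) + p.k1 * (S - 500.0)
        m_f = (-b + np.sqrt(b * b + 4 * a * 500.0)) / (2 * a)
        SeT_f = S / (1 + p.k1 * m_f)
        expected = rate_ratio_from_slope(p.SP_L, p.rho, p.kF) * p.k1 * m_f * SeT_f
        assert P_L_inf == pytest.approx(expected, rel=1e-4)

    def test_full_matches_mrna_only_when_charging_is_linear(self):
        # For k3*Se << 1 the pool saturation is negligible and the full
        # model coincides with the unlimited-tRNA variant.
        p = KineticParameters(k1=1.0, kF=10.0, k3=1e-6, T_total=500, rho=10)
        m = np.linspace(1, 4000, 20)
        full = predict_gfp(p, m * p.rho * p.rho_p, 5.0, "full")
        mrna = predict_gfp(p, m * p.rho * p.rho_p, 5.0, "mrna_only")
        assert np.allclose(full, mrna, rtol=1e-5)


class TestObservableGfp:
    def test_zero_rfp(self, demo_params):
        assert predict_gfp(demo_params, 0.0, 1.0) == 0.0

    def test_slope_non_increasing_under_full(self, demo_params):
        rfp = np.linspace(1, 4000, 300) * demo_params.rho * demo_params.rho_p
        gfp = predict_gfp(demo_params, rfp, 8.0)
        slopes = np.diff(gfp) / np.diff(rfp)
        assert np.all(np.diff(slopes) <= 1e-9)

    def test_none_variant_exactly_linear(self, demo_params):
        rfp = np.linspace(1, 4000, 100) * demo_params.rho * demo_params.rho_p
        for se in (0.0, 1.0, 10.0):
            gfp = predict_gfp(demo_params, rfp, se, "none")
            slope = gfp / rfp
            assert np.allclose(slope, slope[0], rtol=1e-9)

    def test_gfp_non_decreasing_in_selenium(self, demo_params):
        rfp = np.linspace(1, 4000, 50) * demo_params.rho * demo_params.rho_p
        prev = np.zeros_like(rfp)
        for se in (0.0, 0.1, 1.0, 10.0, 100.0):
            gfp = np.asarray(predict_gfp(demo_params, rfp, se))
            assert np.all(gfp >= prev - 1e-9)
            prev = gfp


class TestSecFraction:
    def test_zero_selenium(self, demo_params):
        assert uga_sec_fraction(demo_params, 100.0, 0.0) == 0.0

    def test_negligible_release_factor_term(self):
        p = KineticParameters(k1=1.0, kF=1e-12, k3=1.0, T_total=100, rho=1)
        assert uga_sec_fraction(p, 10.0, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_decreasing_in_mrna_load(self, demo_params):
        m = np.linspace(1, 4000, 200)
        eta = uga_sec_fraction(demo_params, m, 1.0)
        assert np.all(np.diff(eta) <= 0)
        assert np.all((eta >= 0) & (eta <= 1))


class TestNmd:
    def test_disabled_returns_unity_without_eta(self):
        assert nmd_alphas(NMDParameters(enabled=False), eta=0.0) == (1.0, 1.0)

    def test_alpha_L_is_escape_probability(self):
        a_L, _ = nmd_alphas(NMDParameters(True, e0=0.0, N=10), eta=0.9)
        assert a_L == 1.0

    def test_printed_formula_value(self):
        # e0=0.1, N=11, eta=0.5: z=(N-1)*eta=5
        # alpha_S = 1 - 1/5 - 0.1*5/6 = 0.71666...
        _, a_S = nmd_alphas(NMDParameters(True, e0=0.1, N=11), eta=0.5)
        assert a_S == pytest.approx(1 - 1 / 5 - 0.5 / 6, rel=1e-12)

    def test_singular_inputs_rejected(self):
        with pytest.raises(ValueError):
            nmd_alphas(NMDParameters(True, e0=0.1, N=5), eta=0.0)
        with pytest.raises(ValueError):
            NMDParameters(True, e0=0.1, N=1.0)

    def test_enabled_state_self_consistent(self, demo_params):
        nmd = NMDParameters(True, e0=0.05, N=20)
        st_ = resolve_state(demo_params, 1000.0, 1.0, nmd=nmd)
        baseline = resolve_state(demo_params, 1000.0, 1.0)
        assert st_.P_S <= baseline.P_S  # decay removes truncated output
        assert st_.m_f + st_.m_SeT + st_.m_RF == pytest.approx(1000.0, rel=1e-9)


class TestHalfLifeMixture:
    @pytest.mark.parametrize(
        "x,lam_L,lam_S,expected",
        [(1.0, 0.3, 2.0, 0.3), (0.0, 0.3, 2.0, 2.0), (0.5, 1.0, 3.0, 1.5)],
    )
    def test_values(self, x, lam_L, lam_S, expected):
        assert mixture_half_life(x, lam_L, lam_S) == pytest.approx(expected, rel=1e-12)

    def test_bounded_between_component_rates(self):
        lam = mixture_half_life(0.3, 0.2, 5.0)
        assert 0.2 <= lam <= 5.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            mixture_half_life(1.5, 1.0, 2.0)


class TestRateRatio:
    def test_direct_substitution(self):
        assert rate_ratio_from_slope(1.0, 1.0, 1.0) == 2.0

    def test_homogeneous_in_slope_and_rho(self):
        base = rate_ratio_from_slope(2.0, 3.0, 0.5)
        assert rate_ratio_from_slope(4.0, 3.0, 0.5) == pytest.approx(2 * base)
        assert rate_ratio_from_slope(2.0, 6.0, 0.5) == pytest.approx(2 * base)

    def test_published_scale_within_physiological_range(self):
        # Near the published SEPHS2 optimum the synthesis/degradation
        # ratio must land in the 1e-3..1e4 physiological range.
        value = rate_ratio_from_slope(7.0, 10.40, 9803.03)
        assert 1e-3 <= value <= 1e4

    def test_zero_kF_rejected(self):
        with pytest.raises(ValueError):
            rate_ratio_from_slope(1.0, 1.0, 0.0)


class TestAblationSignatures:
    def test_trna_only_collapses_across_selenium(self, demo_params):
        rfp = np.linspace(1, 4000, 60) * demo_params.rho * demo_params.rho_p
        curves = [
            np.asarray(predict_gfp(demo_params, rfp, se, "trna_only"))
            for se in (8.0, 40.0, 200.0, 1000.0)
        ]
        spread = (np.max(curves, axis=0) - np.min(curves, axis=0)) / np.max(curves, axis=0)
        assert spread[-1] < 0.02  # beyond tRNA exhaustion the curves merge

    def test_mrna_only_ratio_grows_linearly_in_selenium(self, demo_params):
        se = np.array([1e3, 2e3, 4e3])
        P_L, P_S = predict_proteins(demo_params, 1000.0, se, "mrna_only")
        ratio = P_L / P_S
        growth = ratio[1:] / ratio[:-1]
        assert np.all(growth > 1.8)  # ~doubles when selenium doubles

    def test_full_ratio_saturates_in_selenium(self, demo_params):
        P_L, P_S = predict_proteins(demo_params, 1000.0, np.array([100.0, 1000.0]), "full")
        ratio = P_L / P_S
        assert ratio[1] / ratio[0] < 1.01


class TestParameterValidation:
    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            KineticParameters(k1=0.0, kF=1, k3=1, T_total=100, rho=1)

    def test_inverted_stability_warns(self):
        with pytest.warns(UserWarning):
            KineticParameters(k1=1, kF=1, k3=1, T_total=100, rho=1, SP_L=0.5, SP_S=0.7)
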