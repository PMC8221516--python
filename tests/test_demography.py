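"""Matrix demography: habitat coefficients, lambda, sensitivities,
elasticities, the source-sink threshold, and vital-rate mixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avirisk.demography import (
    HabitatCoefficients,
    PatchState,
    PesticideEffect,
    VitalRates,
    build_projection_matrix,
    elasticities,
    finite_rate,
    habitat_coefficient,
    mix_vital,
    patch_step,
    sensitivities,
    source_sink_threshold,
)

vitals_st = st.builds(
    VitalRates,
    s_j=st.floats(0.01, 1.0),
    s_a=st.floats(0.01, 1.0),
    f=st.floats(0.0, 5.0),
)


class TestHabitatCoefficient:
    @pytest.mark.parametrize(
        "q, alpha, expected",
        [(1.0, 5.0, 1.0), (0.0, 3.0, 0.0), (0.5, 5.0, 0.96875)],
    )
    def test_values(self, q, alpha, expected):
        assert habitat_coefficient(q, alpha) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            habitat_coefficient(1.2, 3.0)
        with pytest.raises(ValueError):
            habitat_coefficient(-0.1, 3.0)
        with pytest.raises(ValueError):
            habitat_coefficient(0.5, 0.5)

    @given(
        q1=st.floats(0.0, 1.0),
        q2=st.floats(0.0, 1.0),
        alpha=st.floats(1.0, 10.0),
    )
    @settings(deadline=None)
    def test_monotone_in_quality(self, q1, q2, alpha):
        lo, hi = sorted((q1, q2))
        assert habitat_coefficient(lo, alpha) <= habitat_coefficient(hi, alpha)

    @given(q=st.floats(0.001, 0.999), a1=st.floats(1.0, 5.0), a2=st.floats(1.0, 5.0))
    @settings(deadline=None)
    def test_monotone_in_exponent(self, q, a1, a2):
        # larger alpha -> larger coefficient for interior q (c rises faster)
        lo, hi = sorted((a1, a2))
        assert habitat_coefficient(q, lo) <= habitat_coefficient(q, hi) + 1e-12


class TestProjectionMatrix:
    def test_best_habitat_matrix(self, table_vitals):
        m = build_projection_matrix(table_vitals, q=1.0)
        expected = np.array([[0.974964, 1.1752], [0.4314, 0.52]])
        np.testing.assert_allclose(m, expected, atol=1e-12)

    def test_neutral_effect_is_identity(self, table_vitals):
        base = build_projection_matrix(table_vitals, q=1.0)
        neutral = build_projection_matrix(
            table_vitals, q=1.0, effect=PesticideEffect(s_p=1.0, f_e=table_vitals.f)
        )
        assert np.array_equal(base, neutral)

    def test_zero_quality_zero_matrix(self, table_vitals):
        assert np.all(build_projection_matrix(table_vitals, q=0.0) == 0.0)

    @given(vitals=vitals_st, q=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_rank_deficient(self, vitals, q):
        m = build_projection_matrix(vitals, q=q)
        assert abs(np.linalg.det(m)) < 1e-9


class TestFiniteRate:
    def test_table_vitals_growth_rate(self, table_vitals):
        lam = finite_rate(build_projection_matrix(table_vitals, q=1.0))
        assert round(lam, 3) == 1.495

    def test_degenerate_no_juvenile_survival(self):
        m = build_projection_matrix(VitalRates(s_j=0.0, s_a=0.52, f=2.26), q=1.0)
        assert finite_rate(m) == pytest.approx(0.52, abs=1e-12)

    @given(data=st.lists(st.floats(0.01, 5.0), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=50)
    def test_matches_power_iteration(self, data):
        m = np.array(data).reshape(2, 2)
        v = np.ones(2)
        for _ in range(2000):
            v = m @ v
            v /= np.linalg.norm(v)
        lam_power = float(v @ m @ v)
        assert finite_rate(m) == pytest.approx(lam_power, abs=1e-10)

    @given(vitals=vitals_st, q=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_closed_form(self, vitals, q):
        coeffs = HabitatCoefficients()
        lam = finite_rate(build_projection_matrix(vitals, q=q, coeffs=coeffs))
        closed = coeffs.c_s(q) * (
            vitals.s_a + vitals.s_j * vitals.f * coeffs.c_f(q)
        )
        assert lam == pytest.approx(closed, abs=1e-10)

    def test_rejects_negative_matrix(self):
        with pytest.raises(ValueError):
            finite_rate(np.array([[1.0, -0.1], [0.2, 0.3]]))


class TestSensitivitiesElasticities:
    def test_sensitivity_values(self, table_vitals):
        d_sa, d_f, d_sj = sensitivities(table_vitals)
        assert d_sa == 1.0
        assert d_f == 0.4314
        assert d_sj == 2.26

    @given(vitals=vitals_st)
    @settings(deadline=None, max_examples=30)
    def test_sensitivities_match_finite_differences(self, vitals):
        h = 1e-6

        def lam(s_j, s_a, f):
            return finite_rate(build_projection_matrix(VitalRates(s_j, s_a, f), q=1.0))

        sj, sa, f = vitals.s_j, vitals.s_a, vitals.f
        sa_lo, sa_hi = max(sa - h, 0.0), min(sa + h, 1.0)
        fd_sa = (lam(sj, sa_hi, f) - lam(sj, sa_lo, f)) / (sa_hi - sa_lo)
        fd_f = (lam(sj, sa, f + h) - lam(sj, sa, max(f - h, 0.0))) / (
            f + h - max(f - h, 0.0)
        )
        d_sa, d_f, _ = sensitivities(vitals)
        assert fd_sa == pytest.approx(d_sa, abs=1e-5)
        assert fd_f == pytest.approx(d_f, abs=1e-5)

    def test_elasticity_values(self, table_vitals):
        e_sa, e_f = elasticities(table_vitals)
        assert round(e_sa, 2) == 0.35
        assert round(e_f, 2) == 0.65

    @given(vitals=vitals_st)
    @settings(deadline=None, max_examples=50)
    def test_elasticities_sum_to_one(self, vitals):
        e_sa, e_f = elasticities(vitals)
        assert e_sa + e_f == pytest.approx(1.0, abs=1e-12)

    def test_zero_lambda_raises(self):
        with pytest.raises(ValueError):
            elasticities(VitalRates(s_j=0.5, s_a=0.0, f=0.0))


class TestSourceSinkThreshold:
    def test_gnatcatcher_threshold(self, table_vitals):
        q_star = source_sink_threshold(
            table_vitals, HabitatCoefficients(alpha_f=3.0, alpha_s=5.0)
        )
        assert q_star == pytest.approx(0.3136, abs=1e-3)
        # printed two-decimal approximation
        assert abs(q_star - 0.32) < 0.01

    def test_no_root_raises(self):
        with pytest.raises(ValueError):
            source_sink_threshold(VitalRates(s_j=0.1, s_a=0.3, f=0.5))

    @given(vitals=vitals_st)
    @settings(deadline=None, max_examples=30)
    def test_threshold_is_a_root(self, vitals):
        coeffs = HabitatCoefficients()
        lam1 = coeffs.c_s(1.0) * (vitals.s_a + vitals.s_j * vitals.f)
        if lam1 <= 1.0 + 1e-9:
            return
        q_star = source_sink_threshold(vitals, coeffs)
        lam = finite_rate(build_projection_matrix(vitals, q=q_star, coeffs=coeffs))
        assert lam == pytest.approx(1.0, abs=1e-4)


class TestMixVital:
    @pytest.mark.parametrize(
        "p, v_e, v_u, expected",
        [(0.0, 123.0, 2.26, 2.26), (1.0, 0.0, 2.26, 0.0), (0.4, 0.0, 2.26, 1.356)],
    )
    def test_values(self, p, v_e, v_u, expected):
        assert mix_vital(p, v_e, v_u) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            mix_vital(1.5, 0.0, 1.0)

    @given(
        p=st.floats(0.0, 1.0), v_e=st.floats(0.0, 5.0), v_u=st.floats(0.0, 5.0)
    )
    @settings(deadline=None)
    def test_bounded_by_endpoints(self, p, v_e, v_u):
        mixed = mix_vital(p, v_e, v_u)
        assert min(v_e, v_u) - 1e-12 <= mixed <= max(v_e, v_u) + 1e-12


class TestPatchStep:
    def test_one_year_best_habitat(self, table_vitals):
        m = build_projection_matrix(table_vitals, q=1.0)
        new = patch_step(PatchState(10.0, 10.0), m)
        assert new.n_j == pytest.approx(21.50164, abs=1e-5)
        assert new.n_a == pytest.approx(9.514, abs=1e-9)

    def test_zero_state_absorbing(self, table_vitals):
        m = build_projection_matrix(table_vitals, q=1.0)
        new = patch_step(PatchState(0.0, 0.0), m)
        assert new.n_j == 0.0 and new.n_a == 0.0

    def test_linear_in_multiplier(self, table_vitals):
        m = build_projection_matrix(table_vitals, q=0.7)
        base = patch_step(PatchState(3.0, 5.0), m, env_multiplier=1.0)
        up = patch_step(PatchState(3.0, 5.0), m, env_multiplier=1.1)
        assert up.n_j == pytest.approx(1.1 * base.n_j, rel=1e-12)
        assert up.n_a == pytest.approx(1.1 * base.n_a, rel=1e-12)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            PatchState(-1.0, 0.0)
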