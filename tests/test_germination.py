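"""Dormancy model: rates, anchors, probabilities, fitting, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedlife.germination import (
    GerminationModelError,
    GerminationParams,
    dormancy_probabilities,
    fit_germination_params,
    germination_probability,
    infer_maturation_temperature,
    offsets,
    primary_dormancy,
    primary_rate,
    secondary_dormancy,
    secondary_rate,
    select_rate_model,
)
from seedlife.synthetic import SyntheticAssaySpec, synth_germination_assays


class TestRates:
    @pytest.mark.parametrize(
        "t_m,expected", [(15.0, 1.61), (12.0, -3.07), (18.0, 6.29)]
    )
    def test_primary_rate_linear_in_tm(self, params, t_m, expected):
        assert primary_rate(t_m, params) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "t_i,expected", [(4.0, 0.05 * np.exp(0.72)), (20.0, 0.05 * np.exp(3.6))]
    )
    def test_secondary_rate_exponential_in_ti(self, params, t_i, expected):
        assert secondary_rate(t_i, params) == pytest.approx(expected)

    def test_secondary_rate_strictly_increasing(self, params):
        ti = np.linspace(0, 30, 200)
        assert np.all(np.diff(secondary_rate(ti, params)) > 0)

    def test_dormancy_switch_near_14(self, params):
        # the zero of Rp is an emergent switch between dormant and
        # non-dormant progeny; with the published constants it sits at
        # -b/a = 21.79/1.56
        assert params.switch_temperature == pytest.approx(21.79 / 1.56)
        assert 13.5 <= params.switch_temperature <= 14.5

    def test_invalid_params_rejected(self):
        with pytest.raises(GerminationModelError):
            GerminationParams(a=-1.0, b=0.0, c=0.05, d=0.18)
        with pytest.raises(GerminationModelError):
            GerminationParams(a=1.0, b=0.0, c=-0.05, d=0.18)


class TestOffsets:
    def test_closed_forms(self):
        o = offsets(1.61, 0.4336)
        assert o.a_p == pytest.approx(-np.log(99) / 1.61)
        assert o.a_s == pytest.approx(-np.log(99) / 0.4336)

    @pytest.mark.parametrize("r_p", [-3.07, -0.5, 0.3, 1.61, 6.29])
    @pytest.mark.parametrize("r_s", [0.05, 0.4336, 1.83])
    def test_anchors_hold_for_any_nonzero_rates(self, r_p, r_s):
        o = offsets(r_p, r_s)
        p_p0 = 1.0 / (1.0 + np.exp(r_p * (0.0 + o.a_p)))
        p_s0 = 1.0 - 1.0 / (1.0 + np.exp(r_s * (0.0 + o.a_s)))
        assert p_p0 == pytest.approx(0.99, abs=1e-12)
        assert p_s0 == pytest.approx(0.01, abs=1e-12)

    def test_zero_primary_rate_limit(self):
        o = offsets(0.0, 0.5)
        assert o.a_p is None
        assert float(primary_dormancy(100.0, 0.0)) == pytest.approx(0.99, abs=1e-12)

    def test_nonpositive_secondary_rate_rejected(self):
        with pytest.raises(GerminationModelError):
            offsets(1.0, 0.0)
        with pytest.raises(GerminationModelError):
            offsets(1.0, -0.1)


class TestDormancyProbabilities:
    def test_fresh_seed_anchor_state(self, params):
        s = dormancy_probabilities(0.0, 16.0, 10.0, params)
        assert s.p_primary == pytest.approx(0.99, abs=1e-12)
        assert s.p_secondary == pytest.approx(0.01, abs=1e-12)
        assert s.p_dormant == pytest.approx(0.9901, abs=1e-12)
        assert s.p_germ == pytest.approx(0.0099, abs=1e-12)

    def test_cold_stratification_releases_dormancy(self, params):
        # warm-matured seed, cold imbibition: primary dormancy collapses,
        # little secondary dormancy -> high germination
        s = dormancy_probabilities(14.0, 15.0, 4.0, params)
        assert s.p_primary == pytest.approx(1.61e-8, rel=0.01)
        assert s.p_secondary == pytest.approx(0.0408, rel=0.01)
        assert s.p_germ == pytest.approx(0.959, abs=0.001)

    def test_warm_imbibition_induces_secondary_dormancy(self, params):
        s = dormancy_probabilities(14.0, 15.0, 12.0, params)
        assert s.p_secondary == pytest.approx(0.814, abs=0.001)
        assert s.p_germ == pytest.approx(0.186, abs=0.001)

    def test_cool_matured_seed_stays_dormant(self, params):
        # below the switch Rp < 0: primary dormancy deepens instead of lifting
        for x in (7.0, 28.0, 42.0):
            assert dormancy_probabilities(x, 12.0, 4.0, params).p_germ < 0.05

    def test_negative_time_rejected(self, params):
        with pytest.raises(GerminationModelError):
            dormancy_probabilities(-1.0, 15.0, 4.0, params)

    @given(
        x=st.floats(0, 60),
        t_m=st.floats(8, 22),
        t_i=st.floats(0, 25),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_disjunction_equals_complement_form(self, params, x, t_m, t_i):
        # P(Dp) + P(Ds) - P(Dp)P(Ds) == 1 - (1-P(Dp))(1-P(Ds))
        s = dormancy_probabilities(x, t_m, t_i, params)
        assert s.p_dormant == pytest.approx(
            1.0 - (1.0 - s.p_primary) * (1.0 - s.p_secondary), abs=1e-12
        )
        assert s.p_germ == pytest.approx(1.0 - s.p_dormant, abs=1e-12)
        for p in (s.p_primary, s.p_secondary, s.p_dormant, s.p_germ):
            assert 0.0 <= p <= 1.0

    def test_secondary_monotone_in_time(self, params):
        x = np.linspace(0, 60, 300)
        for t_i in (4.0, 12.0, 20.0):
            p = secondary_dormancy(x, secondary_rate(t_i, params))
            assert np.all(np.diff(p) >= 0)

    def test_primary_monotone_direction_set_by_rate_sign(self, params):
        x = np.linspace(0, 60, 300)
        lifting = primary_dormancy(x, primary_rate(16.0, params))   # Rp > 0
        deepening = primary_dormancy(x, primary_rate(12.0, params))  # Rp < 0
        assert np.all(np.diff(lifting) <= 0)
        assert np.all(np.diff(deepening) >= 0)

    def test_germination_monotone_in_tm_across_switch(self, params):
        tm = np.linspace(10.0, 18.0, 50)
        p = germination_probability(14.0, tm, 8.0, params)
        assert np.all(np.diff(p) >= -1e-12)


class TestFitting:
    def test_noise_free_recovery_is_fixed_point(self, params, noise_free_assays):
        fit = fit_germination_params(noise_free_assays)
        for name in "abcd":
            got, want = getattr(fit.params, name), getattr(params, name)
            assert got == pytest.approx(want, rel=0.01), name
        assert fit.r_squared > 0.999

    def test_binomial_noise_recovery(self, params):
        spec = SyntheticAssaySpec(params=params, n_seeds=50, replicates=5, seed=7)
        fit = fit_germination_params(synth_germination_assays(spec))
        for name in "abcd":
            got, want = getattr(fit.params, name), getattr(params, name)
            assert got == pytest.approx(want, rel=0.15), name

    def test_single_cell_design_rejected(self, params):
        spec = SyntheticAssaySpec(
            params=params, t_m_levels=(15.0,), t_i_levels=(4.0,), noise=False
        )
        with pytest.raises(GerminationModelError):
            fit_germination_params(synth_germination_assays(spec))


class TestModelSelection:
    def test_parameter_counts_match_grid(self, noise_free_assays):
        specs = select_rate_model(noise_free_assays)
        assert len(specs) == 9
        by_combo = {(s.primary_form, s.secondary_form): s.n_params for s in specs}
        assert by_combo[("linear", "exponential")] == 4
        assert by_combo[("logistic", "logistic")] == 6
        # lin/lin, lin/exp, exp/lin, exp/exp are 4; one combo of each with
        # logistic is 5; logistic/logistic is 6
        assert sorted(by_combo.values()) == [4, 4, 4, 4, 5, 5, 5, 5, 6]

    def test_true_form_attains_top_r2(self, noise_free_assays):
        # data generated from a linear-primary / exponential-secondary truth
        specs = select_rate_model(noise_free_assays)
        best = max(s.r_squared for s in specs if np.isfinite(s.r_squared))
        linexp = next(
            s for s in specs
            if (s.primary_form, s.secondary_form) == ("linear", "exponential")
        )
        assert linexp.r_squared >= best - 0.01
        assert linexp.r_squared > 0.999

    def test_ranking_breaks_ties_by_parsimony(self, noise_free_assays):
        specs = select_rate_model(noise_free_assays)
        r2 = [s.r_squared if np.isfinite(s.r_squared) else -np.inf for s in specs]
        assert all(a >= b - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_degenerate_data_reports_nan_without_crash(self, params):
        from seedlife.germination import GerminationAssay

        assays = [
            GerminationAssay(
                t_m=t_m, t_i=t_i,
                times=np.array([3.0, 7.0, 14.0]),
                germinated=np.zeros(3), total=np.full(3, 50.0),
            )
            for t_m in (10.0, 11.0, 12.0)
            for t_i in (4.0, 8.0, 12.0)
        ]
        specs = select_rate_model(assays)
        assert all(np.isnan(s.r_squared) for s in specs)


class TestInferTm:
    def _lot(self, params, t_m):
        spec = SyntheticAssaySpec(params=params, t_m_levels=(t_m,), noise=False)
        return synth_germination_assays(spec)

    @pytest.mark.parametrize("t_m", [14.5, 15.0, 16.0, 18.0])
    def test_noise_free_inversion_recovery(self, params, t_m):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = infer_maturation_temperature(self._lot(params, t_m), params)
        assert est.t_m == pytest.approx(t_m, abs=0.1)
        if t_m <= 16.0:
            # well-identified regime: primary dormancy kinetics still
            # discriminate nearby maturation temperatures
            assert not est.flat_objective

    def test_all_dormant_lot_flags_flat_objective(self, params):
        with pytest.warns(UserWarning, match="flat"):
            est = infer_maturation_temperature(self._lot(params, 12.0), params)
        assert est.t_m <= 14.0
        assert est.flat_objective
        assert est.interval[1] - est.interval[0] > 2.0

    def test_invariant_to_duplicated_rows(self, params):
        lot = self._lot(params, 16.0)
        est1 = infer_maturation_temperature(lot, params)
        est2 = infer_maturation_temperature(lot + lot, params)
        assert est1.t_m == pytest.approx(est2.t_m, abs=1e-9)
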