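"""Life-history chaining, sweeps, progeny maps, cohorts and scenarios."""

import datetime as dt

import numpy as np
import pytest

from seedlife.climate import shift_series
from seedlife.simulator import (
    GenotypeConfig,
    SimulationError,
    annual_sweep,
    cohort_summary,
    progeny_germination,
    progeny_map,
    seed_set_spread,
    simulate_life_history,
    warming_scenarios,
    _shedding_weights,
)
from seedlife.phenology import BoltingModelConfig, ThermalModelParams
from seedlife.synthetic import SyntheticClimateSpec, synth_climate

from conftest import constant_climate


class TestLifeHistory:
    def test_stub_chain_closed_form(self, stub_genotype):
        # 30 d stub bolting + 5370/(24*14.75) = 15.2 d seed set at 20 degC
        clim = constant_climate(20.0)
        r = simulate_life_history(clim, dt.date(2001, 1, 1), stub_genotype)
        assert r.status == "completed"
        assert r.bolting_date == dt.date(2001, 1, 31)
        total = (r.first_seed_set_date - r.germination_date).days
        assert total == pytest.approx(30 + 5370 / (24 * 14.75), abs=1.0)
        assert r.t_m == pytest.approx(20.0)

    def test_event_ordering_invariant(self, surrogate_genotype, sinusoidal_climate):
        for month in (3, 6, 10):
            r = simulate_life_history(
                sinusoidal_climate, dt.date(2001, month, 1), surrogate_genotype
            )
            if r.status == "completed":
                assert r.germination_date <= r.bolting_date <= r.first_seed_set_date

    def test_warming_never_delays_seed_set(self, surrogate_genotype, sinusoidal_climate):
        r0 = simulate_life_history(sinusoidal_climate, dt.date(2001, 10, 1), surrogate_genotype)
        r2 = simulate_life_history(
            shift_series(sinusoidal_climate, 2.0), dt.date(2001, 10, 1), surrogate_genotype
        )
        assert r2.first_seed_set_date <= r0.first_seed_set_date

    def test_cold_climate_does_not_complete(self, surrogate_genotype):
        clim = constant_climate(2.0, n_years=3)  # below both base temperatures
        r = simulate_life_history(clim, dt.date(2001, 10, 1), surrogate_genotype)
        assert r.status == "did_not_complete"
        assert r.first_seed_set_date is None and r.t_m is None


class TestAnnualSweep:
    def test_constant_climate_translation_invariance(self, stub_genotype):
        clim = constant_climate(18.0)
        dates = [dt.date(2001, m, 1) for m in range(1, 13)]
        results = annual_sweep(clim, dates, stub_genotype)
        durations = {
            (r.first_seed_set_date - r.germination_date).days
            for r in results
            if r.status == "completed"
        }
        assert len(durations) == 1

    def test_shape_contract_weekly_grid(self, surrogate_genotype, sinusoidal_climate):
        dates = [dt.date(2001, 1, 1) + dt.timedelta(weeks=k) for k in range(52)]
        results = annual_sweep(sinusoidal_climate, dates, surrogate_genotype)
        assert len(results) == 52
        assert [r.germination_date for r in results] == dates

    def test_autumn_to_spring_seed_set_compression(self, surrogate_genotype,
                                                   sinusoidal_climate):
        # germination dates spread over ~7 months funnel onto a much
        # narrower seed-set window (the winter-annual convergence)
        dates = [dt.date(2001, 10, 1) + dt.timedelta(days=14 * k) for k in range(16)]
        results = annual_sweep(sinusoidal_climate, dates, surrogate_genotype)
        done = [r for r in results if r.status == "completed"]
        assert len(done) >= 10
        sow_spread = np.std([r.germination_date.toordinal() for r in done])
        set_spread = seed_set_spread(done)
        assert set_spread < sow_spread


class TestProgeny:
    def test_cool_maturation_blocks_germination(self, stub_genotype):
        # at 12 degC the primary-dormancy rate is negative: deep dormancy
        clim = constant_climate(12.0)
        r = simulate_life_history(clim, dt.date(2001, 1, 1), stub_genotype)
        frac = progeny_germination(r, clim, stub_genotype.germination)
        assert frac < 0.05

    def test_warm_maturation_cold_window(self, params, stub_genotype):
        # T_m = 16 with a cold post-shedding window: stratification releases
        from seedlife.simulator import LifeHistoryResult
        from seedlife.germination import germination_probability

        # direct evaluation: P(Dp)(28) ~ 0, P(Ds)(28) = sigmoid(0.1027*28 - ln99)
        # = 0.152, so P(G) = 0.848
        frac = float(germination_probability(28.0, 16.0, 4.0, params))
        assert frac == pytest.approx(0.848, abs=0.001)
        assert frac > 0.8

    def test_zero_horizon_anchor(self, stub_genotype):
        clim = constant_climate(16.0)
        r = simulate_life_history(clim, dt.date(2001, 1, 1), stub_genotype)
        frac = progeny_germination(r, clim, stub_genotype.germination, horizon_days=0)
        assert frac == pytest.approx(0.0099, abs=1e-6)

    def test_incomplete_parent_rejected(self, stub_genotype):
        clim = constant_climate(16.0)
        from seedlife.simulator import LifeHistoryResult

        r = LifeHistoryResult(dt.date(2001, 1, 1), None, None, None, "did_not_complete")
        with pytest.raises(SimulationError):
            progeny_germination(r, clim, stub_genotype.germination)

    def test_progeny_map_long_format(self, stub_genotype):
        clim = constant_climate(16.0)
        dates = [dt.date(2001, m, 1) for m in (1, 4)]
        results = annual_sweep(clim, dates, stub_genotype)
        grid = progeny_map(results, clim, stub_genotype.germination, horizons=(7, 28))
        assert len(grid) == 4
        assert set(grid.columns) == {"germination_date", "horizon", "fraction"}
        assert grid["fraction"].between(0, 1).all()


class TestCohort:
    @pytest.mark.parametrize("scheme", ["uniform", "normal"])
    def test_weights_sum_to_one(self, scheme):
        w = _shedding_weights(scheme)
        assert len(w) == 30
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()

    @pytest.mark.parametrize("scheme", ["uniform", "normal"])
    def test_constant_climate_fraction_is_pointwise_value(self, stub_genotype, scheme):
        # every shedding date sees the same T_m/T_i, so the weighted mean
        # equals the common per-date probability under either scheme
        clim = constant_climate(16.0)
        r = simulate_life_history(clim, dt.date(2001, 1, 1), stub_genotype)
        p = progeny_germination(r, clim, stub_genotype.germination)
        summ = cohort_summary(r, clim, stub_genotype.germination, scheme=scheme)
        assert summ.fraction_low_dormant == pytest.approx(p, abs=1e-9)
        assert summ.mean_shedding_temperature == pytest.approx(16.0)

    def test_later_genotype_sheds_warmer_on_warming_climate(self, seed_set_params, params):
        # linearly warming spring: a late-bolting genotype must shed at
        # equal-or-warmer temperatures
        clim = synth_climate(
            SyntheticClimateSpec(mean=12.0, amplitude=8.0, diurnal_range=4.0,
                                 n_years=3, peak_doy=200)
        )
        early = GenotypeConfig(BoltingModelConfig("fixed", duration_days=30),
                               seed_set_params, params)
        late = GenotypeConfig(BoltingModelConfig("fixed", duration_days=55),
                              seed_set_params, params)
        sow = dt.date(2001, 2, 1)  # spring: temperatures rising through seed set
        r_e = simulate_life_history(clim, sow, early)
        r_l = simulate_life_history(clim, sow, late)
        s_e = cohort_summary(r_e, clim, params)
        s_l = cohort_summary(r_l, clim, params)
        assert s_l.mean_shedding_temperature >= s_e.mean_shedding_temperature

    def test_hard_cutoff_mode_counts_dates(self, stub_genotype):
        clim = constant_climate(16.0)
        r = simulate_life_history(clim, dt.date(2001, 1, 1), stub_genotype)
        summ = cohort_summary(r, clim, stub_genotype.germination, hard_cutoff=True)
        assert summ.fraction_low_dormant in (0.0, 1.0)  # constant climate


class TestWarmingScenarios:
    def test_zero_delta_identity(self, surrogate_genotype, sinusoidal_climate,
                                 autumn_sowing):
        base = simulate_life_history(sinusoidal_climate, autumn_sowing, surrogate_genotype)
        table = warming_scenarios(sinusoidal_climate, [0.0], surrogate_genotype,
                                  autumn_sowing)
        assert table.loc[0, "first_seed_set_date"] == base.first_seed_set_date
        assert table.loc[0, "t_m"] == pytest.approx(base.t_m)

    def test_seed_set_monotone_in_delta(self, surrogate_genotype, sinusoidal_climate,
                                        autumn_sowing):
        table = warming_scenarios(sinusoidal_climate, [-2, 0, 2, 4],
                                  surrogate_genotype, autumn_sowing)
        done = table[table["status"] == "completed"]
        ords = [d.toordinal() for d in done["first_seed_set_date"]]
        assert all(a >= b for a, b in zip(ords, ords[1:]))

    def test_maturation_temperature_buffered_vs_deltas(self, surrogate_genotype,
                                                       sinusoidal_climate, autumn_sowing):
        deltas = [-4, -2, 0, 2, 4]
        table = warming_scenarios(sinusoidal_climate, deltas, surrogate_genotype,
                                  autumn_sowing)
        done = table[table["status"] == "completed"]
        assert len(done) == len(deltas)
        t_m_range = done["t_m"].max() - done["t_m"].min()
        assert t_m_range < (max(deltas) - min(deltas))
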