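"""Generator behavior: determinism, degenerate configs, calibration, coupling."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cgmtrends.data_model import ObservationWindow, SLOTS_PER_DAY
from cgmtrends.metrics import metrics_table
from cgmtrends.stratification import burden_correlation, county_improver_fractions
from cgmtrends.comparison import paired_changes
from cgmtrends.synthetic import (
    GeneratorConfig, TrueUserParams, generate_cohort, generate_counties,
    generate_user_stream,
)

PRE2 = ObservationWindow("pre", dt.date(2020, 2, 3), dt.date(2020, 2, 16))
POST2 = ObservationWindow("post", dt.date(2020, 4, 20), dt.date(2020, 5, 3))


def _quiet_cfg(**kw) -> GeneratorConfig:
    base = dict(n_users=3, n_counties=2, seed=5, daily_dropout_prob=0.0,
                within_day_missing_frac=0.0)
    base.update(kw)
    return GeneratorConfig(**base)


class TestDeterminism:
    def test_identical_config_and_seed_reproduce_bytes(self):
        cfgs = [GeneratorConfig(n_users=25, n_counties=5, seed=123) for _ in range(2)]
        a, b = (generate_cohort(c, (PRE2, POST2)) for c in cfgs)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.counties, b.counties)
        assert a.deaths == b.deaths
        for uid in a.streams:
            np.testing.assert_array_equal(a.streams[uid].times, b.streams[uid].times)
            np.testing.assert_array_equal(a.streams[uid].glucose, b.streams[uid].glucose)

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(n_users=5, seed=1), (PRE2,))
        b = generate_cohort(GeneratorConfig(n_users=5, seed=2), (PRE2,))
        assert not a.truth["baseline_mean"].equals(b.truth["baseline_mean"])


class TestDegenerateConfigs:
    def test_empty_cohort_is_valid(self):
        c = generate_cohort(GeneratorConfig(n_users=0, n_counties=3, seed=0), (PRE2,))
        assert c.users == [] and c.streams == {} and len(c.truth) == 0
        assert len(c.counties) == 3

    def test_single_county_holds_all_users(self):
        c = generate_cohort(_quiet_cfg(n_users=10, n_counties=1), (PRE2,))
        assert {u.county_fips for u in c.users} == {c.counties["fips"].iloc[0]}

    def test_zero_coupling_means_zero_county_effects(self):
        counties, _ = generate_counties(GeneratorConfig(burden_coupling=0.0),
                                        np.random.default_rng(0))
        assert (counties["burden_effect"] == 0).all()

    def test_full_dropout_gives_empty_stream(self):
        c = generate_cohort(_quiet_cfg(daily_dropout_prob=1.0), (PRE2,))
        assert all(len(s) == 0 for s in c.streams.values())

    def test_noise_off_gives_constant_stream_at_baseline(self):
        cfg = _quiet_cfg(within_user_sd=0.0, between_user_sd=0.0,
                         income_gradient=0.0, burden_coupling=0.0,
                         pandemic_shift_mean=0.0, pandemic_shift_sd=0.0,
                         pop_mean_glucose=150.0)
        c = generate_cohort(cfg, (PRE2,))
        for s in c.streams.values():
            assert np.unique(s.glucose).tolist() == [150]

    def test_no_missingness_fills_every_slot(self):
        window = ObservationWindow("w8", dt.date(2020, 1, 6), dt.date(2020, 3, 1))
        params = TrueUserParams("u", 160.0, 0.0, "00001", 70000.0, 12)
        s = generate_user_stream(params, [window], _quiet_cfg(),
                                 np.random.default_rng(0))
        assert len(s) == 56 * SLOTS_PER_DAY

    def test_glucose_stays_in_reportable_range(self):
        c = generate_cohort(GeneratorConfig(n_users=10, seed=3,
                                            between_user_sd=80.0), (PRE2,))
        for s in c.streams.values():
            assert s.glucose.min() >= 40 and s.glucose.max() <= 400


class TestShiftStructure:
    def test_step_applies_only_after_onset(self):
        cfg = _quiet_cfg(within_user_sd=0.0, between_user_sd=0.0,
                         income_gradient=0.0, burden_coupling=0.0,
                         pandemic_shift_mean=-30.0, pandemic_shift_sd=0.0,
                         pop_mean_glucose=200.0)
        c = generate_cohort(cfg, (PRE2, POST2))
        for s in c.streams.values():
            pre = s.restrict(PRE2).glucose
            post = s.restrict(POST2).glucose
            assert np.unique(pre).tolist() == [200]
            assert np.unique(post).tolist() == [170]

    def test_null_config_change_is_centered_at_zero(self):
        cfg = GeneratorConfig(n_users=150, n_counties=5, seed=17,
                              pandemic_shift_mean=0.0, pandemic_shift_sd=0.0,
                              burden_coupling=0.0, income_gradient=0.0)
        c = generate_cohort(cfg, (PRE2, POST2))
        ids = list(c.streams)
        pre = metrics_table(c.streams, ids, PRE2)
        post = metrics_table(c.streams, ids, POST2)
        d = (post["tir"] - pre["tir"]).to_numpy()
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean()) < 3 * se

    def test_larger_shift_magnitude_raises_improver_fraction(self):
        fracs = {}
        for shift in (-1.0, -6.0):
            vals = []
            for seed in range(3):
                cfg = GeneratorConfig(n_users=120, n_counties=4, seed=seed,
                                      pandemic_shift_mean=shift,
                                      burden_coupling=0.0, income_gradient=0.0)
                c = generate_cohort(cfg, (PRE2, POST2))
                ids = list(c.streams)
                pre = metrics_table(c.streams, ids, PRE2)
                post = metrics_table(c.streams, ids, POST2)
                vals.append(float(((post["tir"] - pre["tir"]) >= 5).mean()))
            fracs[shift] = np.mean(vals)
        assert fracs[-6.0] > fracs[-1.0]


class TestCalibration:
    def test_marginal_tir_matches_direct_monte_carlo_oracle(self):
        """The simulated cohort's mean pre-window TIR must agree with a
        closed-form lognormal evaluation of the same generative marginal."""
        cfg = GeneratorConfig(n_users=2000, seed=29)
        cohort = generate_cohort(cfg, (PRE2,))
        ids = list(cohort.streams)
        pre = metrics_table(cohort.streams, ids, PRE2)
        simulated = float(pre["tir"].mean())

        rng = np.random.default_rng(1729)
        m = 200_000
        z_inc = rng.standard_normal(m)
        baseline = (cfg.pop_mean_glucose + cfg.between_user_sd * rng.standard_normal(m)
                    - cfg.income_gradient * z_inc)
        baseline = np.clip(baseline, 60.0, 380.0)
        sigma = cfg.sigma_log
        mu = np.log(baseline) - 0.5 * sigma**2
        # readings are integer mg/dL, so the closed [70, 180] band on rounded
        # values corresponds to continuous glucose in [69.5, 180.5)
        z_hi = (np.log(180.5) - mu) / sigma
        z_lo = (np.log(69.5) - mu) / sigma
        oracle = float((sps.norm.cdf(z_hi) - sps.norm.cdf(z_lo)).mean() * 100)

        assert simulated == pytest.approx(oracle, abs=1.5)
        # and both sit in the plausible range for the emulated population
        assert 50 < simulated < 70
        assert pre["tir"].std() == pytest.approx(20.0, abs=4.0)

    def test_tenure_mixture_populates_the_long_tenure_stratum(self):
        c = generate_cohort(GeneratorConfig(n_users=400, seed=31), (PRE2,))
        tenures = c.truth["tenure_months"]
        assert (tenures >= 37).mean() > 0.05
        assert (tenures < 13).mean() > 0.02


class TestCouplingRecovery:
    def test_positive_coupling_yields_positive_correlation_across_seeds(self):
        rs = []
        for seed in range(20):
            cfg = GeneratorConfig(n_users=400, n_counties=12, seed=seed,
                                  burden_coupling=8.0, income_gradient=0.0)
            c = generate_cohort(cfg, (PRE2, POST2))
            ids = list(c.streams)
            pre = metrics_table(c.streams, ids, PRE2)
            post = metrics_table(c.streams, ids, POST2)
            changes = paired_changes(pre, post)
            rows = county_improver_fractions(changes, c.users, c.deaths, min_users=15)
            if len(rows) < 3:
                continue
            r, _, _ = burden_correlation(rows)
            rs.append(r)
        assert len(rs) >= 15
        assert np.mean([r > 0 for r in rs]) >= 0.95

    def test_zero_coupling_correlation_centered_at_zero(self):
        rs = []
        for seed in range(12):
            cfg = GeneratorConfig(n_users=300, n_counties=10, seed=100 + seed,
                                  burden_coupling=0.0, income_gradient=0.0)
            c = generate_cohort(cfg, (PRE2, POST2))
            ids = list(c.streams)
            pre = metrics_table(c.streams, ids, PRE2)
            post = metrics_table(c.streams, ids, POST2)
            changes = paired_changes(pre, post)
            rows = county_improver_fractions(changes, c.users, c.deaths, min_users=10)
            if len(rows) < 3:
                continue
            rs.append(burden_correlation(rows)[0])
        assert len(rs) >= 8
        assert abs(np.mean(rs)) < 2 * np.std(rs) / np.sqrt(len(rs)) + 0.25


class TestConfigValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(ar1_rho=1.0)
        with pytest.raises(ValueError):
            GeneratorConfig(daily_dropout_prob=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(between_user_sd=-1.0)
        with pytest.raises(ValueError):
            GeneratorConfig(n_counties=0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_users=7, seed=99, pandemic_shift_mean=-2.5)
        p = tmp_path / "gen.yaml"
        cfg.to_yaml(p)
        assert GeneratorConfig.from_yaml(p) == cfg
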