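import datetime as dt
from dataclasses import replace

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
from scipy import stats as sps

from sleepspan.night_metrics import circular_mean_sd, score_hypnogram
from sleepspan.synthetic_data import (
    InfeasibleTargetsError,
    SyntheticConfig,
    VariableSpec,
    generate_cohort,
    generate_hypnogram,
    null_variables,
)


def _noise_free_config():
    variables = {
        name: replace(spec, sd_between=0.0, sd_within=0.0)
        for name, spec in null_variables().items()
    }
    return SyntheticConfig(
        n_participants=3,
        enrollment_start=dt.date(2017, 10, 1),
        enrollment_end=dt.date(2017, 10, 1),
        study_end=dt.date(2017, 12, 1),
        variables=variables,
        cluster_frac=0.0,
        cluster_offsets={},
        missing_rate=0.0,
        wake_within_sd_h=0.0,
    )


class TestGenerateCohort:
    def test_zero_noise_gives_constant_series_at_the_mean(self):
        cfg = _noise_free_config()
        panel, _ = generate_cohort(cfg, seed=0)
        for var, col in [("sol_min", "sol_min"), ("deep_h", "deep_h"),
                         ("sleep_midtime_min", "sleep_midtime_min")]:
            vals = panel.nights[col].to_numpy()
            assert np.allclose(vals, cfg.variables[var].mu, atol=1e-9)
        # TST is the stage sum plus the (constant) intra-sleep wake
        expected_tst = sum(cfg.variables[v].mu for v in ("deep_h", "rem_h", "light_h"))
        expected_tst += cfg.wake_within_mean_h
        assert np.allclose(panel.nights["tst_h"], expected_tst, atol=1e-9)
        assert np.allclose(panel.nights["total_in_bed_h"],
                           cfg.variables["total_in_bed_h"].mu, atol=1e-9)

    def test_same_config_and_seed_reproduces_panel(self):
        cfg = SyntheticConfig(n_participants=4)
        a, _ = generate_cohort(cfg, seed=9)
        b, _ = generate_cohort(cfg, seed=9)
        pdt.assert_frame_equal(a.nights, b.nights)
        pdt.assert_frame_equal(a.days, b.days)
        c, _ = generate_cohort(cfg, seed=10)
        assert not a.nights["tst_h"].equals(c.nights["tst_h"])

    def test_generated_nights_respect_record_invariants(self, small_panel):
        n = small_panel.nights
        assert (n["tst_h"] <= n["total_in_bed_h"] + 1e-9).all()
        assert (
            n["deep_h"] + n["rem_h"] + n["light_h"] <= n["tst_h"] + 1 / 60 + 1e-9
        ).all()
        assert (n["sol_min"] >= 0).all()
        assert (n["n_awake"] >= 0).all()
        assert (n["n_awake"] == n["n_awake"].round()).all()
        assert ((n["sleep_midtime_min"] >= 0) & (n["sleep_midtime_min"] < 1440)).all()

    def test_missingness_rate_within_binomial_tolerance(self):
        cfg = SyntheticConfig(
            n_participants=20,
            enrollment_start=dt.date(2017, 9, 1),
            enrollment_end=dt.date(2017, 9, 1),
            study_end=dt.date(2017, 12, 28),
            missing_rate=0.2,
        )
        panel, _ = generate_cohort(cfg, seed=4)
        total = 20 * ((cfg.study_end - dt.date(2017, 9, 1)).days + 1)
        realized = 1 - len(panel.nights) / total
        se = np.sqrt(0.2 * 0.8 / total)
        assert abs(realized - 0.2) < 4 * se

    def test_seasonal_step_slope_recovered_by_regression(self):
        cfg = SyntheticConfig(n_participants=30, cluster_frac=0.0, cluster_offsets={})
        panel, _ = generate_cohort(cfg, seed=2)
        days = panel.days
        t = (days["day_date"] - pd.Timestamp(cfg.enrollment_start)).dt.days
        fit = sps.linregress(t, days["steps"])
        slope = cfg.variables["steps"].slope_per_day
        assert abs(fit.slope - slope) < 2 * fit.stderr

    def test_grand_means_match_configured_means(self):
        """Monte-Carlo mean recovery on the stationary generator."""
        cfg = SyntheticConfig(
            n_participants=30, variables=null_variables(),
            cluster_frac=0.0, cluster_offsets={},
        )
        seeds = range(25)
        acc = {v: [] for v in cfg.variables}
        for seed in seeds:
            panel, _ = generate_cohort(cfg, seed=seed)
            for v in acc:
                col = panel.nights[v] if v in panel.nights else panel.days[v]
                if v == "sleep_midtime_min":
                    acc[v].append(circular_mean_sd(col.to_numpy())[0])
                else:
                    acc[v].append(float(col.mean()))
        for v, vals in acc.items():
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - cfg.variables[v].mu) < 4 * se, v

    def test_planted_cluster_offset_shifts_the_awakening_count(self):
        cfg = SyntheticConfig(n_participants=40, variables=null_variables())
        panel, truth = generate_cohort(cfg, seed=6)
        means = panel.nights.groupby("participant_id")["n_awake"].mean()
        by_cluster = means.groupby(truth.cluster_labels).mean()
        assert by_cluster[2] - by_cluster[1] > 0.5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_participants=0).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(missing_rate=1.5).validate()
        with pytest.raises(ValueError):
            # nonzero DST delta but the clock change outside the study range
            SyntheticConfig(dst_date=dt.date(2018, 6, 1)).validate()

    def test_config_dict_round_trip(self):
        cfg = SyntheticConfig(n_participants=7, missing_rate=0.05)
        back = SyntheticConfig.from_dict(cfg.to_dict())
        assert back == cfg


class TestGenerateHypnogram:
    def test_exact_round_trip_of_stated_targets(self):
        h = generate_hypnogram(
            sol_min=2, n_awake=1, deep_min=2, rem_min=2, light_min=3,
            bed_minutes=12, seed=0,
        )
        r = score_hypnogram(h).record
        assert r.sol_min == 2
        assert r.n_awake == 1
        assert round(r.deep_h * 60) == 2
        assert round(r.rem_h * 60) == 2
        assert round(r.light_h * 60) == 3

    def test_no_awakenings_means_no_interior_wake(self):
        h = generate_hypnogram(
            sol_min=5, n_awake=0, deep_min=30, rem_min=20, light_min=40,
            bed_minutes=120, seed=1,
        )
        sn = score_hypnogram(h)
        assert "WAKE" not in h.stages[sn.onset_index:sn.final_wake_index]

    def test_infeasible_targets_raise(self):
        with pytest.raises(InfeasibleTargetsError):
            generate_hypnogram(sol_min=0, n_awake=0, deep_min=200, rem_min=0,
                               light_min=0, bed_minutes=60)
        with pytest.raises(InfeasibleTargetsError):
            # two awakenings cannot fit between two sleep minutes
            generate_hypnogram(sol_min=0, n_awake=2, deep_min=1, rem_min=1,
                               light_min=0, bed_minutes=60)
        with pytest.raises(InfeasibleTargetsError):
            generate_hypnogram(sol_min=-1, n_awake=0, deep_min=5, rem_min=5,
                               light_min=5, bed_minutes=60)

    def test_random_feasible_targets_round_trip(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            deep, rem, light = rng.integers(1, 120, 3)
            n_awake = int(rng.integers(0, min(6, deep + rem + light)))
            sol = int(rng.integers(0, 40))
            bed = sol + deep + rem + light + n_awake + int(rng.integers(0, 30))
            h = generate_hypnogram(sol, n_awake, int(deep), int(rem), int(light),
                                   int(bed), seed=int(rng.integers(0, 2**31)))
            r = score_hypnogram(h).record
            assert (r.sol_min, r.n_awake) == (sol, n_awake)
            assert round(r.deep_h * 60) == deep
            assert round(r.rem_h * 60) == rem
            assert round(r.light_h * 60) == light
            assert not r.violations()
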