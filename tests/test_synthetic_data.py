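"""Generator contracts: determinism, conservation, ground truth, Monte Carlo
agreement with the configured laws."""

import numpy as np
import pytest

from somnarch.sleep_core import call_bouts
from somnarch.synthetic_data import (BoutLaw, SurvivalScenario,
                                     SyntheticScenario, apply_rebound_operator,
                                     apply_sd_operator, gen_activity_trace,
                                     gen_cohort, gen_survival_cohort,
                                     gen_trajectory, scenario_to_config)


def degenerate_scenario(**kw):
    return SyntheticScenario(
        sleep_bout_law_day=BoutLaw("fixed", 10),
        sleep_bout_law_night=BoutLaw("fixed", 10),
        wake_bout_law_day=BoutLaw("fixed", 5),
        wake_bout_law_night=BoutLaw("fixed", 5),
        transition_surge=(0, 1.0), **kw)


class TestActivityGenerator:
    def test_degenerate_laws_give_exact_durations(self):
        tr, truth = gen_activity_trace(degenerate_scenario(seed=1, n_days=1))
        sleeps = [b for b in truth if b.kind == "sleep"]
        # bouts truncated at transitions or the trace end may be shorter
        interior = [b for b in sleeps
                    if b.end < len(tr) and (b.onset_zt_min + b.duration_min)
                    % 720 != 0]
        assert interior and all(b.duration_min == 10 for b in interior)

    def test_same_seed_same_output(self):
        sc = SyntheticScenario(seed=42, n_days=2)
        tr1, truth1 = gen_activity_trace(sc)
        tr2, truth2 = gen_activity_trace(sc)
        np.testing.assert_array_equal(tr1.counts, tr2.counts)
        assert [(b.kind, b.start, b.duration_min) for b in truth1] == \
            [(b.kind, b.start, b.duration_min) for b in truth2]

    def test_different_flies_differ(self):
        sc = SyntheticScenario(seed=42, n_days=1)
        cohort = gen_cohort(sc, 2)
        assert not np.array_equal(cohort[0][0].counts, cohort[1][0].counts)

    def test_trace_length_and_conservation(self):
        sc = SyntheticScenario(seed=5, n_days=3)
        tr, truth = gen_activity_trace(sc)
        assert len(tr) == 3 * 1440
        assert sum(b.duration_min for b in truth) == len(tr)
        sleep_min = sum(b.duration_min for b in truth if b.kind == "sleep")
        wake_min = sum(b.duration_min for b in truth if b.kind == "motion")
        assert sleep_min + wake_min == len(tr)
        # wake minutes all carry >= 1 count; sleep minutes are all zero
        asleep = np.zeros(len(tr), dtype=bool)
        for b in truth:
            if b.kind == "sleep":
                asleep[b.start:b.end] = True
        assert (tr.counts[asleep] == 0).all()
        assert (tr.counts[~asleep] >= 1).all()

    def test_night_bout_mean_recovered_monte_carlo(self):
        """Mean ground-truth night sleep-bout duration tracks the configured
        law (60 min night / 10 min day) within 10% over 100 flies."""
        sc = SyntheticScenario(
            seed=9, n_days=2,
            sleep_bout_law_day=BoutLaw("exponential", 10),
            sleep_bout_law_night=BoutLaw("exponential", 60))
        durs = []
        for _, truth in gen_cohort(sc, 100):
            durs += [b.duration_min for b in truth
                     if b.kind == "sleep" and b.onset_phase == "dark"
                     and b.end < len(range(2 * 1440))
                     and (b.onset_zt_min + b.duration_min) % 1440 != 0]
        mean = np.mean(durs)
        assert abs(mean - 60) / 60 < 0.10

    def test_transition_minutes_always_wake(self):
        sc = SyntheticScenario(seed=13, n_days=3)
        tr, truth = gen_activity_trace(sc)
        for t in range(0, len(tr), 720):
            assert tr.counts[t] >= 1
        anchored = [b for b in truth if b.is_transition]
        assert len(anchored) >= 3  # at least one bout per transition pair

    def test_ground_truth_matches_caller_for_clean_traces(self):
        sc = degenerate_scenario(seed=3, n_days=2)
        tr, truth = gen_activity_trace(sc)
        called = call_bouts(tr)
        assert [(b.kind, b.start, b.duration_min) for b in truth] == \
            [(b.kind, b.start, b.duration_min) for b in called]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BoutLaw("exponential", -1)
        with pytest.raises(ValueError):
            SyntheticScenario(wake_activity_rate=0)
        with pytest.raises(ValueError):
            SyntheticScenario(rebound_multiplier=0.5)
        with pytest.raises(ValueError):
            BoutLaw("weird", 10)

    def test_config_serialization_records_seed(self):
        text = scenario_to_config(SyntheticScenario(seed=77))
        assert "seed = 77" in text


class TestSdOperator:
    def test_full_efficacy_clears_window(self):
        tr, _ = gen_activity_trace(SyntheticScenario(seed=2, n_days=2))
        window = tr.zt_window(1, 1080, 1440)
        out, hit = apply_sd_operator(tr, window, 1.0, seed=0)
        assert (out.counts[window] >= 1).all()
        assert hit.size == int((tr.counts[window] == 0).sum())

    def test_zero_efficacy_is_identity(self):
        tr, _ = gen_activity_trace(SyntheticScenario(seed=2, n_days=2))
        window = tr.zt_window(1, 1080, 1440)
        out, hit = apply_sd_operator(tr, window, 0.0, seed=0)
        np.testing.assert_array_equal(out.counts, tr.counts)
        assert hit.size == 0

    def test_partial_efficacy_binomial(self):
        """Converted-minute count across replicates is binomial around
        efficacy * sleep minutes."""
        tr, _ = gen_activity_trace(SyntheticScenario(seed=2, n_days=2))
        window = tr.zt_window(1, 1080, 1440)
        n_sleep = int((tr.counts[window] == 0).sum())
        p = 0.9
        hits = [apply_sd_operator(tr, window, p, seed=s)[1].size
                for s in range(200)]
        mean = np.mean(hits)
        se = np.sqrt(n_sleep * p * (1 - p) / 200)
        assert abs(mean - p * n_sleep) < 4 * se

    def test_window_outside_trace_rejected(self):
        tr, _ = gen_activity_trace(SyntheticScenario(seed=2, n_days=1))
        with pytest.raises(ValueError):
            apply_sd_operator(tr, slice(5000, 6000), 1.0)


class TestReboundOperator:
    def test_programmed_surplus_is_achieved(self):
        tr, _ = gen_activity_trace(SyntheticScenario(seed=8, n_days=2))
        window = tr.zt_window(1, 0, 180)
        from somnarch.sleep_core import sleep_mask
        before = int(sleep_mask(tr)[window].sum())
        out, achieved = apply_rebound_operator(tr, window, 80)
        after = int(sleep_mask(out)[window].sum())
        assert after - before == achieved
        assert achieved >= 80
        assert achieved <= 80 + 4  # may absorb one short quiescent run

    def test_zero_surplus_is_identity(self):
        tr, _ = gen_activity_trace(SyntheticScenario(seed=8, n_days=1))
        out, achieved = apply_rebound_operator(tr, slice(0, 180), 0)
        np.testing.assert_array_equal(out.counts, tr.counts)
        assert achieved == 0


class TestSurvivalCohort:
    def test_exponential_mean_equals_scale(self):
        sc = SurvivalScenario(n_vials=1, flies_per_vial=1000, weibull_scale=20,
                              weibull_shape=1, censor_time=np.inf,
                              escape_rate=0, seed=1)
        led = gen_survival_cohort(sc)
        assert (led["event"] == "death").all()
        assert led["time"].mean() == pytest.approx(20, rel=0.1)

    def test_censor_time_zero_censors_everything(self):
        sc = SurvivalScenario(n_vials=2, flies_per_vial=10, censor_time=0,
                              seed=1)
        led = gen_survival_cohort(sc)
        assert (led["event"] == "censored").all()
        assert (led["time"] == 0).all()

    def test_censored_fraction_matches_weibull_survivor(self):
        """P(censored at study end) = S(89) = exp(-(89/40)^3)."""
        sc = SurvivalScenario(n_vials=10, flies_per_vial=30, weibull_scale=40,
                              weibull_shape=3, censor_time=89, escape_rate=0,
                              seed=6)
        led = gen_survival_cohort(sc)
        frac = (led["event"] == "censored").mean()
        p = np.exp(-((89 / 40) ** 3))
        se = np.sqrt(p * (1 - p) / len(led))
        assert abs(frac - p) < 4 * se + 1e-12

    def test_vial_grouping_preserved(self):
        sc = SurvivalScenario(n_vials=4, flies_per_vial=7, seed=3)
        led = gen_survival_cohort(sc)
        assert led.groupby("vial_id").size().tolist() == [7, 7, 7, 7]


class TestTrajectoryGenerator:
    def test_all_rest_means_zero_displacement(self):
        traj, run = gen_trajectory(10, rest_fraction=1.0, seed=0)
        assert not run.any()
        assert np.ptp(traj.x) == 0 and np.ptp(traj.y) == 0

    def test_constant_speed_distance(self):
        traj, run = gen_trajectory(
            10, fps=15, run_speed_law=BoutLaw("fixed", 5.0),
            rest_fraction=0.0, turn_sd_rad=0.0, arena_diameter_mm=1000, seed=0)
        from somnarch.behavior import locomotion_metrics
        m = locomotion_metrics(traj)
        assert m.total_distance_mm == pytest.approx(5.0 * 10, rel=1e-6)
        assert m.fraction_moving == 1.0
        assert m.running_velocity_mean == pytest.approx(5.0, rel=1e-6)

    def test_positions_stay_inside_arena(self):
        traj, _ = gen_trajectory(30, rest_fraction=0.2, seed=4,
                                 arena_diameter_mm=37)
        r = np.hypot(traj.x, traj.y)
        assert (r <= 37 / 2 + 1e-9).all()

    def test_moving_fraction_tracks_ground_truth_state(self):
        traj, run = gen_trajectory(120, rest_fraction=0.5, seed=7)
        from somnarch.behavior import locomotion_metrics
        m = locomotion_metrics(traj)
        assert abs(m.fraction_moving - run.mean()) < 0.05
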