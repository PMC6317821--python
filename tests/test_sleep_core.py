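"""Bout calling, dead-flagging, architecture metrics and bout distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from somnarch.dam_io import ActivityTrace
from somnarch.sleep_core import (MissingDataError, architecture,
                                 bout_distribution, call_bouts, flag_dead,
                                 mark_transition_bouts, sleep_mask)

from conftest import brute_force_bouts


def as_tuples(bouts):
    return [(b.kind, b.start, b.duration_min) for b in bouts]


class TestCallBouts:
    def test_ten_zero_minutes_form_one_sleep_bout(self, make_trace):
        tr = make_trace([3, 1] + [0] * 10 + [2, 4])
        bouts = call_bouts(tr)
        sleeps = [b for b in bouts if b.kind == "sleep"]
        assert len(sleeps) == 1
        assert sleeps[0].start == 2 and sleeps[0].duration_min == 10

    def test_four_minute_quiescence_is_wake(self, make_trace):
        """Quiescent runs below the 5-min threshold are absorbed into the
        surrounding motion bout."""
        tr = make_trace([1, 1, 0, 0, 0, 0, 1, 1])
        bouts = call_bouts(tr)
        assert [b.kind for b in bouts] == ["motion"]
        assert bouts[0].duration_min == 8

    def test_five_minute_boundary_is_sleep(self, make_trace):
        tr = make_trace([1, 0, 0, 0, 0, 0, 1])
        kinds = [b.kind for b in call_bouts(tr)]
        assert kinds == ["motion", "sleep", "motion"]

    def test_every_minute_in_exactly_one_bout(self, make_trace, rng):
        counts = rng.integers(0, 2, 500)
        bouts = call_bouts(make_trace(counts))
        covered = np.zeros(500, dtype=int)
        for b in bouts:
            covered[b.start:b.end] += 1
        assert (covered == 1).all()
        kinds = [b.kind for b in bouts]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_matches_brute_force_on_random_traces(self, make_trace, rng):
        for _ in range(300):
            n = int(rng.integers(1, 300))
            counts = (rng.random(n) < 0.6).astype(int)
            tr = make_trace(counts)
            assert as_tuples(call_bouts(tr)) == brute_force_bouts(counts)

    def test_missing_data_rejected(self):
        tr = ActivityTrace("m", np.zeros(20, dtype=int),
                           missing=np.eye(1, 20, 10, dtype=bool)[0])
        with pytest.raises(MissingDataError):
            call_bouts(tr)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=120),
           st.integers(1, 10))
    def test_oracle_equivalence_property(self, counts, min_sleep):
        tr = ActivityTrace("h", np.array(counts))
        assert as_tuples(call_bouts(tr, min_sleep)) == \
            brute_force_bouts(counts, min_sleep)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=1, max_size=200))
    def test_raising_threshold_never_increases_sleep(self, counts):
        tr = ActivityTrace("h", np.array(counts))
        prev_sleep, prev_bouts = None, None
        for thr in (1, 3, 5, 8, 12):
            bouts = [b for b in call_bouts(tr, thr) if b.kind == "sleep"]
            total = sum(b.duration_min for b in bouts)
            if prev_sleep is not None:
                assert total <= prev_sleep
                assert len(bouts) <= prev_bouts
            prev_sleep, prev_bouts = total, len(bouts)


class TestFlagDead:
    def test_all_zero_trace_is_dead(self, make_trace):
        assert flag_dead(make_trace(np.zeros(1440, dtype=int))) == "dead"

    def test_exactly_ten_active_minutes_per_phase_is_alive(self, make_trace):
        """The criterion is 'less than 10 minutes of activity', so 10 exactly
        passes."""
        counts = np.zeros(1440, dtype=int)
        counts[:10] = 1       # 10 active light minutes
        counts[720:730] = 1   # 10 active dark minutes
        assert flag_dead(make_trace(counts)) == "alive"
        counts[729] = 0       # 9 active dark minutes
        assert flag_dead(make_trace(counts)) == "dead"

    def test_either_phase_triggers(self, make_trace):
        counts = np.zeros(1440, dtype=int)
        counts[:720] = 1      # fully active light phase
        counts[720:725] = 1   # 5 active dark minutes
        assert flag_dead(make_trace(counts)) == "dead"

    def test_counts_measure_minutes_not_crosses(self, make_trace):
        # 9 minutes with huge counts still fail the duration criterion
        counts = np.zeros(1440, dtype=int)
        counts[:9] = 500
        counts[720:740] = 1
        assert flag_dead(make_trace(counts)) == "dead"


class TestArchitecture:
    def test_single_full_dark_sleep_bout(self, make_trace):
        counts = np.ones(1440, dtype=int)
        counts[720:] = 0
        tr = make_trace(counts)
        arch = architecture(tr, call_bouts(tr)).set_index("phase")
        dark = arch.loc["dark"]
        assert dark["total_sleep_min"] == 720
        assert dark["bout_count"] == 1
        assert dark["max_bout_min"] == 720
        assert dark["sleep_latency_min"] == 0

    def test_no_sleep_latency_censored(self, make_trace):
        tr = make_trace(np.ones(1440, dtype=int))
        arch = architecture(tr, call_bouts(tr)).set_index("phase")
        assert bool(arch.loc["light", "latency_censored"])
        assert arch.loc["light", "sleep_latency_min"] == 720

    def test_metrics_match_minute_grid_recomputation(self, make_trace, rng):
        counts = (rng.random(2880) < 0.5).astype(int) * rng.integers(1, 5, 2880)
        tr = make_trace(counts)
        bouts = call_bouts(tr)
        arch = architecture(tr, bouts)
        mask = sleep_mask(tr)
        for _, row in arch.iterrows():
            d, ph = row["day"], row["phase"]
            lo, hi = (0, 720) if ph == "light" else (720, 1440)
            sl = tr.zt_window(d, lo, hi)
            assert row["total_sleep_min"] == mask[sl].sum()
            onset = [b for b in bouts if b.kind == "sleep"
                     and b.day_index == d and b.onset_phase == ph]
            assert row["bout_count"] == len(onset)
            if onset:
                assert row["max_bout_min"] == max(b.duration_min for b in onset)
            wake_idx = np.arange(sl.start, sl.stop)
            wake_idx = wake_idx[~mask[sl]]
            expect = counts[wake_idx].sum() / len(wake_idx)
            assert row["waking_activity_per_min"] == pytest.approx(expect)

    def test_straddling_bout_splits_minutes_counts_once(self, make_trace):
        # sleep from ZT 700 to 740: 20 light + 20 dark minutes, onset in light
        counts = np.ones(1440, dtype=int)
        counts[700:740] = 0
        tr = make_trace(counts)
        arch = architecture(tr, call_bouts(tr)).set_index("phase")
        assert arch.loc["light", "total_sleep_min"] == 20
        assert arch.loc["dark", "total_sleep_min"] == 20
        assert arch.loc["light", "bout_count"] == 1
        assert arch.loc["dark", "bout_count"] == 0
        assert arch.loc["light", "max_bout_min"] == 40


class TestTransitionBouts:
    def test_motion_bout_spanning_zt720_is_flagged(self, make_trace):
        counts = np.zeros(1440, dtype=int)
        counts[710:730] = 2
        tr = make_trace(counts)
        bouts = mark_transition_bouts(call_bouts(tr))
        flagged = [b for b in bouts if b.is_transition]
        # ZT0 falls inside the opening sleep bout, so only the ZT720-spanning
        # motion bout is flagged
        assert [(b.start, b.end) for b in flagged] == [(710, 730)]

    def test_sleep_at_transition_flags_nothing(self, make_trace):
        counts = np.ones(1440, dtype=int)
        counts[700:740] = 0  # sleep covers ZT720
        tr = make_trace(counts)
        bouts = mark_transition_bouts(call_bouts(tr))
        flagged = [b for b in bouts if b.is_transition and 700 <= b.start < 740]
        assert flagged == []

    def test_generator_anchored_bouts_are_recovered(self):
        from somnarch.synthetic_data import SyntheticScenario, gen_activity_trace
        sc = SyntheticScenario(seed=11, n_days=2)
        tr, truth = gen_activity_trace(sc)
        bouts = mark_transition_bouts(call_bouts(tr))
        truth_anchors = {b.start for b in truth
                         if b.kind == "motion" and b.is_transition}
        called_anchors = {b.start for b in bouts
                          if b.kind == "motion" and b.is_transition}
        assert truth_anchors == called_anchors


class TestBoutDistribution:
    @pytest.mark.parametrize("duration,expected_bin", [
        (5, "[5,15)"), (14, "[5,15)"), (15, "[15,51)"), (50, "[15,51)"),
        (51, "[51,150)"), (149, "[51,150)"), (150, "[150,500)"),
        (499, "[150,500)"), (500, "[500,721)"), (720, "[500,721)"),
    ])
    def test_bin_assignment(self, make_trace, duration, expected_bin):
        counts = np.ones(1440, dtype=int)
        counts[10:10 + duration] = 0
        tr = make_trace(counts)
        dist = bout_distribution(call_bouts(tr))
        row = dist[(dist["phase"] == "light") & (dist["bout_count"] > 0)]
        assert list(row["bin"]) == [expected_bin]
        assert int(row["sleep_min"].iloc[0]) == duration

    def test_minute_sums_conserve_total_sleep(self, make_trace, rng):
        counts = (rng.random(2880) < 0.55).astype(int)
        tr = make_trace(counts)
        bouts = call_bouts(tr)
        dist = bout_distribution(bouts)
        total = sum(b.duration_min for b in bouts if b.kind == "sleep")
        assert dist["sleep_min"].sum() == total
        assert dist["bout_count"].sum() == \
            sum(1 for b in bouts if b.kind == "sleep")

    def test_overlong_bout_capped_into_final_bin(self, make_trace):
        counts = np.ones(2880, dtype=int)
        counts[100:1000] = 0  # 900-min bout exceeds the last edge
        tr = make_trace(counts)
        dist = bout_distribution(call_bouts(tr))
        row = dist[dist["bout_count"] > 0]
        assert list(row["bin"]) == ["[500,721)"]

    def test_edges_must_start_at_threshold(self, make_trace):
        tr = make_trace(np.ones(100, dtype=int))
        with pytest.raises(ValueError):
            bout_distribution(call_bouts(tr), edges=(1, 10, 721))
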