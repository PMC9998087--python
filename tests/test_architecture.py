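import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import somnopharm as sp
from somnopharm.architecture import _state_runs

from ._oracles import oracle_episode_intervals


def series(text):
    return sp.EpochSeries.from_states(list(text))


class TestDetectEpisodes:
    def test_exact_minimum_span_qualifies(self):
        s = series("W" * 3 + "N" * 15 + "W" * 3)
        eps = sp.detect_episodes(s, "N", 60, 16)
        assert len(eps) == 1
        assert eps[0].span_s == 60.0
        assert eps[0].net_s == 60.0

    def test_below_minimum_span_rejected(self):
        s = series("W" * 3 + "N" * 14 + "W" * 3)
        assert sp.detect_episodes(s, "N", 60, 16) == []

    def test_interruption_within_gap_merges(self):
        s = series("N" * 8 + "W" * 3 + "N" * 8)
        eps = sp.detect_episodes(s, "N", 60, 16)
        assert len(eps) == 1
        assert eps[0].span_s == 76.0
        assert eps[0].gaps == ((8, 3),)
        assert eps[0].net_s == 64.0

    def test_interruption_beyond_gap_splits_and_fails_span(self):
        s = series("N" * 8 + "W" * 5 + "N" * 8)
        assert sp.detect_episodes(s, "N", 60, 16) == []

    def test_gap_composition_is_state_agnostic(self):
        s = series("N" * 8 + "WR" + "N" * 8)
        eps = sp.detect_episodes(s, "N", 60, 16)
        assert len(eps) == 1 and eps[0].gaps == ((8, 2),)

    def test_default_rules_per_state(self):
        s = series("R" * 4 + "W" * 10)
        assert len(sp.detect_episodes(s, "R")) == 1  # 16 s minimum for REM
        assert sp.detect_episodes(s, "W") == []      # 40 s of wake < 60 s

    def test_invalid_thresholds_rejected(self):
        s = series("N" * 20)
        with pytest.raises(sp.ParameterError):
            sp.detect_episodes(s, "N", 30, 16)  # not a multiple of 4
        with pytest.raises(sp.ParameterError):
            sp.detect_episodes(s, "N", -4, 16)

    @pytest.mark.parametrize("rule", [(16, 8), (60, 16)])
    def test_matches_oracle_on_all_length8_sequences(self, rule):
        min_ep, gap_ep = rule[0] // 4, rule[1] // 4
        for states in itertools.product((0, 1, 2), repeat=8):
            codes = np.array(states, dtype=np.int8)
            s = sp.EpochSeries("a", "c", codes, np.zeros(8, bool))
            got = [(e.start_epoch, e.end_epoch) for e in sp.detect_episodes(s, "N", *rule)]
            assert got == oracle_episode_intervals(states, 1, min_ep, gap_ep)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=150)
    def test_matches_oracle_on_random_length100_sequences(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.choice(3, size=100, p=[0.4, 0.4, 0.2]).astype(np.int8)
        s = sp.EpochSeries("a", "c", codes, np.zeros(100, bool))
        for state, (min_s, gap_s) in sp.EPISODE_RULES.items():
            got = [(e.start_epoch, e.end_epoch) for e in sp.detect_episodes(s, state)]
            want = oracle_episode_intervals(
                codes, sp.STATES.index(state), int(min_s // 4), int(gap_s // 4)
            )
            assert got == want

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60)
    def test_detection_is_mirror_symmetric(self, seed):
        """Scanning direction must not matter: reversing the sequence mirrors episodes."""
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 3, 80).astype(np.int8)
        s = sp.EpochSeries("a", "c", codes, np.zeros(80, bool))
        r = sp.EpochSeries("a", "c", codes[::-1].copy(), np.zeros(80, bool))
        fwd = [(e.start_epoch, e.end_epoch) for e in sp.detect_episodes(s, "N", 16, 8)]
        rev = sorted(
            (79 - e.end_epoch, 79 - e.start_epoch) for e in sp.detect_episodes(r, "N", 16, 8)
        )
        assert fwd == rev

    def test_episodes_disjoint_and_ordered(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, 500).astype(np.int8)
        s = sp.EpochSeries("a", "c", codes, np.zeros(500, bool))
        eps = sp.detect_episodes(s, "N", 16, 8)
        for a, b in zip(eps, eps[1:]):
            assert a.end_epoch < b.start_epoch


class TestTimeInState:
    def test_all_wake_rem_share_is_missing_not_zero(self):
        alloc = sp.time_in_state(series("W" * 1800))
        assert alloc.pct["W"] == 100.0
        assert math.isnan(alloc.rem_pct_tst)
        assert math.isnan(alloc.rem_nrem_ratio)

    def test_mixed_allocation_arithmetic(self):
        alloc = sp.time_in_state(series("N" * 900 + "R" * 100 + "W" * 800))
        assert alloc.pct["N"] == 50.0
        assert alloc.pct["R"] == pytest.approx(100 / 18)
        assert alloc.rem_pct_tst == pytest.approx(10.0)
        assert alloc.rem_nrem_ratio == pytest.approx(1 / 9)

    def test_rem_suppression_lowers_group_mean_rem_share(self):
        base = sp.SleepDynamicsParams()
        vals = {}
        for label, drug in [
            ("saline", sp.IDENTITY_DRUG),
            ("drug", sp.DrugEffectParams(rem_entry_mult=0.5)),
        ]:
            vals[label] = [
                sp.time_in_state(
                    sp.simulate_hypnogram(base, drug, 21600, seed=1000 + i)
                ).rem_pct_tst
                for i in range(12)
            ]
        assert np.mean(vals["drug"]) < np.mean(vals["saline"])


class TestTimecourse:
    def test_six_hour_series_in_hour_bins(self):
        rec = sp.simulate_hypnogram(sp.SleepDynamicsParams(), duration_s=21600, seed=2)
        tc = sp.timecourse(rec, 3600)
        assert len(tc) == 6
        assert list(tc["bin_start_s"]) == [0, 3600, 7200, 10800, 14400, 18000]

    def test_constant_nrem_is_always_100(self):
        tc = sp.timecourse(series("N" * 1800), 600)
        assert (tc["pct_N"] == 100.0).all()

    def test_pooled_window_equals_weighted_mean_of_bins(self):
        rec = sp.simulate_hypnogram(sp.SleepDynamicsParams(), duration_s=7200, seed=3)
        tc = sp.timecourse(rec, 1800)
        pooled = sp.time_in_state(rec, sp.ACUTE)
        assert tc["pct_N"].mean() == pytest.approx(pooled.pct["N"], abs=1e-9)

    def test_bin_longer_than_series_rejected(self):
        with pytest.raises(sp.CoverageError):
            sp.timecourse(series("N" * 10), 3600)


class TestLatencies:
    def test_nrem_latency_counts_wake_prefix(self):
        assert sp.nrem_latency(series("W" * 30 + "N" * 20)) == 120.0

    def test_immediate_sleep_onset_is_offset_only(self):
        s = sp.EpochSeries.from_states(["N"] * 15, t0_offset=8.0)
        assert sp.nrem_latency(s) == 8.0

    def test_no_episode_warns_and_returns_missing(self):
        with pytest.warns(UserWarning, match="no NREM episode"):
            assert math.isnan(sp.nrem_latency(series("NWWWWW" * 6)))

    def test_rem_latency_measured_from_sleep_onset(self):
        s = series("W" * 30 + "N" * 120 + "R" * 5 + "W" * 10)
        # sleep onset at 120 s, first R epoch at (30+120)*4 = 600 s
        assert sp.rem_latency_from_sleep_onset(s) == 480.0

    def test_rem_latency_missing_without_rem(self):
        with pytest.warns(UserWarning, match="no REM"):
            assert math.isnan(sp.rem_latency_from_sleep_onset(series("W" * 5 + "N" * 100)))

    def test_latency_first_qualifying_interval_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            codes = rng.choice(3, 120, p=[0.35, 0.5, 0.15]).astype(np.int8)
            s = sp.EpochSeries("a", "c", codes, np.zeros(120, bool))
            want = oracle_episode_intervals(codes, 1, 15, 4)
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                got = sp.nrem_latency(s)
            if want:
                assert got == 4.0 * want[0][0]
            else:
                assert math.isnan(got)


class TestNremBeforeRem:
    def test_simple_accumulation(self):
        res = sp.nrem_before_first_rem(series("N" * 30 + "R"))
        assert res.minutes == 2.0 and not res.censored

    def test_wake_prefix_contributes_nothing(self):
        res = sp.nrem_before_first_rem(series("W" * 50 + "N" * 15 + "R"))
        assert res.minutes == 1.0

    def test_no_rem_returns_total_censored(self):
        res = sp.nrem_before_first_rem(series("W" * 5 + "N" * 45))
        assert res.minutes == 3.0 and res.censored

    def test_matches_cumulative_sum_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            codes = rng.integers(0, 3, 200).astype(np.int8)
            s = sp.EpochSeries("a", "c", codes, np.zeros(200, bool))
            rem = np.flatnonzero(codes == 2)
            stop = rem[0] if rem.size else 200
            want = 4.0 * (codes[:stop] == 1).sum() / 60.0
            assert sp.nrem_before_first_rem(s).minutes == pytest.approx(want)


class TestBriefAwakenings:
    def test_short_intrusion_counts(self):
        assert sp.brief_awakenings(series("NNWWNN")).count == 1

    def test_long_intrusion_excluded(self):
        assert sp.brief_awakenings(series("NWWWWWN")).count == 0

    def test_window_edge_runs_excluded(self):
        assert sp.brief_awakenings(series("WWNNNNNN")).count == 0
        assert sp.brief_awakenings(series("NNNNNNWW")).count == 0

    def test_rem_flank_counts_as_sleep(self):
        assert sp.brief_awakenings(series("RRWNRR")).count == 1

    def test_rate_is_per_hour_of_sleep(self):
        ba = sp.brief_awakenings(series("N" * 898 + "WW" + "N" * 900))
        assert ba.tst_h == pytest.approx(1798 * 4 / 3600)
        assert ba.rate_per_h_sleep == pytest.approx(1 / ba.tst_h)

    def test_rate_missing_without_sleep(self):
        assert math.isnan(sp.brief_awakenings(series("W" * 10)).rate_per_h_sleep)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=80)
    def test_count_bounded_by_short_wake_runs(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 3, 150).astype(np.int8)
        s = sp.EpochSeries("a", "c", codes, np.zeros(150, bool))
        short_runs = [r for r in _state_runs(codes, 0) if r[1] - r[0] + 1 <= 4]
        assert sp.brief_awakenings(s).count <= len(short_runs)

    def test_hazard_halving_detected_at_cohort_scale(self):
        base = sp.SleepDynamicsParams()
        rates = {}
        for label, drug in [
            ("saline", sp.IDENTITY_DRUG),
            ("drug", sp.DrugEffectParams(ba_hazard_mult=0.5)),
        ]:
            rates[label] = np.array([
                sp.brief_awakenings(
                    sp.simulate_hypnogram(base, drug, 21600, seed=2000 + i)
                ).rate_per_h_sleep
                for i in range(12)
            ])
        eff = sp.paired_t(rates["drug"], rates["saline"], side="less")
        assert eff.p < 0.05


class TestEpisodeStats:
    def test_basic_summary(self):
        eps = [sp.Episode("N", 0, 14), sp.Episode("N", 30, 74)]
        stats = sp.episode_stats(eps)
        assert stats.count == 2
        assert stats.mean_span_s == 120.0
        assert stats.max_span_s == 180.0

    def test_empty_is_missing(self):
        stats = sp.episode_stats([])
        assert stats.count == 0
        assert math.isnan(stats.mean_span_s) and math.isnan(stats.max_span_s)

    def test_window_filters_by_start_and_total_bounded(self):
        rec = sp.simulate_hypnogram(sp.SleepDynamicsParams(), duration_s=21600, seed=9)
        eps = sp.detect_episodes(rec, "N")
        stats = sp.episode_stats(eps, sp.ACUTE)
        assert stats.count <= len(eps)
        full = sp.episode_stats(eps)
        assert full.mean_span_s * full.count <= 21600.0


def test_summary_percentages_always_partition(cno_study):
    arch = cno_study.tables["architecture"]
    wide = arch.pivot_table(
        index=["animal_id", "condition", "window"], columns="metric", values="value"
    )
    total = wide["pct_W"] + wide["pct_N"] + wide["pct_R"]
    assert np.allclose(total, 100.0)
    assert ((wide["rem_pct_tst"] >= 0) & (wide["rem_pct_tst"] <= 100)).all()
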