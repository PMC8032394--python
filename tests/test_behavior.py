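"""Behavioral statistics: interval arithmetic, preference/habituation indices,
success rates, threshold scan, and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from olfquant import (
    Epoch,
    EpochSchedule,
    EventStream,
    cross_habituation_delta_npi,
    cross_habituation_schedule,
    delta_npi,
    dishabituation_threshold_scan,
    epoch_durations,
    group_anova,
    isi_statistics,
    npi,
    preference_index,
    success_rate_go_nogo,
    success_rate_two_choice,
)
from olfquant.behavior import BaselineError, EpochSummary, ScheduleError, SpikeTrain


def make_summary(air_ts, odor_ts, epoch_s=300.0, gap_s=0.0):
    """EpochSummary with prescribed per-epoch investigation times."""
    rows, t = [], 0.0
    for T in air_ts:
        rows.append({"kind": "air", "odor_id": None, "concentration": None,
                     "start_s": t, "end_s": t + epoch_s, "T": float(T),
                     "n_events": 1, "n_long_events": 1})
        t += epoch_s + gap_s
    for T in odor_ts:
        rows.append({"kind": "odor", "odor_id": "odor", "concentration": 1e-4,
                     "start_s": t, "end_s": t + epoch_s, "T": float(T),
                     "n_events": 1, "n_long_events": 1})
        t += epoch_s + gap_s
    return EpochSummary(per_epoch=pd.DataFrame(rows),
                        baseline_indices=tuple(range(len(air_ts))))


class TestEpochDurations:
    def test_interval_arithmetic_within_one_epoch(self, one_air_epoch):
        stream = EventStream(intervals=[(1.0, 3.0), (5.0, 6.0)])
        summary = epoch_durations(stream, one_air_epoch)
        row = summary.per_epoch.iloc[0]
        assert row["T"] == 3.0
        assert row["n_events"] == 2
        assert row["n_long_events"] == 1  # the exactly-1-s bout is not "longer than 1 s"

    def test_boundary_spanning_bout_is_clipped_to_each_side(self):
        schedule = EpochSchedule((Epoch("air", 0.0, 300.0), Epoch("odor", 300.0, 600.0, "o")))
        summary = epoch_durations(EventStream(intervals=[(295.0, 305.0)]), schedule)
        assert summary.per_epoch["T"].tolist() == [5.0, 5.0]

    def test_matches_millisecond_discretized_oracle(self):
        rng = np.random.default_rng(11)
        onsets = np.sort(rng.uniform(0, 590, size=40))
        offsets = onsets + rng.uniform(0.05, 8.0, size=40)
        merged = []
        for a, b in zip(onsets, offsets):
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        stream = EventStream(intervals=np.array(merged))
        schedule = EpochSchedule((Epoch("air", 0.0, 300.0), Epoch("odor", 300.0, 600.0, "o")))
        summary = epoch_durations(stream, schedule)
        # 1 ms membership grid as an independent oracle
        grid = np.arange(0, 600.0, 0.001) + 0.0005
        member = np.zeros_like(grid, dtype=bool)
        for a, b in merged:
            member |= (grid >= a) & (grid < b)
        for i, (lo, hi) in enumerate([(0, 300), (300, 600)]):
            oracle_t = member[(grid >= lo) & (grid < hi)].sum() * 0.001
            assert summary.per_epoch["T"].iloc[i] == pytest.approx(oracle_t, abs=0.05)

    def test_time_conservation_when_schedule_covers_session(self):
        stream = EventStream(intervals=[(10.0, 12.0), (100.0, 101.5), (450.0, 452.0)])
        schedule = EpochSchedule((Epoch("air", 0.0, 300.0), Epoch("odor", 300.0, 600.0, "o")))
        summary = epoch_durations(stream, schedule)
        assert summary.per_epoch["T"].sum() == pytest.approx(stream.total_time_s)

    def test_stream_outside_schedule_warns_and_zeroes(self, one_air_epoch):
        stream = EventStream(intervals=[(500.0, 501.0)])
        with pytest.warns(UserWarning, match="outside the schedule"):
            summary = epoch_durations(stream, one_air_epoch)
        assert summary.per_epoch["T"].sum() == 0.0

    def test_empty_schedule_rejected(self):
        with pytest.raises(ScheduleError):
            EpochSchedule(())


class TestPreferenceIndex:
    def test_no_preference_symmetry(self):
        summary = make_summary([10, 10, 10, 10], [10, 10, 10, 10])
        assert preference_index(summary).pi == 0.0

    def test_hand_computed_value(self):
        # 100 * (20 + 16 - 2*8) / (4 * 10) = 50
        summary = make_summary([12, 10, 10, 8], [20, 16, 5, 5])
        res = preference_index(summary)
        assert res.pi == pytest.approx(50.0)
        assert res.t_air_last == 8.0
        assert res.t_ave_air == pytest.approx(10.0)

    def test_unit_rescaling_invariance(self):
        a = preference_index(make_summary([12, 10, 10, 8], [20, 16, 5, 5])).pi
        b = preference_index(make_summary([1.2, 1.0, 1.0, 0.8], [2.0, 1.6, 0.5, 0.5],
                                          epoch_s=30.0)).pi
        assert a == pytest.approx(b)

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(BaselineError):
            preference_index(make_summary([0, 0, 0, 0], [5, 5, 5, 5]))

    def test_needs_two_odor_epochs(self):
        with pytest.raises(ScheduleError):
            preference_index(make_summary([10, 10], [5]))


class TestNpiAndDeltaNpi:
    @pytest.mark.parametrize("t, base, expected", [(8.0, 8.0, 1.0), (0.0, 8.0, 0.0),
                                                   (12.0, 8.0, 1.5)])
    def test_npi_values(self, t, base, expected):
        assert npi(t, base) == pytest.approx(expected)

    def test_npi_zero_baseline_rejected(self):
        with pytest.raises(BaselineError):
            npi(1.0, 0.0)

    def test_delta_npi_identical_odors_is_zero(self):
        summary = make_summary([8, 8], [4, 4])
        assert delta_npi(summary, 3, 2) == 0.0

    def test_delta_npi_hand_computed(self):
        # 100 * (12 - 4) / 8 = 100
        summary = make_summary([8, 8], [4, 12])
        assert delta_npi(summary, novel_epoch=3, habituated_epoch=2) == pytest.approx(100.0)

    def test_cross_habituation_picks_novel_and_last_habituated(self):
        schedule = cross_habituation_schedule(n_air=2, n_habituated=2, n_novel=1)
        rows = []
        for i, ep in enumerate(schedule):
            rows.append({"kind": ep.kind, "odor_id": ep.odor_id,
                         "concentration": ep.concentration,
                         "start_s": ep.start_s, "end_s": ep.end_s,
                         "T": [8.0, 8.0, 6.0, 4.0, 12.0][i],
                         "n_events": 1, "n_long_events": 1})
        summary = EpochSummary(per_epoch=pd.DataFrame(rows), baseline_indices=(0, 1))
        assert cross_habituation_delta_npi(summary) == pytest.approx(100.0)


class TestThresholdScan:
    def test_step_response_flags_the_step_concentration(self):
        from olfquant import gen_dishabituation_scan_table

        conc = [1e-8, 1e-7, 1e-6, 1e-5, 1e-4]
        hits = 0
        for seed in range(60):
            tidy = gen_dishabituation_scan_table(conc, n_subjects=9, seed=seed,
                                                 effect_at=1e-5, effect_size=2.0,
                                                 npi_noise_sd=0.3)
            res = dishabituation_threshold_scan(tidy)
            if res.threshold_concentration == pytest.approx(1e-5):
                hits += 1
        # the step itself is always flagged; a false flag at one of the three
        # lower concentrations (5% each) caps P(first = step) at 0.95^3 ~ 0.857
        assert hits >= 44

    def test_single_subject_gives_means_without_pvalues(self):
        from olfquant import gen_dishabituation_scan_table

        tidy = gen_dishabituation_scan_table([1e-8, 1e-7, 1e-6], n_subjects=1, seed=0)
        res = dishabituation_threshold_scan(tidy)
        assert res.n_subjects == 1
        assert res.table["p_value"].isna().all()
        assert res.threshold_concentration is None
        assert res.table["mean_delta_npi"].notna().all()

    def test_summaries_route_matches_tidy_route(self):
        from olfquant import EventStream, dishabituation_schedule, epoch_durations
        from olfquant.behavior import _scan_table_from_summaries

        schedule = dishabituation_schedule([1e-8, 1e-6], n_initial_air=2)
        rng = np.random.default_rng(5)
        summaries = []
        for s in range(3):
            iv = []
            for ep in schedule:
                on = rng.uniform(ep.start_s, ep.end_s - 2.0)
                iv.append((on, on + rng.uniform(0.5, 2.0)))
            summaries.append(epoch_durations(EventStream(intervals=np.array(sorted(iv))),
                                             schedule))
        tidy = _scan_table_from_summaries(summaries)
        assert set(tidy["concentration"]) == {1e-8, 1e-6}
        a = dishabituation_threshold_scan(summaries).table
        b = dishabituation_threshold_scan(tidy).table
        pd.testing.assert_frame_equal(a, b)


class TestSuccessRates:
    def test_two_choice_all_correct(self):
        trials = pd.DataFrame({"stimulus": ["A", "B"] * 5,
                               "action": ["portA", "portB"] * 5})
        assert success_rate_two_choice(trials) == 100.0

    def test_two_choice_hand_computed(self):
        # P[A/A]=3, P[B/B]=2, Ptotal=10 -> 50
        stim = ["A"] * 5 + ["B"] * 5
        act = ["portA"] * 3 + ["portB"] * 2 + ["portB"] * 2 + ["portA"] * 3
        assert success_rate_two_choice(pd.DataFrame({"stimulus": stim, "action": act})) == 50.0

    def test_go_nogo_perfect_discrimination(self):
        trials = pd.DataFrame({"stimulus": ["CS+", "CS-"] * 4,
                               "action": ["lick", "no-lick"] * 4})
        assert success_rate_go_nogo(trials) == 100.0

    def test_go_nogo_hand_computed(self):
        # PCS+=4, NPCS+=1, PCS-=2, NPCS-=3 -> 70
        stim = ["CS+"] * 5 + ["CS-"] * 5
        act = ["lick"] * 4 + ["no-lick"] + ["lick"] * 2 + ["no-lick"] * 3
        assert success_rate_go_nogo(pd.DataFrame({"stimulus": stim, "action": act})) == 70.0

    @pytest.mark.parametrize("fn", [success_rate_two_choice, success_rate_go_nogo])
    def test_empty_table_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(pd.DataFrame({"stimulus": [], "action": []}))


class TestIsiStatistics:
    def test_regular_train(self):
        train = SpikeTrain(times_s=np.arange(0.5, 10.0, 0.5), duration_s=9.5)
        res = isi_statistics([train, train], ["a", "a"])
        row = res.per_train.iloc[0]
        assert row["firing_rate_hz"] == pytest.approx(2.0)
        assert row["mean_log_isi"] == pytest.approx(np.log(0.5))

    def test_short_train_excluded_with_warning(self):
        good = SpikeTrain(times_s=np.arange(0.5, 10.0, 0.5), duration_s=10.0)
        bad = SpikeTrain(times_s=np.array([1.0]), duration_s=10.0)
        with pytest.warns(UserWarning, match="excluded"):
            res = isi_statistics([good, bad], ["a", "b"])
        assert len(res.per_train) == 1
        assert res.anova is None


class TestGroupAnova:
    def test_hand_computed_three_group_example(self):
        # groups (1,2,3),(2,3,4),(3,4,5): SSB=6, SSW=6, F=(6/2)/(6/6)=3, p=0.125
        values = [1, 2, 3, 2, 3, 4, 3, 4, 5]
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = group_anova(values, labels)
        assert res.f == pytest.approx(3.0)
        assert res.p == pytest.approx(0.125)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups_zero_f_convention(self):
        res = group_anova([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.f == 0.0 and res.p == 1.0

    def test_two_groups_f_equals_t_squared(self):
        a, b = [1.0, 2.0, 3.5, 2.2], [2.0, 3.1, 4.0, 3.3]
        res = group_anova(a + b, ["a"] * 4 + ["b"] * 4)
        t = sps.ttest_ind(a, b)
        assert res.f == pytest.approx(t.statistic ** 2)
        assert res.p == pytest.approx(t.pvalue)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        res = group_anova(values, labels)
        ref = sps.f_oneway(*(values[labels == u] for u in "abc"))
        assert res.f == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_tukey_posthoc_table(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(3, 1, 8), rng.normal(0, 1, 8)])
        labels = np.repeat(["a", "b", "c"], 8)
        res = group_anova(values, labels, posthoc=True)
        assert res.posthoc is not None and len(res.posthoc) == 3

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_anova([1, 2, 3], ["a", "a", "b"])
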