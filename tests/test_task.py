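"""MOM-task schedule, behaviour, and epoch-generation tests."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import momdecode as m


class TestSchedule:
    def test_default_design_counts(self):
        """The published design: 1920 dots over 30 main blocks, 64 per block,
        32 per colour, 16 (Active) / 2 (Monitoring) targets among cued dots,
        matched distractor events among non-cued dots."""
        sch = m.generate_schedule(m.TaskConfig(), seed=1)
        df = m.schedule_to_frame(sch)
        assert len(df) == 1920
        assert df["block_index"].nunique() == 30
        for _, g in df.groupby("block_index"):
            assert len(g) == 64
            assert (g["colour"] == "cued").sum() == 32
            n_targets = (g["role"] == "target").sum()
            n_distr = (g["role"] == "distractor_event").sum()
            assert n_targets == n_distr == (16 if g["condition"].iat[0] == "active" else 2)
            assert (g.loc[g["role"] == "target", "colour"] == "cued").all()
            assert (g.loc[g["role"] == "distractor_event", "colour"] == "noncued").all()

    def test_monitoring_block_target_fraction(self):
        """A Monitoring block has exactly 2 targets among its 32 cued dots."""
        sch = m.generate_schedule(m.TaskConfig(condition_order="monitoring_first"), seed=3)
        block0 = [d for d in sch if d.block_index == 0]
        cued = [d for d in block0 if d.colour == "cued"]
        assert len(cued) == 32
        assert sum(d.role == "target" for d in cued) == 2

    def test_zero_target_config(self):
        cfg = m.TaskConfig(targets_active=0, targets_monitoring=0, n_blocks_per_condition=1)
        sch = m.generate_schedule(cfg, seed=4)
        assert all(d.role == "event" for d in sch)

    def test_timing_and_onsets(self, small_task):
        sch = m.generate_schedule(small_task, seed=5)
        df = m.schedule_to_frame(sch)
        block_ms = small_task.block_duration_s * 1000
        assert (df["onset_ms"] >= 0).all() and (df["onset_ms"] <= block_ms).all()
        assert (df["deflection_ms"] < df["collision_ms"]).all()
        assert abs(df["deflection_ms"].mean() - 1226) < 15
        # directions approximately even within each block
        per_block = df.groupby("block_index")["direction"].apply(
            lambda s: abs((s == "left").sum() - (s == "right").sum())
        )
        assert (per_block <= small_task.dots_per_block // 2).all()

    def test_scheduling_error(self):
        with pytest.raises(m.SchedulingError):
            m.generate_schedule(m.TaskConfig(block_duration_s=1.0), seed=6)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            m.TaskConfig(dots_per_colour=10)  # 2 x 10 != 64
        with pytest.raises(ValueError):
            m.TaskConfig(targets_monitoring=20)  # exceeds targets_active


class TestBehaviour:
    def test_flat_model_no_trend(self):
        """With zero slopes, blockwise miss rates show no early/late trend."""
        flat = m.BehaviourModel(
            vigilance_slope=0.0, active_learning_slope=0.0,
            monitoring_extra_miss=0.0, active_floor=0.0,
        )
        rates = {"early": [], "late": []}
        for s in range(6):
            sch = m.simulate_behaviour(m.generate_schedule(m.TaskConfig(), 40 + s), flat, 50 + s)
            summ = m.summarize_behaviour(sch)
            n = summ["block_in_condition"].max()
            rates["early"].append(summ[summ["block_in_condition"] <= n // 2]["miss_rate"].mean())
            rates["late"].append(summ[summ["block_in_condition"] > n // 2]["miss_rate"].mean())
        assert abs(np.mean(rates["early"]) - np.mean(rates["late"])) < 0.05

    def test_perfect_performance(self, small_task):
        perfect = m.BehaviourModel(
            base_miss_prob=0.0, monitoring_extra_miss=0.0, vigilance_slope=0.0,
            active_floor=0.0, fa_rate=0.0,
        )
        sch = m.simulate_behaviour(m.generate_schedule(small_task, 7), perfect, 8)
        df = m.schedule_to_frame(sch)
        assert (df.loc[df["role"] == "target", "outcome"] == "hit").all()
        assert not df["outcome"].str.startswith("false_alarm").any()
        assert (m.summarize_behaviour(sch)["miss_rate"] == 0).all()

    def test_rt_within_response_window(self, behaved_schedule):
        hits = [d for d in behaved_schedule if d.outcome == "hit"]
        assert hits
        for d in hits:
            assert 0.0 < d.rt_ms <= d.collision_ms - d.deflection_ms
        # rt defined iff a press is attributed
        for d in behaved_schedule:
            if d.outcome not in ("hit",):
                assert np.isnan(d.rt_ms)

    def test_outcomes_only_on_cued_targets(self, behaved_schedule):
        for d in behaved_schedule:
            if d.outcome in ("hit", "miss"):
                assert d.role == "target" and d.colour == "cued"

    def test_vigilance_decrement_pattern(self):
        """Group-mean Monitoring miss rates rise with block index while
        Active rates fall over the first blocks and then plateau."""
        frames = []
        for s in range(21):
            sch = m.simulate_behaviour(
                m.generate_schedule(m.TaskConfig(), 100 + s), m.BehaviourModel(), 200 + s
            )
            frames.append(m.summarize_behaviour(sch))
        summ = pd.concat(frames)
        mean = summ.groupby(["condition", "block_in_condition"])["miss_rate"].mean()
        mon = mean["monitoring"]
        act = mean["active"]
        assert np.polyfit(mon.index, mon.to_numpy(), 1)[0] > 0
        assert np.polyfit(act.index[:5], act.to_numpy()[:5], 1)[0] < 0
        assert abs(act[act.index >= 6].mean() - 0.17) < 0.05

    def test_blockwise_bf_contrast_late_blocks(self):
        """At 21 simulated subjects the Active-vs-Monitoring miss-rate
        contrast reaches BF > 3 in the late blocks."""
        frames = []
        for s in range(21):
            sch = m.simulate_behaviour(
                m.generate_schedule(m.TaskConfig(), 300 + s), m.BehaviourModel(), 400 + s
            )
            f = m.summarize_behaviour(sch)
            f["subject"] = s
            frames.append(f)
        summ = pd.concat(frames)
        late = summ[summ["block_in_condition"] >= 13]
        piv = late.pivot_table(
            index="subject", columns="condition", values="miss_rate", aggfunc="mean"
        )
        bf = m.jzs_bf_ttest(piv["monitoring"].to_numpy(), piv["active"].to_numpy(), paired=True)
        assert bf > 3


class TestSummaries:
    def test_miss_rate_arithmetic(self):
        base = dict(
            block_index=0, block_in_condition=1, condition="monitoring",
            onset_ms=0.0, colour="cued", direction="left", role="target",
            deflection_ms=1226.0, collision_ms=1636.0,
        )
        dots = [
            m.DotTrial(trial_id=0, outcome="miss", **base),
            m.DotTrial(trial_id=1, outcome="hit", rt_ms=200.0, **base),
        ]
        summ = m.summarize_behaviour(dots)
        assert summ["miss_rate"].iat[0] == 0.5
        assert summ["mean_correct_rt_ms"].iat[0] == 200.0

    def test_zero_target_block_flagged_nan(self):
        cfg = m.TaskConfig(targets_active=0, targets_monitoring=0, n_blocks_per_condition=1)
        sch = m.simulate_behaviour(m.generate_schedule(cfg, 9), m.BehaviourModel(), 10)
        summ = m.summarize_behaviour(sch)
        assert (summ["n_targets"] == 0).all()
        assert summ["miss_rate"].isna().all()


class TestEpochSimulation:
    def test_determinism(self, small_task, small_sensors):
        a = m.generate_schedule(small_task, seed=11)
        b = m.generate_schedule(small_task, seed=11)
        assert a == b
        beh_a = m.simulate_behaviour(a, m.BehaviourModel(), seed=12)
        beh_b = m.simulate_behaviour(b, m.BehaviourModel(), seed=12)
        pd.testing.assert_frame_equal(
            m.schedule_to_frame(beh_a), m.schedule_to_frame(beh_b)
        )
        ep_a = m.simulate_epochs(beh_a[:20], small_sensors, seed=13)
        ep_b = m.simulate_epochs(beh_b[:20], small_sensors, seed=13)
        np.testing.assert_array_equal(ep_a.data, ep_b.data)

    def test_epoch_shape_and_labels(self, subject_epochs, behaved_schedule):
        assert subject_epochs.data.shape[0] == len(behaved_schedule)
        assert subject_epochs.time_ms[0] == -100.0
        assert subject_epochs.time_ms[-1] == 3000.0
        assert set(subject_epochs.labels["epoch_half"]) <= {"early", "mid", "late"}

    def test_epoch_half_labels_canonical(self):
        halves = [m.epoch_half_of_block(b, 15) for b in range(1, 16)]
        assert halves[:5] == ["early"] * 5
        assert halves[10:] == ["late"] * 5
        assert set(halves[5:10]) == {"mid"}

    def test_noise_free_attended_direction_separable(self, small_task):
        """With zero noise the direction signal makes classes separable:
        downstream decoding is perfect after signal onset."""
        sm = m.SensorModel(n_sensors=8, fs_hz=200.0, noise_sd=0.0,
                           attention_gain=1.0, trial_amp_jitter_sd=0.0)
        sch = m.simulate_behaviour(m.generate_schedule(small_task, 14), m.BehaviourModel(), 15)
        ep = m.simulate_epochs(sch[:40], sm, seed=16)
        t = ep.time_ms
        window = (t > 300) & (t < 1000)
        res = m.decode_direction_timecourse(
            m.EpochSet(ep.data[:, :, window], t[window], ep.fs_hz, ep.labels),
            cv=m.CVScheme(n_folds=5, seed=17),
        )
        assert res.accuracy.mean() == 1.0

    def test_sensor_model_validation(self):
        with pytest.raises(ValueError):
            m.SensorModel(miss_attenuation=1.5)
        with pytest.raises(ValueError):
            m.SensorModel(n_sensors=8, frontal_group=(0, 1), occipital_group=(1, 2))
        with pytest.raises(ValueError):
            m.SensorModel(n_sensors=8, occipital_group=(9,))
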