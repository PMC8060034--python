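"""Predicting behavioural misses from neural data before they happen.

Three steps on a small 5-subject cohort: (1) train distance classifiers on
correct trials only and test them on held-out correct and on miss trials —
distance information drops on misses; (2) summarise single-trial accuracy
distributions as a correct-vs-miss Cohen's d; (3) accumulate classifier
correctness along the trajectory and label a trial "miss" when its
accumulated accuracy falls below a validation-derived threshold, with the
threshold multiple transferred leave-one-subject-out.
"""

import numpy as np

import momdecode as m

task = m.TaskConfig(
    dots_per_block=24, dots_per_colour=12, targets_active=6,
    targets_monitoring=2, n_blocks_per_condition=10, block_duration_s=60.0,
)

cohort = []
for s in range(5):
    sch = m.simulate_behaviour(m.generate_schedule(task, 20 + s), m.BehaviourModel(), 40 + s)
    ep = m.downsample(m.simulate_epochs(sch, m.SensorModel(n_sensors=16), seed=60 + s), 200.0)
    cohort.append(m.pool_directions(m.bin_distances(ep, samples_per_bin=3)))

gen = m.train_correct_test_miss(cohort[0], seed=1)
pc, pm = gen.per_distance()
print(f"subject 1: {gen.correct_ids.size} correct / {gen.miss_ids.size} miss trials, "
      f"{gen.n_folds} folds")
print(f"mean distance decoding  correct {np.nanmean(pc):.3f}   miss {np.nanmean(pm):.3f}")

dist = m.single_trial_accuracy_distributions(gen.correct_trial_acc, gen.miss_trial_acc)
print(f"single-trial accuracy   correct {dist.correct.mean():.3f}   miss {dist.miss.mean():.3f}"
      f"   Cohen's d = {dist.cohens_d:.2f}")

data = [m.prepare_prediction_data(b, seed=100 + s) for s, b in enumerate(cohort)]
for res in m.loso_predict(data):
    acc = res.accuracy_by_distance
    print(f"subject {res.subject + 1}: LOSO threshold multiple m* = {res.chosen_m:.2f}, "
          f"outcome-prediction accuracy {acc.mean():.3f} "
          f"(farthest distance {acc[14]:.3f} -> nearest {acc[0]:.3f}; chance 0.5)")
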