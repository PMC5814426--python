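"""Train the scaled-down CNN on a synthetic cohort and evaluate it.

Runs the core experiment at desk scale: 60 train / 20 test subjects,
quarter-width network, a few optimizer passes.  Subject-level calls
average each subject's 40 per-epoch male probabilities and threshold at
0.5.  Accuracy is compared against the Monte-Carlo chance threshold for
the test-set size.  Expect several minutes on one CPU; accuracy grows
with more subjects and runs (see docs/methods.md for the sizes the
acceptance suite uses).
"""

import numpy as np

import eegsex as e

cohort_spec = e.CohortSpec(n_subjects=80, seed=5)
epochsets = [e.preprocess_recording(r) for r in e.iter_cohort(cohort_spec)]
train_set, test_set = e.split_cohort(epochsets, 60, seed=0)

net = e.build_network(e.default_archspec(filter_scale=0.25), seed=1)
X, y = e.stack_epochsets(train_set)
result = e.train(net, X, y, e.TrainConfig(max_runs=4, seed=2))
print(result.history.to_string(index=False))
print("stopped because:", result.stop_reason)

table = e.predict_subjects(net, test_set)
acc = e.subject_accuracy(table)
null = e.simulate_null_threshold(
    len(test_set), float(np.mean([s.sex for s in test_set])), 0.47,
    n_sims=100_000, seed=3)
print(f"subject-level test accuracy: {acc:.1f}%")
print(f"chance threshold (p<1e-5, n={len(test_set)}): "
      f"{null.threshold_percent}%")
print("significant" if acc > null.threshold_percent else
      "not significant at this scale")
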