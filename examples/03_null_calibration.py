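"""Calibrate the chance-level accuracy threshold by Monte-Carlo.

With 308 test subjects (49% male) and labels assigned at random with the
cohort prior of 47% male, the expected accuracy of guessing is
0.49*0.47 + 0.51*0.53 ~ 50.06%.  The maximum accuracy over 100,000
simulations estimates the p < 1e-5 chance level: any classifier scoring
above it is significant at that level.  The printed threshold should be
about 63%.
"""

import eegsex as e

res = e.simulate_null_threshold(n_subjects=308, true_male_fraction=0.49,
                                assigned_male_fraction=0.47,
                                n_sims=100_000, seed=1)
print(f"simulations: {res.n_sims:,} at n={res.n_subjects}")
print(f"mean chance accuracy: {res.accuracies.mean() * 100:.2f}% "
      "(analytic: 50.06%)")
print(f"significance threshold (max over sims): {res.threshold_percent}%")

small = e.simulate_null_threshold(40, 0.475, 0.47, 100_000, seed=1)
print(f"for a 40-subject test set the threshold rises to "
      f"{small.threshold_percent}% — small cohorts need much higher "
      "accuracy to beat chance")
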