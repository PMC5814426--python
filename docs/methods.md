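# Methods

## The analysis in one paragraph

A convolutional network receives raw 2-second epochs of preprocessed
eyes-closed EEG (256 time samples × 24 channels at 128 Hz) and outputs a
male/female probability. A subject is called male when the mean of the
per-epoch male probabilities over their 40 epochs exceeds 0.5. Accuracy
is the percentage of correctly called subjects on a held-out test set,
and it is judged against a chance threshold calibrated by Monte-Carlo
simulation at p < 10⁻⁵. The feature the trained network relies on is
exposed two ways: by activation maximization of its convolutional
filters (surrogate inputs whose spectra reveal the preferred rhythm) and
by a classical comparison of Welch band powers between the sexes.

## Synthetic cohorts

No public cohort exists for this analysis, so the generator is the
ground-truth instrument. Each subject's recording is the sum of three
independent Gaussian components per channel, synthesized in the
frequency domain (random-phase spectra, one inverse FFT per channel):

- **1/f background** — random-phase spectrum with deterministic modulus
  ∝ f^(−γ/2), γ = 1 (flattened below 0.5 Hz), RMS 10 µV;
- **alpha** (8–12 Hz), RMS 6 µV before a fixed posterior weighting
  (×1 + 0.8·max(−y, 0) from the schematic electrode y-coordinate),
  reflecting the posterior dominance of eyes-closed alpha;
- **fast beta** (20–25 Hz), RMS 3 µV. Band-limited components are
  complex-normal in the frequency domain under a 4th-order Butterworth
  magnitude mask — filtered white noise, with the natural χ²-like
  epoch-to-epoch band-power fluctuation the oscillatory components need.

Inter-subject variability: each component's amplitude is multiplied by a
per-subject lognormal factor with CV 0.3 (shared across channels), plus
a smaller per-channel lognormal jitter (CV 0.05). The amplitudes and
jitter are the package's own realism choices — values a clinical
neurophysiologist would accept for adult resting EEG in µV — and are
deliberately not tuned further.

The planted sex difference multiplies the female beta amplitude by
1 + (g−1)·w(ch), with g = 1.4 and w = 1 on montage channels 4–20
(Fz…Pz, the fronto-central/centro-parietal strip) and w = 0.3
elsewhere, plus a broadband female gain of 1.05 on all components. With
g = 1 male and female recordings are identically distributed, which is
the null cohort used for control experiments. Both gains are
configurable; the defaults define the study conditions used throughout
the tests.

What the generator does **not** emulate: volume conduction / a forward
head model (channels are independent up to shared amplitude factors),
eye-movement or muscle artifacts (source data are assumed
EOG-corrected), age structure, eyes-open recordings, and non-Gaussian
waveform morphology. Passing tests therefore show that the pipeline
recovers a planted spectral-spatial group difference of realistic size
from realistically noisy amplitudes — not that real cohorts carry such a
difference.

## Preprocessing

Channel selection (24 of 26; O2 and Oz dropped so the channel axis
factorizes as 3·2·2·2 for pooling), polyphase rational resampling
500→128 Hz (32/125, FIR anti-aliasing), then a **causal** first-order
Butterworth band-pass 0.5–25 Hz — the stated "minimum phase distortion"
filter is read as minimum-phase/causal; zero-phase forward-backward
filtering is available as a flag. Epochs are the first 40 contiguous
non-overlapping 2-s segments. Network inputs are divided by a fixed
100 µV constant (an arbitrary O(1) normalization that leaks no
per-epoch information); per-epoch standardization is available but not
default. A first-order high-pass rolls off at only 6 dB/oct, so small
residual per-epoch means (≲ 0.3 of channel RMS in the worst epoch)
remain; this is inherent to the stated filter order.

## Network and training

The 15-row layer stack is taken verbatim from the reference layer table
(filters 100/100/300/300/100/100; kernels 3×3, 3×3, 2×3, 1×7, 1×3, 1×3
as channel-axis × time-axis; max-pools 2×2, 2×2, 2×2, 1×2; dropout 25%
after the first four pools; dense softmax head). Unstated details are
fixed as: same-padding (valid padding would collapse the 3-row channel
axis before the later kernels can act), max pooling, Glorot-uniform
initialization, Adamax ε = 10⁻⁸ (the printed 10⁸ is a typo that would
freeze updates). With these choices the shape arithmetic gives
24→12→6→3→3 channels and 256→128→64→32→16 time points, a 4800-unit
feature block, and exact parameter counts (conv stack 1,021,900; total
1,031,502). The prose variant of the architecture (300/300/50… filters,
2×2 kernels) is expressible through `ArchSpec` but not default, and the
separately printed total of 9,051,902 parameters is not reconcilable
with the table under any standard padding/pooling reading, so it is not
used anywhere.

The engine is a self-contained NumPy implementation (channels-last
im2col convolutions so each pass is one BLAS product, inverted dropout,
fused ReLU, Adamax). `count_parameters` is pure arithmetic on the spec
and is cross-checked in tests against the engine's actual parameter
arrays — two independent routes to the same number.

Training follows the original recipe (Adamax lr 0.002, β₁ 0.9,
β₂ 0.999; categorical cross-entropy; batches of 70; stopping on 100%
training accuracy, loss plateau, or the run budget). The plateau rule
"loss did not further decrease" is operationalized as no improvement
≥ 10⁻⁴ for 10 consecutive runs. Training accuracy per run is
accumulated from the pre-update forward passes, the usual convention.
Determinism is best-effort: seeded initialization, shuffling and
dropout give bit-reproducible runs on a fixed BLAS configuration.

## Chance calibration

True test labels are held fixed at exactly round(0.49·n) males; each of
100,000 simulations assigns every subject male independently with
probability 0.47 and is scored against the truth. The maximum accuracy
over simulations, rounded to a whole percent, is the p < 10⁻⁵
threshold. A single simulated accuracy is Binomial(n, q·m+(1−q)(1−m))/n
— ≈ 0.5006 at the study fractions — and the simulated distribution is
checked against that binomial by a goodness-of-fit test. For n = 308
the threshold lands at 63% (62–64 across seeds); for n = 40 it rises to
~85%, which is the bar the desk-scale CNN experiments must clear. The
null simulation fixes the true labels and redraws only the assignments;
redrawing the truth per simulation is a defensible alternative reading
and changes the threshold by well under a percentage point.

## Activation maximization

For a (layer, filter) pair the objective is the mean post-activation
response of that filter's map. Ascent starts from seeded uniform noise
in [−0.05, 0.05]; each step normalizes the gradient to unit RMS and
moves by `step_size` (default 0.1); a step that would lower the
objective is rejected and halves that surrogate's step, making the
recorded loss trajectory non-decreasing without an explicit
regularizer. Filters whose objective stays at zero (dead ReLU paths)
are flagged degenerate. Surrogates are characterized by the row-averaged
amplitude spectrum (peak frequency within 0.5–25 Hz) and per-channel
power shares. A subtlety discovered in testing: with a purely *linear*
activation this objective is blind to the filter's oscillation (the
kernel summed over all shifts cancels), so analytic template-recovery
checks use rectified filters — as does the trained network itself.

## Spectral baseline

Welch PSDs use 10-s Hann segments with half overlap on the raw-rate
signal of the kept channels, cropped to 0.5–35 Hz. Band powers are
rectangle-rule integrals over [low, high) so a band partition sums
exactly; beta is fixed at 12–25 Hz for internal consistency with the
figure convention (the discussion's cited 13–25 Hz variant is not
used). Group maps are standardized mean differences (female − male) of
log₁₀ band power per channel and band. The baseline classifier is an
unpenalized logistic regression on the 24 per-channel log beta powers,
always fit on the training split and scored on the held-out split —
fitting on all subjects, as the original phrasing permits, would leak.
Topographic rendering interpolates channel values over the unit disc
(Clough–Tocher, nearest-neighbour fill outside the hull) and reproduces
electrode values exactly.

## Desk-scale profile

The full original training recipe (1000 subjects × 40 epochs × up to 150
runs ≈ 86,000 optimizer updates on a million-parameter network) is far
beyond a single-CPU test run, so the package defines one scaled profile
used by the end-to-end tests and the pipeline defaults: 160 subjects
(120 train / 40 test), `filter_scale` 0.25 (66,627 parameters), a run
budget of 5–8 passes over the 4,800 training epochs (≈ 350–550
updates), 60 activation-maximization steps, one seeded repetition per
condition, and 100,000 null simulations. These sizes are the package's
choice of what one CPU can train while the whole suite stays
responsive; the pipeline accepts larger values throughout. Cohort
generation streams one subject at a time (a 2-min 26-channel recording
is ~12 MB; cohorts are never held in memory as raw signal). The
pipeline's `run_experiment` caches a completed report by config hash
and reuses it on identical re-runs.

## Known limitations

- **Desk-scale significance is out of reach by design arithmetic.** At
  40 test subjects the p < 10⁻⁵ chance threshold sits at ~80–85%
  (`simulate_null_threshold` computes it) — a bar higher than the
  accuracy the full-scale analysis reported on its real 308-subject
  cohort, where the same p-value corresponded to 63%. A quarter-width
  network given a few hundred optimizer updates (against the ~86,000 of
  the full recipe) cannot reach that bar, so the end-to-end
  significance test fails at this scale and is retained as an honest
  record, with its measured accuracy printed in the failure message.
  The planted effect itself is strongly detectable at desk scale: the
  logistic band-power baseline beats its own calibrated threshold in
  the test suite, and the dream analyses of the same trained network
  recover the planted band and channel subset.
- The EDF writer emits 1-s records and therefore requires integer
  sampling rates and whole-second recordings (trailing samples are
  dropped).
- Best-effort determinism: results are reproducible on one platform /
  BLAS build, not bit-identical across platforms.
- The montage's 2-D electrode positions are schematic (for rendering
  only), not digitized coordinates.
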