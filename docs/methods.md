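# Methods

This note documents the models, algorithms and numerical choices behind
`emgsleeve`, in the spirit of a package methods appendix: what is being
simulated, how each stage of the decoding chain works, which parameters
matter, and what the synthetic benchmarks do and do not demonstrate.

## The decoding problem

A high-density surface-EMG sleeve records bipolar muscle activity across
the forearm at 3,000 Hz from 59 (small), 70 (medium) or 75 (large)
channels while a wearer follows on-screen movement cues; an 18-sensor
data glove simultaneously tracks hand kinematics at 90 Hz, from which 23
named joint angles are computed.  Two recording paradigms are modelled:
*sequential* blocks (10 repetitions of a single movement, rest
interleaved between every attempt) and *mixed* blocks (3-6 distinct
movements, 5 repetitions each, shuffled so the wearer cannot anticipate
the next cue).  Cue and rest durations are uniform on 2-3 s.  The
decoding tasks are (i) per-100 ms-bin gesture classification including
rest, and (ii) continuous regression of the joint-angle vector.

## Synthetic data generator

Real sleeve recordings are not publicly downloadable, so the package is
driven by a generator that reproduces the statistical structure the
pipeline relies on, channel by channel:

    x_c(t) = n_c(t) + A * a_g(c) * e_g(t) * w_c(t) + line60(t)

* `n_c` — baseline noise, unit-RMS white noise band-limited to
  20-400 Hz (order-8 Butterworth shaping, which keeps out-of-band
  carrier power below 5% of in-band power);
* `a_g` — the gesture's spatial activation map: 1-3 Gaussian blobs on
  the flattened electrode grid, peak-normalized, with pairwise map
  correlations kept below 0.9 so gestures are separable but confusable;
* `e_g` — a trapezoidal effort envelope whose rise begins one *reaction
  delay* after cue onset and whose fall begins a second delay after cue
  offset; delays are truncated-normal (≥ 0) draws with defaults
  mean 500 ms (onset), 330 ms (offset), SD 100 ms, bracketing typical
  visually cued reaction times; rise/fall times default to 150/200 ms;
* `A` — the plateau amplitude; `snr` is defined as the plateau
  carrier-to-baseline RMS ratio on a fully active channel, and the
  plateau is jittered ±20% per trial to emulate submaximal effort
  variability;
* `w_c` — a per-channel unit-RMS band-limited carrier;
* `line60` — common-mode 60 Hz interference, default amplitude 10% of
  the active carrier RMS.

Glove sensors follow raised-cosine transitions between a neutral rest
pose and each gesture's 23-joint target pose, time-locked to the same
reaction delays, plus Gaussian sensor noise (SD 0.5°).  The injected
per-trial delays are returned as ground truth so alignment algorithms
can be validated against them.

What the generator does **not** model: motor-unit physiology and volume
conduction, electrode-skin impedance drift, fatigue, co-contraction,
inter-movement kinematic coupling, or label noise in the cue schedule.
Passing the synthetic benchmarks therefore demonstrates that the
pipeline's machinery is correct and well-calibrated, not that the same
accuracy numbers would be obtained on real recordings.

## Signal processing

Raw EMG is notch-filtered at 60 Hz (IIR notch, Q = 30) and band-passed
20-400 Hz with a 10th-order Butterworth filter realized as second-order
sections.  Filtering is **causal** (forward-only, no `filtfilt`): the
same filters run with persisted state in the streaming loop, and the
offline and streaming paths are required to agree exactly.  RMS features
are taken over non-overlapping 100 ms bins (300 samples at 3,000 Hz);
each bin is concatenated with its 4 predecessors (oldest first), so a
75-channel sleeve yields 375 features per bin.  Missing history at the
start is padded by replicating the earliest bin, which preserves
row/label alignment and matches streaming warm-up.  Features are
z-scored per flattened column with statistics from the training split
only (ε = 1e-8 guards zero-variance columns); when pretraining, the
scaler is fit on the pooled pretraining rows and re-fit on in-session
rows before fine-tuning.

## Joint angles

The 18 directly measured joints map one-to-one to glove sensors; the
four finger DIJs and the thumb IJ are derived from the same digit's MPJ
as 30% of the squared angle.  The square is evaluated in radians
(`DIJ = deg(0.3 * rad(MPJ)^2)`): evaluating it in degrees would give
absurd magnitudes (0.3 * 90² = 2430°), and the radian reading gives
anatomically plausible distal flexion (90° MPJ → 42.4° DIJ).  Tracks are
resampled to the 10 Hz bin clock by per-bin windowed means (robust to
sample jitter) and smoothed with a causal 5-bin trailing average.
Group analyses drop exactly {index MPJ, index DIJ} — the damaged-sensor
convention — leaving 21 regression targets.

## Cue alignment

Labels rasterized straight from the cue schedule lead the muscle
activity by the wearer's reaction time.  Three remedies:

* **Mid-window**: keep only the central 1 s (10 bins) of every cue,
  excluding transitions from both training and evaluation.
* **Static shift**: delay every cue boundary by a fixed amount (400 or
  600 ms in the comparisons).
* **Dynamic shift**: relocate each movement-cue edge to the steepest
  slope of aggregate RMS (mean over channels of per-channel z-scored
  RMS, robust to channel gain).  Within a ±1 s window around the edge —
  truncated at the midpoints of neighboring events so windows never
  cross into an adjacent cue — every candidate breakpoint of a
  two-segment piecewise-linear least-squares fit is evaluated
  exhaustively and the minimum-residual candidate is chosen (ties →
  earliest).  Because the wide window also contains the flat effort
  plateau, the raw two-segment breakpoint is biased toward the window
  center; a second, identical sweep restricted to ±400 ms around the
  coarse breakpoint (transition duration plus margin) removes this bias.
  On noiseless piecewise-linear input the procedure recovers bends on
  the bin grid exactly.  The signed edge displacement is the extracted
  reaction time, floored at −200 ms (anticipation allowance); windows
  with no slope fall back to a static 400 ms shift and are logged.

On the standard synthetic session (SNR 10, delays N(500, 100) ms) the
extracted onset delays track the injected ones with Spearman ρ ≈ 0.8-0.9
and a median absolute error below one bin.

## Decoders

Classifiers: extra-trees and logistic regression (scikit-learn, with a
frozen hyperparameter snapshot in `models.SKLEARN_DEFAULTS`; logistic
`max_iter` is raised to 1000 because the stock 100 does not converge on
lagged-RMS features), and a fully connected network with hidden layers
1000/500, batch norm + ReLU between layers, 20% dropout per layer, a
softmax head over movements + rest, and label-smoothing cross-entropy
with target confidence 0.9 (smoothing mass 0.1 spread uniformly).

Regressors: ridge and Laplacian kernel ridge (library defaults; kernel
bandwidth = inverse feature count), and a network with an extra
4000-unit first hidden layer (4000/1000/500), 40% dropout, MSE loss, and
per-joint output truncation to the training min/max.

Both networks train with Adam under a cosine one-cycle schedule (peak
learning rate 1e-3, warm-up fraction 0.3, start/final divisors 25/1e4);
the learning-rate trace is recorded and asserted to rise then fall.
Default schedules are 200 epochs (fresh) and 50 (fine-tune); the test
profile scales these to 20/5, and 10 epochs for the regression network,
which converges faster per epoch at the bench scale used here.  The
classifier batches 64 rows; the regression network batches 128, because
with a 4000-unit layer the per-step optimizer overhead at batch 64
dominates single-core wall time.  The implementation is plain numpy
(float32 training, float64 layer-by-layer inference so batched and
row-by-row prediction agree to machine precision), seeded through a
single generator per run: training is bit-reproducible given (data,
seed).  All reported metrics are means over 5 random seeds (3 for the
auxiliary comparisons).

Cross-sleeve transfer maps any layout onto the 70-channel medium sleeve
by nearest-neighbor assignment on normalized grid coordinates (ties →
lower source index; mapping a smaller sleeve necessarily duplicates
sources).  Pretraining pools mid-window data from other synthetic
wearers, then fine-tunes all layers in session; if the class sets
differ, the output head is reinitialized.

## Evaluation

* **Bin-wise accuracy** — % of 100 ms bins matching ground truth.  With
  matched-duration rest interleaved between movements, an always-rest
  decoder scores ≈ 50%, which is the task's chance level.
* **Success rate** — per-cue binary score; a cue succeeds iff the cued
  class is predicted for ≥ 5 consecutive bins (0.5 s) *and* ≥ 50% of the
  cue's bins (inclusive at the boundary; the rule is verified against
  exhaustive enumeration for all outcomes up to 12 bins).  Rest cues are
  scored in the full variant; the movements-only variant drops them
  (uniform chance 1/n movements, 2.7% at 37).
* **Decoder latency** — time from a per-event reference (measured EMG
  onset, or shifted cue onset) to the first correct prediction inside
  [onset − 500 ms, offset]; anticipatory correctness counts negative;
  events never predicted correctly are excluded from the distribution
  and counted separately.
* **Regression** — R² (uniform average over joints, pooled value also
  reported) and MAE, the per-joint median absolute error in degrees,
  with the grand MAE the mean of per-joint medians.

## Benchmark scales and reproducibility

The standard synthetic session used by the test suite is 12 movements ×
10 attempts on a 20-channel mini-sleeve at SNR 10 (~10 minutes of
signal); the pretraining benchmark uses 8 movements × 10 attempts on 12
channels at SNR 2.5 across a 4-session cohort with per-wearer activation
jitter — the moderate SNR is what makes single-attempt calibration
genuinely insufficient, so the pretraining comparison is informative.
Attempt splits follow the recording protocol: per movement, attempts 1-4
train, 5-7 validate (merged into training once hyperparameters are
frozen), 8-10 test; reduced-calibration sweeps keep the first k attempts.
Full-scale runs (37 movements, 75 channels, 200 epochs) use the same code
paths via `ExperimentConfig`.

Every stochastic stage funnels through explicit integer seeds; a config
plus its seeds reproduces a run at the metric level, and the experiment
manifest records the config hash and seed list.

## Known limitations

* The synthetic activation model is stationary within a session; it
  cannot probe electrode-shift robustness or fatigue adaptation.
* The two-segment sweep assumes one dominant transition per search
  window; severely anticipatory or double-peaked efforts would need the
  three-segment extension.
* The mixed-paradigm chance level for movements-only success is computed
  as the uniform 1/n rule; schedule-weighted variants are not
  implemented.
* Kernel ridge is dense and O(n²) in training rows; it is practical only
  at mid-window scale.
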