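# emgsleeve

A tested, fully synthetic pipeline for decoding hand gestures and
continuous joint angles from high-density forearm surface EMG.

Wearable EMG sleeves with 59-75 bipolar channels can classify dozens of
hand movements and regress the full 23-joint hand pose, but the raw
recordings behind such systems are rarely shareable.  `emgsleeve`
implements the complete decoding chain — and a statistically faithful
simulator of the recordings — so every stage can be developed, tested and
benchmarked end to end on one workstation.  It is aimed at researchers
prototyping myoelectric decoders, and at anyone who needs a reproducible
testbed for cue-alignment and decoder-latency questions.

## What it implements

* **`simdata`** — synthetic sessions: sequential blocks (10 repetitions
  per movement, rest interleaved) and mixed blocks (3-6 movements × 5
  shuffled repetitions); per-gesture spatial activation maps on the
  electrode grid; 20-400 Hz band-limited carriers with trapezoidal effort
  envelopes, 60 Hz line interference, per-trial reaction delays
  (truncated-normal, ~500/330 ms onset/offset), and glove kinematics
  locked to the same delays, with the injected delays kept as ground
  truth.
* **`sigproc`** — causal 60 Hz notch + 10th-order Butterworth bandpass
  (20-400 Hz), RMS over non-overlapping 100 ms bins, lag stacking
  (current + 4 preceding bins → `channels × 5` features), and
  leakage-free train-split standardization.
* **`kinematics`** — 18 glove sensors → 23 named joint angles; distal
  joints from `DIJ = deg(0.3·rad(MPJ)²)`; resampling to the 10 Hz bin
  clock; causal 5-bin smoothing; the 21-target group-analysis exclusion.
* **`cue_align`** — per-bin labels via mid-window extraction, static cue
  shifts, or the dynamic minimum-residuals sweep: each cue edge moves to
  the steepest RMS slope found by exhaustive two-segment least-squares
  changepoint search, yielding per-trial reaction-time estimates.
* **`models`** — extra-trees, logistic regression, ridge and Laplacian
  kernel ridge baselines; fully connected networks (1000/500 hidden for
  classification, 4000/1000/500 for regression) with batch norm, dropout,
  label-smoothing cross-entropy, Adam and a one-cycle schedule; medium-
  sleeve channel mapping and pretraining/fine-tuning across sessions.
* **`evalmetrics`** — bin-wise accuracy, the two-criteria per-cue success
  rate (≥5 consecutive correct bins and ≥50% of the cue), movements-only
  success, chance levels, decoder latency, R², per-joint median absolute
  error, confusion matrices.
* **`orchestrate`** — attempt-level train/validation/test splits
  (4/3/3, validation merged after freezing), seed-averaged experiment
  runs, pretraining sweeps, and a causal streaming loop that matches the
  offline pipeline exactly.

## Worked example

```python
from emgsleeve import orchestrate

cfg = orchestrate.ExperimentConfig(
    n_movements=6, reps=10, n_channels=12,
    epochs=10, seeds=3, analyses=("mid_window", "continuous"), sim_seed=3,
)
report = orchestrate.run_experiment(cfg)
c = report["continuous"]
print("mid-window accuracy %", round(report["mid_window"]["binwise_accuracy_pct"], 1))
print("continuous accuracy %", round(c["binwise_accuracy_pct"], 1))
print("success rate %", round(c["success_rate_pct"], 1),
      "| movements-only %", round(c["movements_only_success_rate_pct"], 1))
print("chance binwise %", round(c["chance_binwise_pct"], 1),
      "| chance movements-only %", round(c["chance_movements_only_pct"], 1))
print("mean onset latency ms", round(c["latency_summary"]["mean_ms"], 0))
```

prints

```
mid-window accuracy % 99.4
continuous accuracy % 95.7
success rate % 100.0 | movements-only % 100.0
chance binwise % 51.0 | chance movements-only % 16.7
mean onset latency ms 140.0
```

The simulator builds a 6-movement sequential session on a 12-channel
mini-sleeve; the network is trained on attempts 1-7 of each movement
(three seeds) and scored on attempts 8-10.  Mid-window accuracy ignores
movement transitions; the continuous numbers include them, using
dynamically shifted labels, which is why the mean onset latency — time
from measured muscle-activity onset to the first correct prediction —
stays near one bin.  Chance bin-wise accuracy is ~50% because rest of
matched duration is interleaved between movement cues.

A command-line wrapper covers the common entry points:

```bash
emgsleeve generate --paradigm sequential --movements 12 --seed 1 --out session.h5
emgsleeve run --seed 1 --out report.json
emgsleeve cues --paradigm mixed --movements 19 --seed 1 --out cues.csv
```

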