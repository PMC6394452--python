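# eegdecode

Sliding-window multivariate pattern analysis (MVPA) for epoched EEG data.

Conventional event-related potential (ERP) analyses average single
electrodes or electrode groups and can miss information that is only
present in the *pattern* of amplitudes across channels. `eegdecode` trains
linear support vector machines on such patterns inside a short analysis
time window, slides the window through the epoch, and reports a decoding
time course: at which latencies the EEG carries information about the
experimental conditions (or, via support vector regression, about a
continuous trial variable such as response time). It is written for
cognitive neuroscientists who already have preprocessed, epoched,
condition-sorted EEG and want classification-based analyses with honest
statistics.

## What it computes

For each analysis window and each subject, exemplars (single trials or
block averages) of each condition are balanced to equal counts, randomly
split into *k* cross-validation sets (left-over trials are excluded for
that cycle), and a linear soft-margin SVM (C = 1; SVR with C = 0.1 for
regression) is trained on k−1 sets and tested on the held-out set. The
whole cycle is repeated *m* times with fresh set draws; the reported
window accuracy is the mean over all m·k analyses (defaults k = m = 10,
i.e. 100 analyses per window). Feature vectors are built spatially
(window-averaged amplitude per channel), temporally (all samples of one
channel) or spatiotemporally (all samples of all channels).

Running the identical procedure with condition labels re-shuffled per
repetition yields an **empirical chance distribution** that inherits any
biases of the real data. Linear-model weights are transformed into
interpretable activation patterns via a = Σₓ·w / Var(wᵀx) (the
forward-model correction), reduced to one absolute, z-standardised value
per channel per window.

At the group level, window-wise accuracies are tested against theoretical
or empirical chance with paired Student or Yuen (20 % trimmed) t-tests,
corrected for multiple comparisons by Holm–Bonferroni, maximum-statistic
or cluster-mass sign-flip permutation tests, generalised FWER control
(u = 1), or FDR (Benjamini–Hochberg and its two-stage adaptive variant).
A minimum-statistic permutation test additionally gives a lower bound on
the prevalence of decodable information in the population.

## Worked example

Simulate a small group study — 64 channels, 100 timepoints at 1000 Hz,
200 epochs per condition, pure Gaussian noise in condition 1 and the same
noise plus a constant 0.3 on channels 1–10 during timepoints 51–100 in
condition 2 — and decode it:

```python
from eegdecode import (SyntheticSpec, DecodingConfig, SubjectDecoder,
                       GroupAnalysis, generate_group_study)

spec = SyntheticSpec(n_timepoints=100, n_channels=64, n_epochs=200,
                     signal_value=0.3, signal_channels=tuple(range(1, 11)),
                     signal_timepoints=(51, 100), rng_seed=1)
datasets = generate_group_study(spec, n_subjects=5)
config = DecodingConfig(mode="spatial", window_width_ms=10, step_ms=10,
                        k_folds=10, m_repetitions=10, permute_labels=True,
                        rng_seed=7)
results = [SubjectDecoder(ds, config).fit() for ds in datasets]
print(results[0].summary().round(2).to_string(index=False))

group = GroupAnalysis(results).fit(test="student_paired", correction="holm",
                                   chance="empirical")
print(group.summary().round(3).to_string(index=False))
```

The first table is one subject's decoding time course (accuracy in %,
permuted-label accuracy alongside):

```
 window_start_ms  window_end_ms  accuracy  permuted_accuracy
             0.0           10.0     50.80              49.35
            10.0           20.0     50.58              50.55
            20.0           30.0     45.02              49.80
            30.0           40.0     52.20              47.50
            40.0           50.0     46.15              49.65
            50.0           60.0     90.50              50.20
            60.0           70.0     91.05              50.88
            70.0           80.0     89.88              51.08
            80.0           90.0     88.40              48.62
            90.0          100.0     90.72              48.75
```

Windows covering the signal-free first half hover at the 50 % chance
level; windows covering the signal half decode at ~90 %. The group table
then shows which windows survive Holm correction when each subject is
compared against their own permuted-label chance estimate:

```
 window_start_ms  window_end_ms  mean_accuracy    se      t     p  significant  mean_permuted
             0.0           10.0         50.525 1.383  0.854 0.221        False         49.290
            ...
            40.0           50.0         48.905 1.082 -0.476 0.670        False         49.445
            50.0           60.0         88.960 0.660 73.341 0.000         True         49.445
            ...
            90.0          100.0         90.185 0.866 48.285 0.000         True         49.800
```

`results[0].feature_weights.per_channel` holds the corrected, absolute,
z-standardised per-channel weights; in this simulation the ten
signal-bearing channels dominate every signal window.

## Command line

A thin CLI wraps the same library:

```bash
eegdecode simulate --out data --subjects 8 --signal 0.3 --seed 1
eegdecode decode study.yaml     # per-subject result files + run manifest
eegdecode group study.yaml      # group statistics, CSV summary, figures
eegdecode plot results/subject01_group1.npz --out fig.pdf
```

`study.yaml` lists the subject files (native directories or MAT files in
the `eeg_sorted_cond{run, cond}` cell-array layout, v7 or v7.3), the
decoding parameters and the group-statistics options; see
`tests/test_cli.py` for a complete example.

## Acceptance script

`scripts/acceptance.py` regenerates the chance-level calibration analyses
from scratch: balanced two-class decoding of signal-free Gaussian noise
(accuracy averaged over the windows covering the first half of the epoch)
and balanced three-class decoding of signal-free noise (averaged over all
windows), both with 10-sample spatial windows, k = m = 10. It writes the
recomputed values to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
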