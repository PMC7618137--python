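# retrocue

Analysis toolkit for **retro-cue visual working memory EEG experiments** —
for cognitive neuroscientists studying how retrospective attention
reshapes memory representations, and for methodologists who want the full
analysis chain of such a study as tested, reusable Python.

In the task this package models, two colored oriented bars are encoded;
during retention a retro-cue (valid: points at the to-be-probed "target"
bar; neutral: uninformative) appears, and the participant reproduces the
target orientation on a continuous dial. The package implements every
analysis stage such a study needs, end to end, with a synthetic generator
that produces EEG + behavior with *known ground truth* so each stage can be
validated by parameter recovery rather than by eye.

## What it computes

**Behavior — mixture decomposition of recall errors.** The signed error on
the 180°-periodic orientation circle is modeled as a three-component
mixture: with probability *pT* a von Mises (concentration κ) around the
target, with *pNT* around the non-target (swap errors), with *pU* uniform
guessing. On doubled angles the log likelihood is

```
L = Σᵢ log[ pT·VM(2εᵢ; 0, κ) + pNT·VM(2(εᵢ−δᵢ); 0, κ) + pU/2π ]
```

maximized by EM with random restarts; SD is reported in orientation
degrees via the circular-SD transform of κ.

**Decoding — time-resolved MVPA, temporal generalization, spread time.**
Epochs are downsampled to 50 Hz by block averaging; same-label trials are
averaged into three pseudo-trial bins; a linear SVM on all 60 channels is
cross-validated (stratified 3-fold × 10 iterations) at every time point.
Chance is exactly 1/n_labels (12.5% for 8 orientations, 25% for 4 colors,
50% for 2 sides). Training at t₁ and testing at t₂ yields the
generalization map ACC(t₁, t₂), summarized by

```
Spd(t₁,t₂) = 1 if ACC(t₁,t₂) > chance else 0
Spreadtime(t₁) = Σ_{t₂} Spd(t₁,t₂)
```

**Evoked — frontal N2 (320–360 ms) and N600 (600–1300 ms)** mean
amplitudes over nine fronto-central sites, plus RT-tertile binning.

**Spectral — ERD, ITPC, PAC.** Hanning-tapered STFT (2–30 Hz in 0.5 Hz
steps) on ERP-subtracted epochs; event-related desynchronization as
log₁₀ power minus a −1800…−1400 ms log-baseline; inter-trial phase
coherence `ITPC = |⟨c/|c|⟩_trials|` (theta 3–7 Hz at Fz, 100–700 ms); and
theta-phase/alpha-amplitude coupling via the entropy-based modulation
index `MI = (log N − H)/log N` over 18 phase bins in the 0–1500 ms
retention window.

**Statistics — cluster-based permutation tests** (pointwise t, summed-t
cluster mass, max-statistic sign-flip null, `p = (1+#{null≥obs})/(1+n)`),
Benjamini–Hochberg FDR, and the usual paired t / Pearson r / 2×2 RM-ANOVA
plumbing.

**Pipeline** — `run_pipeline(RunConfig)` chains everything over any number
of "virtual subjects" (independent generator seeds), writes per-stage
artifacts, a group significance table, a markdown report, and a SHA-256
manifest; identical config + seed reproduce byte-identical artifacts.

## Worked example

`examples/02_behavior_mixture.py` simulates 560 trials per condition and
fits the mixture:

```
condition  n_trials  mean_abs_error_deg  mean_rt_ms  p_target  p_nontarget  p_uniform  sd_deg
    valid       560              14.814     946.049     0.883        0.050      0.067  13.806
  neutral       560              21.424    1272.047     0.797        0.083      0.120  18.883

generating parameters: {'valid': (0.88, 0.04, 0.08, 14.0), 'neutral': (0.78, 0.07, 0.15, 19.0)}
```

The fit recovers the generating parameters to within a few hundredths
(probabilities) and ~1° (SD): the valid retro-cue raises the probability
of reporting the target and sharpens precision — the behavioral retro-cue
benefit. `examples/03_decoding_timecourse.py` then decodes the cued
orientation from the EEG patterns:

```
chance level: 0.125
mean accuracy in the 500-1500 ms code window: 0.192
mean accuracy before the cue: 0.122
peak accuracy 0.347 at 628 ms
```

Accuracy sits at chance before the cue and rises above it only while the
injected orientation code is active. The other examples cover
preprocessing, temporal generalization + spread time, ERP components,
ERD/ITPC/PAC, cluster statistics, and the full multi-subject pipeline.

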