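# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## The synthetic experiment

The generator (`retrocue.synth`) emulates a retrospective-cue continuous
report working memory study: per trial, two bars with distinct orientations
(from the 8-value set ±11.25°, ±33.75°, ±56.25°, ±78.75°) and distinct
colors (of 4) appear left and right of fixation; a retro-cue presented
during retention is valid (indicates the later-probed target) on half the
trials and neutral on the rest. Epochs are time-locked to cue onset,
−2000…2400 ms at 1000 Hz over a 60-channel 10–20 montage plus an HEOG
channel; defaults use 560 trials per condition, matching the per-condition
scale of a 20-block × 56-trial session.

Injected structure, each with an independent knob:

- **Background noise**: per-channel Gaussian 1/f^β noise (β = 1 by
  default, RMS 10 µV), generated by spectral shaping, with optional random
  spatial mixing. Chosen because it matches broadband EEG spectra without
  modeling physiology.
- **Feature codes**: each label of each feature (target orientation,
  non-target orientation, target color, target side) maps to a fixed
  random unit-norm channel vector, scaled by `pattern_snr × noise_sd` and
  added only inside that feature's time window (orientation 500–1500 ms,
  color/space 100–1500 ms by default). This yields linear decodability
  with tunable difficulty; `pattern_snr = 0` removes the code entirely.
  Default SNRs (orientation 1.0, color/space 0.8, non-target 0.0) give
  clearly above-chance but non-saturated decoding at the default trial
  counts; the zero non-target SNR mirrors the empirical finding this kind
  of study probes (no decodable non-target enhancement).
- **Evoked response**: a fronto-central, phase-locked waveform (N2-like
  Gaussian bump at 340 ms, sustained 600–1300 ms plateau, and a theta
  burst that drives frontal theta ITPC), amplitude −4 µV scaled per
  condition (valid 1.0, neutral 0.6) and optionally per trial by the RT
  latent (`evoked_rt_slope`), with Gaussian onset jitter
  (`evoked_jitter_sd`, 0 ⇒ perfectly phase-locked).
- **Alpha ERD and theta–alpha coupling**: parieto-occipital 10 Hz alpha
  (8 µV pre-cue) whose amplitude drops by `alpha_erd_depth` (valid 0.5,
  neutral 0.3) after the cue, and is modulated during retention by the Fz
  theta phase as `1 + pac_depth·cos(θ)` (valid 0.4, neutral 0.2) — the
  standard synthetic-coupling construction, monotone in depth by design.
- **Behavior**: reports drawn from the three-component mixture with
  condition-specific (pT, pNT, pU, SD) — defaults valid (0.88, 0.04, 0.08,
  14°) vs neutral (0.78, 0.07, 0.15, 19°), a mid-sized retro-cue benefit —
  and shifted-log-normal RTs (valid faster), sharing a latent with the
  evoked gain so N2–RT coupling can be switched on.

All randomness derives from one seed; identical configs are bit-identical.
`null_config()` zeroes every effect (including the condition RT
difference) for calibration runs.

**What the generator does not emulate**: volume conduction from realistic
sources, eye movements and muscle artifacts (rejection is exercised with
injected square pulses), non-stationary noise, learning or fatigue across
blocks, and any coupling between the EEG patterns and the behavioral
report beyond the shared condition labels. Passing tests therefore show
that the *analysis* recovers what was injected under realistic noise — not
that real data would show these effects.

## Behavior: mixture model

Orientations are 180°-periodic, so all circular computation doubles the
angles onto the full circle; SD is reported back in orientation degrees
(sd = ½·√(−2 ln(I₁(κ)/I₀(κ))) in degrees). The likelihood has a target von
Mises at 0, a non-target von Mises at each trial's doubled offset (one
non-target per trial; κ shared between the two, the toolbox convention),
and a uniform component. Fitting is EM: analytic M-step for the mixing
weights, κ via Newton-refined inversion of A₁(κ) = I₁/I₀ on the
responsibility-weighted mean cosine, 10 random restarts (Dirichlet
weights, log-uniform κ), tolerance 1e−9 on the log likelihood, 500
iterations; `converged=False` when unmet. κ is bounded to [1, 200]: below
κ ≈ 1 (orientation SD ≈ 38°, far broader than any plausible report
precision) a von Mises is practically indistinguishable from uniform on
the doubled circle, and the flat ridge lets EM trade guessing mass for
near-flat von Mises mass; the bound keeps the weights identifiable.
Degenerate all-identical data cap κ at the upper bound with a warning.
Fits require ≥ 50 trials by default.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (0.1–40 Hz default) applied
forward–backward per epoch with maximal odd-reflection padding — the
0.1 Hz edge's transient is long relative to a 4.4 s epoch, so the
library default padding is insufficient. Baseline correction subtracts
the −200…0 ms mean per trial and channel (idempotent). Artifact screening
flags (never edits) trials whose EEG strictly exceeds ±80 µV or whose
HEOG strictly exceeds ±50 µV ("exceeding" read as strict); participants
are excluded above 40% flagged trials or ±3.2 µV mean HEOG. Ocular ICA is
out of scope: the pipeline accepts externally cleaned data. The working
epoch is standardized to −2000…2400 ms.

## Decoding

50 Hz downsampling is the mean of non-overlapping 20-sample blocks
(timestamps at block centers; trailing partial blocks dropped). Per
iteration, each label's trials are randomly split into 3 near-equal bins
and bin-averaged into pseudo-trials; bins map round-robin onto folds, so
folds are label-stratified and train/test pseudo-trials are disjoint by
construction (asserted). Binning is fixed per iteration (not re-drawn per
time point) — re-randomizing per time point would only decorrelate
adjacent time points at considerable cost. Features are z-scored per time
point using training-fold statistics. The classifier is scikit-learn's
one-vs-one linear SVM (C = 1); vote ties resolve by aggregated decision
values, deterministic given the data. If training features at a time
point are all-constant the fold predicts chance with a warning. Temporal
generalization shares the fold structure, so the map's diagonal equals
the time-course exactly. The spread-time threshold is strict
(ACC = chance counts 0). Accuracy curves/maps average 3 folds × 10
iterations (defaults; reduced in examples and tests for speed).

## Spectral measures

STFT: 500 ms Hanning window, 20 ms step, zero-padded to a 0.5 Hz grid
(chosen to resolve 2 Hz at the requested spacing); only fully supported
window positions are computed. Power is one-sided PSD averaged over
trials; per-trial complex coefficients are retained on request for ITPC.
Phase-locked activity is removed beforehand by subtracting the condition
ERP where non-phase-locked power is wanted. ERD is log₁₀ power minus the
−1800…−1400 ms baseline mean of log₁₀ power (per channel × frequency);
zero cells are floored at machine epsilon with a warning. ITPC is the
modulus of the across-trial mean of unit-normalized coefficients;
zero-amplitude cells carry no phase and are excluded with a count.

PAC uses zero-phase Kaiser-window FIR band-passes (2 Hz transition),
Hilbert phase at Fz (theta 3–7 Hz) and Hilbert amplitude at the
parieto-occipital sites, samples pooled across trials within 0–1500 ms
(pooling matches reporting a single index per condition), 18 phase bins
of 20°, and the entropy-based modulation index. Two deliberate choices:

- The window must span ≥ 6 cycles of the phase band's **center**
  frequency (1200 ms at 5 Hz), which the 1500 ms retention window
  satisfies; anchoring the rule at the band's low edge would reject the
  package's own default window.
- The amplitude **extraction** band is widened around its center to a
  half-width of at least the phase-center frequency + 1 Hz (8–12 Hz →
  4–16 Hz) by default. Amplitude modulated at the phase frequency lives
  in sidebands at carrier ± phase frequency; a narrow 8–12 Hz filter
  provably erases theta-paced modulation of a 10 Hz carrier before it can
  be measured. This is the standard validity requirement for
  phase-amplitude coupling with nested bands (amplitude bandwidth at
  least twice the phase frequency); disable with `widen_amp_band=False`
  to reproduce a strict-band estimate. Phase-shuffled surrogates
  (circular shifts of the pooled phase stream) provide a null for MI.

## Statistics

Cluster tests: pointwise (paired) t, cluster-forming threshold at
two-sided pointwise p < 0.05 (configurable), clusters are contiguous
same-sign supra-threshold runs scored by summed t, and the null is the
maximum absolute cluster mass over random sign flips of unit-level effect
curves (10,000 permutations by default; the sign-flip t is computed
vectorized from per-unit sums of squares). p = (1 + #{null ≥ observed}) /
(1 + n_perm), never zero. Units are subjects — or independent generator
seeds in synthetic group analyses. Degenerate zero-variance inputs return
no clusters with a warning. FDR is Benjamini–Hochberg (via statsmodels,
with a brute-force oracle in the tests). The paired t with x ≡ y returns
t = 0, d = 0, p = 1 by convention (no effect), rather than failing on
zero variance; zero variance around a non-zero mean still raises.

## Pipeline

`RunConfig` validates every window and electrode reference against the
montage and epoch span before any stage runs, freezes the resolved config
next to the outputs, and derives each stage × subject seed from the
global seed via `SeedSequence((seed, stage_id, subject))`. Stages write
their own artifacts; the group significance table applies FDR across the
scalar battery; the markdown report is rendered purely from
`summary.json` (no recomputation); `manifest.json` holds SHA-256 checksums
of all artifacts (the log excluded). The "virtual subjects" construction
generates independent seeded datasets and compares conditions across them
exactly as across participants.

## Problem sizes in tests and examples

Tests and examples run the identical code paths at reduced scale chosen
for quick iteration: typically 250 Hz sampling, 24–60 trials per
condition, 1–3 decoding iterations, and 100–1000 permutations; the
calibration suite uses 200 replications for the family-wise error check
and 10–20 seeds for recovery and monotonicity checks. Defaults in the
library itself remain at the full study scale (1000 Hz, 560 trials per
condition, 10 iterations, 10,000 permutations).

## Known limitations

- The generator's feature codes are constant spatial vectors within their
  window; dynamic or rotating codes (beyond placing different codes in
  different windows by hand) are not modeled.
- Epoch-wise 0.1 Hz high-passing cannot fully suppress sub-epoch-length
  drifts; continuous-recording filtering is out of scope.
- PAC with nested theta/alpha bands is intrinsically at the edge of
  detectability; the widened extraction band trades band purity for
  validity and admits theta-band energy into the amplitude estimate on
  channels where theta power is substantial.
- The 2×2 repeated-measures ANOVA is a thin convenience (each effect's F
  as a squared paired t); factorial designs beyond 2×2 are not supported.
- Import of recorded EEG formats is limited to the package's own
  container; mapping BrainVision/EDF/EEGLAB files onto an `EpochSet` is
  left to the caller's reader of choice.
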