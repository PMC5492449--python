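# Methods

This note documents the models, conventions and numerical choices behind
`p300speller`, and what the synthetic validation does and does not show
about real data.

## Stimulus schedule and timing

Each spelled symbol triggers `n_repetitions` repetition blocks; within a
block the 12 units (6 rows, 6 columns) flash once in a fresh uniformly
random permutation. This blockwise convention guarantees exactly
`n_repetitions` flashes per unit and prevents immediate repeats of a unit
except across block boundaries, where a target can flash twice in a row;
that "repetition effect" is left as a measurable statistic of the schedule,
not a constraint. Onsets advance by the frame-quantized flash + dark
interval; a 4 s feedback pause separates symbols.

Frame quantization rounds a designed duration to the nearest whole count of
display-refresh frames (minimum one frame). The frame period defaults to
the conventional printed value 16.66 ms for a 60 Hz display rather than
1000/60 = 16.667 ms, so that 4 frames equal 66.64 ms exactly; the
exact-period alternative is one config field away
(`SpellerConfig.refresh_frame_ms`). The fast-mode flicker band is derived
as [1/(exposure + one frame), 1/exposure], rounded to integer Hz — (12, 15)
for the 60/10 ms design.

The session order crosses STIM × COLOR × SPEED within subjects: STIM block
order alternates across two equal subject groups, and the four
SPEED × COLOR combinations follow the rows of a balanced (Williams) 4×4
Latin square, cycled over subjects. Positional balance is exact when the
subject count is a multiple of 4 (it is approximate for other even counts,
which the design accepts).

## Synthetic EEG generator

The generator's purpose is parameter recovery: every quantity the analysis
measures is injected with a known value.

* **Evoked components.** N1 and P300 are Hann (raised-cosine) bumps
  parameterized by amplitude (µV), latency (ms) and width (ms; defaults 80
  and 200). The peak value equals the nominal amplitude exactly, widths
  keep the two components' supports disjoint from each other's measurement
  windows, and the waveform is smooth, so an extremum picker can recover
  the parameters to machine precision in the noiseless limit. Per-channel,
  per-condition N1 amplitudes/latencies and Cz P300 values default to the
  grand-average reference tables for slow timing (training and performance
  phases separately); P300 amplitudes at other electrodes scale the Cz
  value by a fixed centro-parietal topography (Cz 1.0, Pz 0.9, P3/P4 0.8,
  Fz 0.6, PO7/Oz/PO8 0.5). Performance-phase P300 values reuse the training
  table (no separate reference exists). Non-target flashes add 25% of the
  channel's N1 (configurable): non-targets still drive visual cortex, which
  is what makes the fast-mode SSVEP and the oddball contrast non-trivial.
* **COLOR.** No additional generative COLOR effect is injected beyond what
  the reference amplitudes already carry, consistent with a design in which
  color is a label rather than a driver.
* **Noise.** Background EEG is Gaussian white noise band-passed to
  0.5–30 Hz (the acquisition filter) and scaled to 8 µV rms per channel —
  a realistic resting-background figure that makes single-trial ERPs
  invisible and yields mostly-high but not ceiling selection accuracies at
  the reference amplitudes. EOG electrodes carry 2 µV instrumental noise
  plus ocular events: Poisson blinks (0.15 Hz, 120 µV, 250 ms) on the
  vertical derivation and signed saccade-like deflections (0.1 Hz, 30 µV)
  on the horizontal one, mixed into EEG channels with coefficients decaying
  from frontal (0.15 at Fz) to occipital (0.02) sites.
* **SSVEP.** In fast mode a sinusoid at the flash-onset rate
  (1000/83.3 ms ≈ 12.005 Hz) spans each symbol's flashing block,
  phase-locked to the block start, over posterior channels (Oz 1.0,
  PO7/PO8 0.6, Pz 0.3; 1.5 µV).
* **Determinism.** One `numpy` generator seeded from the noise model drives
  everything; identical seeds give bit-identical records.

What the generator does **not** emulate: overlap/refractory ERP distortion
beyond linear superposition, habituation or fatigue, non-stationary or
1/f-structured noise, electrode drift, line-noise residue, or
subject-specific topographies. Passing tests therefore demonstrate the
*analysis code* is correct under the stated statistical structure, not that
the pipeline is robust to everything real EEG does.

## Epoch grid and preprocessing

Epochs span −100..+700 ms. At 256 Hz that is 205 samples (indices 0..204);
sample *i* sits at −100 + i·(1000/256) ms. The flash onset, produced by an
asynchronous display, need not fall on the EEG sample grid: the anchor
sample is the one nearest (onset − 100 ms) and is *labelled* −100 ms, which
is how reported peak latencies land on the −100 ms-anchored grid while true
onsets sit between samples (worst-case timing error: half a sample,
≈1.95 ms).

Ocular artifacts are removed by ordinary least squares: each EEG channel's
projection onto the mean-centered bipolar derivations VEOG (above − below)
and HEOG (left − right) is subtracted, and the fitted propagation
coefficients are reported. A derivation with exactly zero variance carries
no information and is skipped (so all-zero EOG leaves the EEG untouched);
non-constant but collinear derivations raise an error instead of silently
producing an unidentifiable fit. A static regression stands in for the
recursive/adaptive variants used by some acquisition systems; extending to
a recursive estimator would be a localized change.

Down-sampling to 64 Hz keeps every 4th sample from index 0 (the 0.5–30 Hz
band makes aliasing negligible; no interpolation). The 3-sample moving
average is centered with symmetrically shrunken edge windows. The feature
matrix takes the 45 post-stimulus samples (t ≥ 0) at 64 Hz and keeps every
3rd — smooth-then-decimate — giving 15 time samples per electrode and
15×8 = 120 columns; channel ablation removes 15-column blocks. The
decimation stride and post-stimulus window are config parameters.

## Classifier and symbol selection

The discriminant is the two-class shared-covariance Fisher solution
w = S⁻¹(µ₁ − µ₀), with the posterior of the target class the logistic of
w·x − w·(µ₀+µ₁)/2 + log(π₁/π₀). Priors default to the class frequencies
(1/6 vs 5/6 under the row/column design); since symbol selection compares
cumulative sums across units, a common prior shift moves every unit's
weight trajectory by the same monotone transformation of the scores and
cannot change an argmax between units with the same flash count — the
prior choice is therefore documented rather than consequential.

The pooled covariance is Ledoit–Wolf shrunk by default: 900×120 is
workable for the plain inverse, but reduced designs (fewer repetitions,
ablated channels) approach singularity. Shrinkage 0 reproduces classical
LDA and raises a conditioning error when the covariance is numerically
singular (condition number > 1e12).

Selection accumulates raw per-flash posteriors per unit, in flash order
(no per-block normalization); weight series are nondecreasing because
posteriors are non-negative, and this invariant is asserted in tests. Ties
in the final row/column argmax break to the lowest unit index and are
flagged on the result. Training and performance phases are strictly
separated; there is no adaptation during performance.

## ERP measurement

Peaks are measured on the 256 Hz average (classification uses the decimated
branch; the two branches share the same epochs). "Maximal deflection" is
the most extreme sample of the required polarity within the window,
preferring samples that are local extrema relative to their immediate
neighbours on the full waveform; if no interior local extremum of the right
polarity exists, the windowed extremum is returned flagged `boundary`, and
exact ties resolve to the earliest latency and are flagged `tie`. The Cz
window means use half-open [lo, hi) windows so the shared 250 and 300 ms
boundaries are counted once. Grand averages are unweighted means of
per-subject averages; per-subject peak extraction is also available, and
table-style outputs default to peaks of the grand average.

The recovery suite defines SNR at the single-trial level: at "SNR 5" each
trial carries band-limited noise with sd = |amplitude|/5 and the ERP
averages 30 target trials before extraction, mirroring the pipeline. Under
this convention median latency error stays below one sample and amplitude
bias below 5%. Extremum picking on a *single* noisy waveform at sd =
amplitude/5 is measurably biased (≈0.1–0.3 µV toward larger deflections) —
an inherent property of max-picking under noise, which averaging, not the
picker, controls.

## Wavelets and phase locking

The Morlet family uses σ_f = f₀/k, σₜ = 1/(2πσ_f) and normalization
A = (σₜ√π)^(−1/2), k = 7, f₀ = 5..20 Hz in 1 Hz steps. The printed
normalization is typographically ambiguous between (σₜ√π)^(−1/2) and
(σₜπ)^(−1/2); the PLF divides the convolution by its own modulus, so it is
provably invariant to A — a test doubles A and asserts identical output —
and the choice cannot affect any reported value. k < 5 warns (too few
cycles) but builds.

Wavelet support is truncated at ±4σₜ. In the default `strict` edge mode an
output sample is defined only where the full support lies inside the
epoch; no zero-padding means no boundary bias, at the cost that family
members below ≈12 Hz (4σₜ ≥ 405 ms) are entirely undefined on an 800 ms
epoch and appear as missing values in the 16-frequency median vector. The
`pad` mode provides conventional zero-padded output over the full grid for
users who prefer coverage over bias purity. Samples whose convolution
modulus falls below 1e−12 × (trial rms × wavelet ℓ¹ norm) are marked
undefined rather than zero-divided; an all-zero trial is fully undefined.
PLF averages unit-modulus values with pairwise exclusion of undefined
samples, recording the effective trial count per cell. The median collapse
runs over post-stimulus samples by default (`post_only=False` collapses the
whole epoch).

Trial partitions follow the selection outcomes: with *c* of *s* symbols
correct, the target/correct set holds c × (2·n_repetitions) epochs and the
non-target/correct set c × (10·n_repetitions), and the four sets are
disjoint and exhaustive.

## Statistics

For the 2×2 within-subject design every effect has an exact contrast form:
per subject, L_A = (mean over A1 cells) − (mean over A0 cells), similarly
L_B, and L_AB = half the difference of differences; then F = n·L̄²/var(L)
with (1, n−1) degrees of freedom, identical to the classical
within-subjects decomposition. Permutation nulls exchange the four cell
labels independently within each subject — exact under exchangeability of
conditions given the subject — with p = (1 + #{F* ≥ F})/(1 + n_perm), so p
is never below 1/(n_perm+1). The Latin-square period effect is assumed
negligible and no period term is offered. Generalized eta squared uses
SS_effect / (SS_effect + SS_subjects + ΣSS_error), comparable across
designs; it is NaN when the data carry no variance.

The sign test is the exact binomial tail at p = ½ on non-tied differences
(ties dropped and counted). Cliff's delta is the unpaired all-pairs
dominance statistic, whose outputs are integer multiples of 1/(|x||y|) —
with 8 subjects per group, multiples of 1/64. Holm adjustment delegates to
statsmodels' step-down implementation behind the package's own surface and
is cross-checked against a brute-force oracle; the Holm family is always
an explicit argument, never guessed. Friedman, Wilcoxon and Spearman are
thin wrappers over scipy.

## Study orchestration and problem sizes

`run_study` derives every session's seeds from the master seed via SHA-256
of a (subject, session, stage) counter — below 2³¹, and stable across
processes — so any single session can be regenerated in isolation. Reports
are CSV tables plus a JSON manifest (package version, seed, config hash);
identical configs and seeds produce byte-identical outputs.

The test suite runs all stochastic suites at deliberately scaled problem
sizes chosen to keep the full battery under a minute while leaving wide
statistical margins: sessions of 2–5 symbols × 4–15 repetitions, 10–20
seeds per condition ladder, 1,000 replicates for the permutation-ANOVA
calibration, 10,000 symbols for the chance-level check. The amplitude
ladder for the accuracy-monotonicity suite (0, 0.5, 1, 2, 4 × reference
amplitudes at 8 µV noise) spans chance to ceiling with well-separated
intermediate points.

## Known limitations

* The EOG regression is static; slow changes in propagation are not
  tracked.
* Strict wavelet edges leave 5–11 Hz undefined on 800 ms epochs (see
  above); analyses needing those frequencies must either use `pad` mode or
  longer epochs.
* The generator's linear-superposition ERPs understate fast-mode waveform
  distortion (overlap/refractoriness), so fast-mode time-domain morphology
  is not a validation target; only its time–frequency structure is.
* Positional Latin-square balance is exact only for subject counts
  divisible by 4.
* Permutation ANOVA supports the 2×2 within design the study needs, not
  arbitrary factorial layouts.
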