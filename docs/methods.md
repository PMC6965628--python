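# Methods

`netlag` implements an analysis chain for intracranial EEG (iEEG) recorded
during the gradual-onset continuous performance task (GradCPT), centered on
the antagonistic dynamics of three large-scale cortical systems: the
default mode network (DMN), which deactivates during externally oriented
attention, and the dorsal attention (DAN) and salience (SN) networks, which
activate. Because clinical iEEG recordings cannot be redistributed, the
package pairs every analysis stage with a synthetic-data generator that
produces recordings with known ground truth, and validates each stage by
parameter recovery. This note documents the models, the defaults and why
they were chosen, the numerical decisions, and what the synthetic
validation does and does not establish about real data.

## Task model and behavioral scoring

GradCPT presents city and mountain scenes that cross-fade every 800 ms
(linear pixel interpolation, full coherence at the 400 ms midpoint).
Subjects press to cities (90%) and withhold to mountains (10%); mountains
never repeat on consecutive trials, which the generator enforces by
sampling mountain positions uniformly among non-adjacent position sets.

Because stimuli overlap in time, presses are mapped to trials by a window
rule plus an iterative disambiguation. A press whose RT relative to a
trial onset falls in [0.7 × rise, transition + 0.4 × rise] = [280, 960] ms
belongs to that trial. The normal windows of consecutive trials leave a
120 ms deviant gap; presses there are resolved by: (1) assignment to
whichever adjacent trial lacks a response, if exactly one does; (2) if
neither has one, to the closest trial — distance measured to the nearest
edge of each trial's normal window, the only metric under which
"equidistant" deviant presses exist, with ties to the earlier trial — with
mountain trials excluded; (3) when several presses compete for one trial,
the fastest RT wins and losers are re-evaluated. Rules are swept to a
fixed point; leftover presses are dropped but counted, so presses are
conserved. The implementation is verified against an independently coded
brute-force oracle on randomized configurations (10,000 in the acceptance
suite); the oracle defines the reference behavior where the prose rules
are ambiguous (e.g. rule-3 timing).

Run scores: omission rate = unpressed cities / cities; commission rate =
pressed mountains / mountains; d′ = Z(hit) − Z(false alarm) with hit =
correct commission and false alarm = commission error, extreme rates
corrected by 1/(2N). Runs are flagged for inclusion when omission < 15%
and commission < 60%. The behavior generator's defaults (25% lapse
probability per mountain, 3% omission probability, RT ~ N(0.70, 0.15²) s)
place simulated cohorts near the error rates reported for clinical GradCPT
cohorts (~2.9% omissions, ~25% commissions); lapses are independent
Bernoulli events — no autocorrelated attentional-state model is attempted.

## Signal model of the synthetic recordings

Each channel is

    x(t) = background(t) + line(t) + artifacts(t)
         + hfb_base · [1 + evoked(t) + m·slow(t)]₊ · carrier(t)

with `background` 1/f-shaped Gaussian noise (PSD ∝ f^−2 by default;
the generated slope is verified to ±0.2 by spectral fit), `line` a mains
sinusoid (60 Hz default, 50 Hz configurable), `carrier` unit-variance
70–170 Hz noise, `evoked` signed Gaussian bumps (FWHM 400 ms) centered at
the channel's time-to-peak after each mountain onset — positive for
DAN/SN, negative for DMN — and `slow` a unit-variance 0.1–1 Hz process
modulating the HFB envelope multiplicatively (depth 0.4). Channel pairs
given a coupling spec share a slow latent, one copy delayed by the
generative lag and signed/scaled so the slow components correlate at the
target value; a two-latent variant controls zero-lag and lagged coupling
separately for the task-vs-rest construction. Artifacts: bad channels are
scaled to exceed the 5× variance rule by construction, and spike channels
receive biphasic >100 µV jumps at a Poisson rate. Defaults: fs = 1000 Hz
(the clinical recording rate), 20 s stimulus-free lead-in before the task.

Deliberately not modeled: cortical geometry, volume conduction, biophysical
neural-mass dynamics, non-stationary artifacts, and any image-level
structure of the stimuli (categories only). Consequently, passing recovery
tests establishes that the *estimators* are correct and well-calibrated
under the stated signal model — not that the model captures every property
of patient recordings (e.g. shared physiological noise that could bias
coupling estimates is absent). Envelope-level fast paths
(`simulate_epoch_ensemble`, `simulate_envelope_pair`) generate the same
statistical structure directly at the envelope stage for cohort-scale
studies; the raw-signal route is exercised by the deeper single-cohort
tests.

## Preprocessing

Fixed order: crop → notch → channel QC / common-average reference (CAR) →
Morlet decomposition → log-ratio normalization → band averaging →
optional Gaussian smoothing.

* **Notch**: zero-phase 3rd-order Butterworth band-stops at the line
  frequency and two harmonics, ±3 Hz (57–63/117–123/177–183 Hz for 60 Hz
  mains).
* **Channel QC**: excluded from the CAR are channels on a clinical
  pathology list, channels on a manual spectral-outlier list (interactive
  inspection is replaced by this input list; no automatic stand-in runs by
  default), channels with variance >5× or <1/5× the median, and channels
  with more than 3× the median count of >100 µV sample-to-sample jumps.
  The CAR subtracts the mean of retained channels from every channel.
  Note that with very few channels the CAR injects a common component into
  all channels (visible as spurious positive envelope coupling); synthetic
  montages therefore use ≥12 channels where coupling is measured.
* **Morlet decomposition**: 38 log-spaced center frequencies, 1–170 Hz,
  7 cycles at every frequency (the width is configurable; the original
  parameterization is unstated, and all validation is tied to recovery
  properties rather than toolbox-level equality). Convolution uses
  reflection padding; samples within half the widest wavelet support of an
  edge are flagged and excluded from any epoch that touches them.
* **Normalization**: per frequency, each sample of the power-amplitude
  series is rescaled by the log ratio against the whole-run level, which
  removes the 1/f decline before band averaging. Two interpretations of
  "log ratio" are implemented: `ratio` (default), log10(x / time-mean x),
  which makes the time-mean of 10^output exactly 1; and `log_mean`,
  log10 x − mean log10 x, which makes the time-mean of the output exactly
  0. They differ by a per-frequency constant and are indistinguishable for
  every downstream contrast.
* **Bands**: δ 1–3, θ 4–7, α 8–12, β1 13–29, β2 30–39, γ 40–70, HFB
  70–170 Hz; a center frequency belongs to the band whose closed interval
  contains it (grid points in the inter-band gaps belong to none; each
  band's membership is verified non-empty). Envelopes are kept at the raw
  sampling rate.
* **Smoothing**: 50 ms FWHM zero-phase Gaussian for the localization and
  dynamics analyses (DC-preserving kernel).

## Electrode localization

Targets are correct-omission mountains not preceded by a mountain
(commission-error mountains are kept as a separately labeled subset);
baselines are correct-commission cities flanked on both sides by
correct-commission cities, randomly subsampled (seeded) to match the
target count. Epochs run −800..+1600 ms around onset at the envelope rate.

The per-electrode test is a cluster-based permutation test on 0..+1500 ms:
two-sample t per timepoint (Student pooled variance by default, Welch
optional), two-tailed p = 0.05 sample threshold, sign-consistent adjacent
suprathreshold samples grouped into clusters, cluster mass = summed t, and
the maximum |mass| compared against its Monte-Carlo distribution over
random trial relabelings (1000 by default), with the add-one estimator
p = (1 + #{perm ≥ obs})/(1 + n_perm). The max statistic is taken over
positive and negative clusters jointly (one two-tailed decision).
Adjacency is temporal only — electrodes are screened independently.

Screening by network identity retains DAN/SN electrodes with significant
positive clusters and DMN electrodes with significant negative clusters;
significant opposite-sign responders are tallied separately. The
correction "for the number of electrodes within each network within
subjects" is not named in the source analyses; Bonferroni within each
subject × network cell is adopted (an assumption), which requires
Monte-Carlo resolution below α/k — raise `n_perm` (e.g. to 2000) when a
cell has many electrodes. Calibration is verified by simulation: the null
responsive fraction at α = 0.05 lies in [0.03, 0.07] over 500 channels,
and a +2 SD effect over 400–900 ms at 50 trials/condition is detected with
a correctly localized cluster in ≥95% of runs.

## Response dynamics

Time-to-peak (TTP) is the latency of the extremum of an electrode's
trial-mean response within +200..+1500 ms — maximum for DAN/SN, minimum
for DMN — with ties to the earliest sample and a degenerate-peak flag for
flat traces. Peak search operates on the trial mean, not per-trial peaks.
Window means use closed windows at −400..0 ms (pre) and +400..+1200 ms
(post); the t = 0 sample belongs to the pre-window. Grand averages are
means over electrodes of per-electrode trial means, with across-electrode
SEM. Recovery: with the generator's network latencies (DAN 500, SN 700,
DMN 1000 ms) and calibrated envelope noise, median recovered TTP is within
±50 ms per network and the DAN < SN < DMN ordering is recovered.

## Inter-electrode coupling

The unsmoothed HFB envelope is trimmed of its first 20 s (pre-task
fixation, or the start of a rest run), band-passed 0.1–1 Hz (zero-phase
4th-order Butterworth; an unfiltered variant skips the band-pass), and
decimated to 10 Hz — well above twice the upper band edge — so that one
envelope sample (0.1 s) is the lag resolution. Two metrics per pair and
run: the zero-lag Pearson correlation, and the lag-minimum correlation —
the most negative Pearson r over all integer-sample shifts within ±2 s.
Each lag's correlation is computed on the truncated overlap of the two
series using that overlap's own mean and SD (no padding or circular wrap);
the sign convention is r(τ) = corr(x[t], y[t+τ]), so a process arriving at
y a delay d after x peaks at τ = d. Ties at the minimum break to the
smallest |lag|, then the negative lag. Values are Fisher-transformed
(z = atanh r, clipping at |r| ≥ 1 − 1e−9 with a warning) and multi-run
values are averaged on the z scale. The lag-minimum of a null curve is
negative by construction (minimum of a noisy function) — the zero-lag
metric in the same model is what controls for this selection bias.

## Multiple kernel learning

For target vs baseline classification, each (electrode, band) contributes
one scalar feature per trial — mean normalized power 0..1500 ms — and one
linear (rank-1) kernel. Kernels are trace-normalized and mean-centered
using training-fold statistics only (implemented as feature centering,
exactly equivalent for linear kernels and leakage-free by construction).
The SVM decision function uses K(d) = Σ d_m K_m with d on the probability
simplex, optimized by alternating exact SVM solves with projected-gradient
steps on the dual objective (step halving on non-decrease, ≤30 iterations,
L1 tolerance 1e−3 — a SimpleMKL-style reduced gradient; equivalence to the
original toolbox is claimed at the level of the optimization problem).
Evaluation is nested, stratified cross-validation: 10 outer folds; an
inner 5-fold CV on each training split picks C from {0.01, 0.1, 1, 10,
100, 1000} by balanced accuracy (ties to the smaller C; the inner fold
count adapts downward for tiny classes). Reported accuracy is the mean
over outer folds of the balanced accuracy (mean of class accuracies);
band contributions are the per-fold sums of d_m over each band's
electrodes, averaged over folds regardless of the fold's chosen C, and sum
to 1. Class imbalance is handled by a seeded subsample of the majority
class before kernel construction. In the separability construction used
for validation, the informative feature's class means sit at ±2
within-class SD of the midpoint. Across-subject comparison of band
contributions (`stats.compare_band_contributions`) uses a
repeated-measures ANOVA over bands followed by two-tailed paired t tests
with Benjamini-Hochberg FDR control at 0.05.

## Group statistics

All models are linear mixed models with a random intercept per subject,
fit by REML (statsmodels MixedLM), with two-tailed Wald F tests at
α = 0.05. Denominator degrees of freedom follow Satterthwaite's
approximation, implemented for the random-intercept structure via the
delta method (gradient of c′(X′V⁻¹X)⁻¹c in the variance components
against the numerical REML information; multi-df terms use the
eigencontrast combination). The implementation reproduces R lmerTest's
DenDF on reference data; at small cohort sizes (6 subjects × 6 runs) the
realized type-I rate of this inference — like lmerTest's — runs slightly
above nominal (≈5–8% at α = 5%), which the calibration tests bound.
Residual df (n − rank X) is the fallback at boundary fits.

Recipes: TTP ~ network; window-mean HFB ~ accuracy within network, and
the error-minus-correct difference ~ network for interactions; run-level
d′ ~ zero-lag z + lag-minimum z, after z-scoring coupling and d′ within
subject across runs (only 90/10-rate runs enter, matching difficulty);
and condition (task = 1, rest = 0) ~ coupling in three variants
(lag-only, zero-only, both). The binary condition model is fit as a
linear(-probability) mixed model rather than logistic, because the
comparison metric is an adjusted R², and is compared via the adjusted R²
of the fixed-effects (marginal) predictions: R² = 1 − SS_res/SS_tot on
Xβ̂, adjusted by (n−1)/(n−p−1). The source analyses do not define their
adjusted-R² formula, so conclusions rest on the *ordering* of R² across
variants, never its absolute value.

## Problem sizes and determinism

Validation runs use deliberately desk-scale problems chosen to make the
statistical properties measurable: 10,000 randomized configurations for
the press-assignment oracle; 500 channels × 1000 permutations for null
calibration; 50 replicate cohorts (6 subjects × 12 electrodes/network ×
100 trials) for TTP recovery; 6-minute envelope pairs for coupling
recovery; 200 trials × 14 kernels for MKL; and a 3-subject, 7-channel,
~2-minute-per-run cohort for the end-to-end demo pipeline. Every
stochastic step takes an explicit seed, and the pipeline writes a manifest
(config hash, seeds, version); identical configs and seeds reproduce all
outputs byte-for-byte.

## Known limitations

* Anatomical electrode localization is out of scope: network labels are
  consumed as input (the synthetic cohort assigns them).
* The generator's lapses are temporally independent; analyses of
  autocorrelated attentional states would need a richer behavior model.
* The mixed-model inference inherits the small-sample anticonservatism of
  the Satterthwaite Wald F shared by standard tools (see above).
* Coupling is measured, not modeled: no directional or causal claims
  follow from a lag-minimum, and no global-signal regression is applied.
* EDF export and clinical-montage handling are not implemented; the flat
  array + JSON sidecar format is the interchange format.
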