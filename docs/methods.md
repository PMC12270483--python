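# Methods

## The detection problem

Serial-bleed LH profiles in mice are short (canonically 19 samples at 10-min
intervals over 180 min) and sparse relative to the underlying secretory
dynamics: a GnRH-driven secretion burst raises serum LH within minutes and
clearance returns it toward baseline with a half-life of tens of minutes, so
a pulse typically occupies one to three grid samples.  Classical
deconvolution is ill-posed at this sampling density; the field instead uses
threshold rules applied to raw assayed values.  This package implements that
rule detector together with everything needed to validate it: a generative
model with known ground truth, the four summary statistics, and the group
statistics used for genotype comparisons.

## Pulse rules and their interpretation

A sample *vᵢ* is called a pulse peak iff it is more than `rise_factor`
(default 1.20) times **each** of the two previous samples, and more than
`fall_factor` (default 1.10) times the following sample; at index 1, where
only one predecessor exists, the rise test uses `second_point_factor`
(default 1.20) against that single value.  Decisions that the rule text
alone does not fix, and how this implementation resolves them:

* **"20% greater than the two previous values"** is read per-value, not as
  a comparison against their mean.  The per-value reading is the stricter
  (more conservative) one; `rise_compare="mean"` switches to the aggregate
  reading.
* **Strict inequalities** throughout: a peak exactly at threshold is not a
  pulse ("greater than" is strict).
* **The fall condition applies everywhere**, including at index 1: it is
  stated for any peak, so the second-point rule replaces only the rise test.
* **The final sample is never callable** because its fall condition has no
  datum to evaluate; `allow_last=True` waives the condition there, but is
  off by default since an un-confirmable peak is not evidence of a pulse.
* **No smoothing, no refractory period**: each index is evaluated
  independently on raw values.  (Arithmetically, two *adjacent* indices can
  never both satisfy the predicate — the fall condition of the first
  contradicts the rise condition of the second — but peaks two samples
  apart can, and do.)

The rules are purely multiplicative, so pulse calls are invariant under
rescaling of the series; the test suite checks this property directly.

## Summary statistics

* **AUC**: trapezoidal integration of (minutes, ng/ml).  With LH around
  0.4–0.6 ng/ml over 180 min this yields AUC ≈ 70–110 ng·min/ml, the
  magnitude reported for this design.  A plain sample-sum is the other
  conceivable convention; the trapezoid is the default because it is the
  standard quadrature and reproduces the published magnitudes.
* **Amplitude / basal**: means of the 4 highest / 4 lowest samples, over
  *all* samples including called peaks — no exclusion is part of the
  definition.  Both are order statistics, so basal ≤ amplitude always.
* **Pulse count**: number of called indices in the window.

## Generative model

Noiseless concentration: `C(t) = baseline + Σ aᵢ·2^(−(t−tᵢ)/half_life)` for
`t ≥ tᵢ` — instantaneous secretion bursts with first-order clearance, the
minimal model producing the sampled morphology the rules target.  Onsets
follow a gamma renewal process (shape 4 by default, giving the quasi-regular
ultradian pulsing seen in rodent profiles) started at a uniform phase;
increments are log-normal.  The observation model adds Gaussian assay noise
and left-censors at the detection floor: `obs = max(C(t) + ε, lod)`.

Default calibration (`SimParams()` / the `paper-like` CLI preset):

| parameter | default | unit | rationale |
|---|---|---|---|
| baseline | 0.35 | ng/ml | control-range basal LH |
| mean_ipi | 60 | min | ~2–4 pulses per 180-min window |
| ipi_shape | 4 | — | quasi-regular renewal; exposed for regularity sweeps |
| amp_mean / amp_sd | 0.3 / 0.15 | ng/ml | peaks reach ~0.5–0.8 ng/ml |
| half_life | 20 | min | murine LH clearance scale |
| noise_sd | 0.02 | ng/ml | ELISA replicate scatter (CV a few %) |
| lod | 0.0039 | ng/ml | assay functional sensitivity |
| interval / duration | 10 / 180 | min | the canonical sampling design |

These defaults place simulated basal, amplitude, AUC and pulse count in the
control ranges reported for this design; they are calibration choices of
this package, not measured secretion parameters — no deposited raw series
exists to fit them against.

What the generator deliberately does **not** emulate: circadian or
estrous-stage modulation of pulse frequency, amplitude–interval coupling,
slow baseline drift, heteroscedastic assay error, and carry-over between
animals.  Tests passing on simulated data therefore validate the *rules and
estimators*, not the biology of any particular mouse line.

`isolated_pulse_params` constructs the noise-free recovery conditions used
in benchmarking: first onset uniform in [35, 50] min (so the four pre-pulse
grid samples sit exactly at baseline and the basal estimator is exact), gaps
uniform in [50, 70] min, amplitudes uniform in [0.4, 0.6] ng/ml.  On the
noiseless grid each such pulse provably passes the rules: at worst the peak
sample is `baseline + 0.707a` (onset just after a grid point), its
predecessors are ≤ `baseline + 0.177a` (≥ 50 min of decay), and the next
sample is `baseline + 0.5a`, so with baseline 0.35 and a ≥ 0.4 both the 20%
rise and the 10% fall margins hold with room to spare.  Detection
sensitivity on these conditions is exactly 1 and basal error exactly 0 —
any failure is a detector defect, not sampling noise.

At the default (noisy, overlapping-pulse) calibration the detector's
sensitivity is ~0.6 with precision ~1.0: the rules are conservative by
construction, missing small increments riding on an undecayed previous
pulse.  The benchmark module reports this honestly rather than tuning the
generator to flatter the rules.

## Other generators

* **Estrous cycles**: a semi-Markov chain P→E→M→D with per-stage dwell
  `1 + Poisson(mean − 1)` days, started in a stage drawn by stationary
  occupancy.  Regular dwell means (P 1, E 1.2, M 1, D 1.5) give ~4.7-day
  cycles; the irregular preset inflates the diestrus dwell to 6 days,
  reproducing the longer-diestrus/shorter-estrus phenotype.  An infinite
  diestrus dwell yields the degenerate all-diestrus log.  Dwell values are
  this package's calibration; the studies report only stage-proportion
  differences, not dwell distributions.
* **Surge cohorts**: AM log-normal around `am_mean` with coefficient of
  variation `cv`; PM = AM × group surge factor × an independent mean-1
  log-normal.  With cv = 0 the recovered group mean PM/AM ratio equals the
  configured factor exactly.
* **qPCR**: a group with true fold f amplifies log2(f) cycles earlier
  (target Ct = base_ct − log2 f + noise); housekeeping Ct is a shared
  constant plus noise; replicates are independent.

## Quantification and statistics

**Comparative Ct.** Replicate Cts are averaged per (sample, gene); ΔCt =
target − housekeeping (Hprt by default); ΔΔCt is referenced to the
*mean* ΔCt of the reference group (the standard convention where mean vs.
median is unstated), so the reference group's geometric-mean fold is exactly
1; fold = 2^(−ΔΔCt), i.e. amplification efficiency is fixed at 2 with no
efficiency correction.  Single-batch normalization is assumed (no per-plate
calibrators).

**Group statistics** are computed from first principles — scipy supplies
only the t, F and studentized-range distributions:

* unpaired t: pooled variance by default, Welch–Satterthwaite optional;
  two-sided p.
* one-way ANOVA: F = MS_between/MS_within on (k−1, N−k) df.  Fisher's LSD
  is, by definition, all pairwise t tests sharing MS_within and its df,
  unadjusted.  Significance letters come from the maximal cliques of the
  non-significant-pair graph, assigned smallest-mean-first: groups share a
  letter iff no member pair differs at α, so "different letters ⇒
  significantly different" holds exactly.  Zero within-group variance is
  rejected as degenerate rather than reported as F = ∞.
* two-way factorial ANOVA: unweighted cell-means analysis with the
  harmonic-mean cell size (Type III-style), which coincides with the
  classical decomposition for balanced data — the designs this serves are
  nearly balanced and no SS type is mandated by convention here.  All cells
  must be non-empty and at least one replicated.  Post hoc comparisons are
  pairwise factor-A levels within each factor-B level (the comparisons the
  typical genotype × stage / genotype × time-of-day figures annotate),
  using the pooled error MS: Sidak adjusts each p as 1−(1−p)^m over the m
  comparisons performed; Tukey refers the studentized range (k = number of
  factor-A levels) to its distribution.  The headline statistic/p of the
  two-way result is the interaction; the full effect table is attached.
* α = 0.05, all p two-sided.  Outlier handling is out of scope: inputs are
  analyzed as given.

**Phenotyping metrics.** Stage proportions are day counts over logged days
×100; metestrus is folded into diestrus by default (three-stage reporting),
with the four-stage breakdown available — collapsing never changes the
proestrus/estrus percents.  Puberty curves report, per integer age, the
percent of animals with event age ≤ that age (non-decreasing, ending at
100), plus mean ± SEM per group.  Surge response is reported descriptively
(delta = PM − AM; ratio = PM/AM, undefined at AM = 0) — no numeric "surge
present" threshold is invented, since blunting is defined only by the group
comparison.  SEM is sd(ddof=1)/√n, NaN (flagged) for n = 1.

## Benchmarking conventions

Detections match true onsets greedily, one-to-one in time order, within a
tolerance of one sampling interval (10 min) — detection resolution cannot
exceed the grid.  Unmatched detections are false positives, unmatched truths
false negatives; sensitivity/precision are NaN when their denominators are
empty (e.g. a no-pulse preset has no truths).  Estimator truth for
AUC/basal/amplitude is the same statistic computed on the *noiseless* curve
at the same grid, so reported bias isolates noise + rules from
discretization.

## Numerical choices and degenerate inputs

* Times are re-based to minutes from each animal's first sample on read;
  duplicate times, negative or non-finite LH, and schema violations raise
  typed errors naming the animal/row — rows are never silently dropped.
* Missing LH values reject the series by default; an explicit option
  interpolates a single missing interior sample linearly (and logs it).
  No missing-sample policy is part of the published analysis, so this is a
  configuration choice.
* CSV writers render floats with the shortest round-trippable decimal repr
  and the readers parse with round-trip precision, making write→read the
  identity bit-for-bit (and the end-to-end pipeline byte-deterministic for
  a fixed seed).
* Amplitude/basal ties are broken arbitrarily — the mean of the k extreme
  values is tie-invariant.
* Detector preconditions: n ≥ 3 for calls, n ≥ 2 for AUC, n ≥ k for the
  extreme-value means; violations raise `SeriesTooShortError`.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at sizes chosen to exercise the
asymptotics that matter while staying quick on one CPU: 1,000 series for
detector–oracle equivalence, 200 seeds for noise-free recovery and the
renewal-rate law of large numbers, 100 datasets for the F = t² identity,
5,000 (suite) / 2,000 (script) replicates for the empirical type-I error,
and 200 simulations per benchmark point.

## Known limitations

* The detector is a fixed-threshold rule set; its sensitivity degrades for
  overlapping or small pulses and it offers no continuous score, so no ROC
  analysis is meaningful (binary output only).
* The generator's defaults cannot be validated against deposited raw data
  (none exists); they are calibrated to the published summary ranges only.
* Unbalanced two-way designs use unweighted cell means; strongly unbalanced
  or missing-cell designs need a regression-based framework out of scope
  here.
* No deconvolution of secretion/clearance parameters, no frequency-domain
  analysis, no baseline-drift correction, no automated outlier removal.
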