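# Methods

This note documents the statistical procedures implemented in `breathval`,
the modeling choices made where the underlying methodology left the design
open, and what the synthetic-data tests do and do not demonstrate.

## Preprocessing of aligned ion tables

The pipeline's input contract is the long-form output of chromatographic
peak alignment: one row per detected ion with retention time (seconds),
m/z, and intensity, plus a sample-metadata table. Peak detection,
deconvolution, vendor formats, and spectral library matching are out of
scope — the aligned table is the interface.

**Internal-standard normalization.** Every chromatogram carries a known
quantity of bromofluorobenzene; its m/z-95 ion is located as the
maximum-intensity m/z-95 record inside a configurable retention-time
window (default: the whole run, since no canonical elution time is
assumed). All intensities are divided by this record's intensity, making
features dimensionless ratios and removing sample-to-sample loading
differences; multiplying a raw chromatogram by any positive constant
leaves the normalized features unchanged (tested). Retention-time
alignment is a single-point linear rescaling by
`reference_is_rt / observed_is_rt` when a reference elution time is
configured — the simplest model consistent with a single anchor
compound — and the identity otherwise.

**Binning.** Records land in half-open 5-second segments,
`segment = floor(rt / 5)`, at unit-mass m/z (fractional m/z rounds half
up, matching the integer m/z convention of reported marker ions). Multiple
records of one (sample, segment, m/z) are summed, because ion current is
additive; a feature absent from a sample's chromatogram is exactly 0
(absence of signal, not missing-at-random). Total normalized intensity is
conserved by binning. An optional prevalence filter can drop features
present in too few samples (default keeps everything).

Room-air samples are ingested and flagged (`sample_kind = room_air`) but
never subtracted: no defensible subtraction rule exists without assay
blanks matched in time, so they are simply excluded from all statistics.

## Monte-Carlo C-statistic screen

Each feature is scored for tissue-confirmed cancer (group 3,
cancer-positive) versus CT-negative controls (group 1, cancer-negative);
other groups, unknown statuses, room air, and blinded-phase samples never
enter screening. The score is the Mann–Whitney concordance probability
(ROC AUC) with midrank tie handling, folded to [0.5, 1] with an
orientation sign (+1 elevated in cancer, −1 depressed). Folding is applied
to permuted scores as well by default (`fold_random=False` gives the raw
alternative).

The null reference is built by randomly reassigning **subjects** — not
rows — to the two diagnosis groups, preserving group sizes, 40 times by
default; one reassignment per replicate is shared by all features, so
inter-feature correlation survives under the null. Subject-level
permutation matters: the analysis pools duplicate samples of each subject
from two laboratories as separate rows, and shuffling rows independently
splits a subject's replicates across classes, shrinking the null variance
of the C-statistic and inflating discoveries. With subject-level
permutation the per-ion null C distribution is indistinguishable from the
correct-assignment distribution on signal-free data (two-sample
Kolmogorov–Smirnov, tested), and on signal-free 1,000-ion panels the
screen selects ~0% of ions.

On a C grid (step 0.01) the screen counts features at or above each value
under correct assignment, and the mean and SD of that count across
permutations. The **cutoff** is the smallest grid value where the mean
random count is exactly zero — i.e. no permutation of any feature reached
it — and the features above the cutoff are the better-than-random markers,
of which the top K (default 500) by C-statistic are retained, with the
deterministic tie-break (C descending, then segment, then m/z ascending).
The curve separation is also summarized in random-count SDs
(`sigma_separation`), evaluated at the largest grid point at or below the
cutoff where that SD is positive (the SD is identically zero wherever the
random count is).

A consequence worth stating plainly: this cutoff is an extreme-value
statistic. With `P` permutations of `F` features it sits near the maximum
of `P·F` null draws — about 4 null SDs above 0.5 for 40 × 1,000 draws,
i.e. C ≈ 0.68 at 95/81 subjects — so markers whose true accuracy is close
to the cutoff are recovered only partially (planted ions at C = 0.70 are
recovered at ~65–70%, while ions at C ≥ 0.75 are recovered almost
completely). The screen trades sensitivity near the threshold for strict
false-discovery control; global ranking across segments is the default,
with within-segment ranking available behind the same interfaces.

## Weighted digital analysis (WDA)

WDA is a weighted-voting discriminant: marker `j` contributes its weight
`w_j` to a sample's discriminant function DF when
`sign_j · (x_j − cutoff_j) > 0`, strictly. The fit freezes, per marker:
the **sign** from the screen's orientation; the **weight** as the oriented
C-statistic (configurable alternative: `2C − 1`); and the **cutoff** as
the intensity threshold maximizing Youden's J (sensitivity + specificity
− 1; configurable alternative: accuracy) over midpoints of consecutive
distinct observed values, ties toward the smaller cutoff. A constant
feature has no midpoint; its rule is retained with a warning and never
fires. DF is bounded by 0 and the summed weights; a feature missing from a
prediction matrix scores as intensity 0, consistent with the binning
semantics. Classification is `DF > df_cutoff`, again strict.

Prediction consults intensities only — never metadata — and the results
object carries a SHA-256 hash of its rule parameters frozen at fit time;
the blinded report recomputes the hash before and after prediction and
refuses to unblind if the model changed. Training pools both laboratories'
rows (a per-subject averaging flag is available given the known risk of
subject-level leakage when duplicates are treated as independent).

## Validation metrics

Sensitivity and specificity are computed at every distinct observed DF
value plus 0, with strict positivity, making sensitivity non-increasing
and specificity non-decreasing in the cutoff. The discrete step curves
rarely intersect exactly; the **crossover** operating point is
operationalized as the cutoff maximizing sens + spec (the quantity that is
maximal where continuous curves would intersect), ties toward the smaller
cutoff. The DF's overall accuracy is its Mann–Whitney C-statistic, which
equals the trapezoidal area under the step ROC built from the same grid
(tested identity). Inter-laboratory concordance is the Pearson correlation
of subject-matched replicate DF values, with a Fisher-z 95% confidence
interval; subjects missing either replicate are dropped and counted.
Samples with unknown cancer status receive DF values but are excluded
from performance metrics.

## Combined-screening outcome model

Two tests with sensitivities/specificities `(sensA, specA)`,
`(sensB, specB)` are combined assuming **conditional independence given
disease status** — the standard, and strong, assumption of the
series/parallel algebra; correlated test errors would pull both combined
profiles toward the better single test. Series (both positive):
`sens = sensA·sensB`, `spec = 1 − (1−specA)(1−specB)`. Parallel (either
positive): `sens = 1 − (1−sensA)(1−sensB)`, `spec = specA·specB`.
Predictive values at prevalence `p`:
`PPV = sens·p / (sens·p + (1−spec)(1−p))`,
`NPV = spec(1−p) / (spec(1−p) + (1−sens)p)`. Expected TP/FN/TN/FP among
`n` screened are the exact cell probabilities times `n`, kept as exact
fractions internally and rounded only for display. Exact consequences of
the algebra (tested): the series rule cuts the first test's false
positives by exactly `specB`, and the parallel rule cuts its false
negatives by exactly `sensB`.

With chest CT at sensitivity 93.8% / specificity 73.4%, a breath test at
70.1% / 68.0%, and prevalence 1.1%, the model gives CT-alone PPV 3.77%,
FP 263,074 and FN 682 per million, series specificity 91.49% and PPV
7.91%, parallel sensitivity 98.15%, and a prevalence-only pre-test NPV of
98.9%. Note the internal tension in published versions of this arithmetic:
a series FP count of 88,919/million corresponds to combined specificity
91.01%, which is inconsistent with the 91.49% produced by these breath
inputs (91.49% gives 84,184). The package reproduces the set consistent
with the stated inputs and does not arbitrate.

## Synthetic cohort generator

The generator emulates the statistical structure of a two-laboratory
breath-biomarker study, not its chemistry. Ion abundances are log-normal
(positive, right-skewed, multiplicative noise — the standard abundance
model). Per subject, each ion's latent log intensity is
`Normal(baseline_log_mean, log_sd_subject)`; each laboratory observes the
latent value plus independent `Normal(0, log_sd_lab)` replicate noise
(optionally a systematic per-lab offset to stress normalization), then
exponentiation, with the internal-standard record appended at a fixed
retention time. Informative ions get their mean shifted by `±δ` in cancer
subjects with random, equiprobable direction, where
`δ = σ_total·√2·Φ⁻¹(target_auc)` and `σ_total² = log_sd_subject² +
log_sd_lab²` is the variance of an observed log intensity — so the
theoretical per-laboratory AUC `Φ(δ/(σ_total√2))` equals `target_auc`
exactly and serves as the oracle for recovery tests (empirical bias
< 0.01 at n = 2,000 per group, tested). The between-laboratory Pearson
correlation of log intensities is
`log_sd_subject²/(log_sd_subject² + log_sd_lab²)`.

Defaults are the study conditions: 95 cancer / 81 control model-building
subjects (73/68 in the blinded phase), 50 informative ions at target AUC
0.70, replicate correlation tuned to 0.88
(`log_sd_subject = 1`, `log_sd_lab ≈ 0.369`), a baseline log-mean of 9.2
(raw abundances ~10⁴ against a 10⁶ internal standard), and a 1,000-ion
candidate panel — a deliberately down-scaled stand-in for a full ~70,000
ion chromatographic panel chosen to keep repeated-replicate calibration
experiments fast; panel size is a config field, and the screen's
vectorized rank computation handles full-scale panels as well. A single
integer seed drives all randomness; identical configs are bit-identical,
and a blinded cohort derives its noise from a decorrelated stream so
reusing a seed cannot couple the two phases.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: ions are independent given the subject, whereas
real fragment ions of one parent VOC are strongly correlated (real marker
panels carry far less independent information than simulated ones, which
is why a simulated 30-marker panel reaches blinded C ≈ 0.99 where a real
study of this design reported C ≈ 0.70); there is no chromatographic
drift, co-elution, or room-air contamination; effect sizes are
homogeneous; and the log-normal form is an assumption. Relatedly, the
DF-level inter-laboratory correlation on a blinded cohort is *not* the
tuned ion-level 0.88: binarized votes attenuate the within-class
correlation (to ≈ 0.65) while the disease separation common to both
laboratories inflates the overall value (to ≈ 0.92–0.94). The ion-level
correlation is the quantity the generator controls and the one recovered
quantitatively; the DF-level value is reported as the study-level
analogue.

## Numerical conventions

- C-statistics use midranks (ties count one half); folded values are
  `max(a, 1 − a)` with orientation `+1` iff `a ≥ 0.5`.
- Strict inequalities throughout rule firing and DF classification; a DF
  exactly at the cutoff is negative.
- Grid step 0.01 for screen curves; "declined to zero" means a mean
  random count of exactly zero (no occurrence in any permutation).
- Ties in cutoff searches and crossover selection break toward the
  smaller threshold; marker ordering ties break by (segment, m/z).
- CSV writers emit shortest round-trip decimal representations and
  readers parse with correct rounding, so write → read is bit-exact; JSON
  artifacts are key-sorted. All stages are byte-deterministic under a
  fixed seed.
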