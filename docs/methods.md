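# Methods

## The marker

A subject's ADC map (units 10⁻⁶ mm²/s) is reduced, after brain masking,
to the multiset of in-mask voxel values. Voxels outside the closed
analysable band [200, 2000] are excluded — low values are predominantly
artefact, high values CSF/fluid — and for each threshold x on the grid
{250, 300, …, 1150}:

ADC-R(x) = 100 · #{v : 200 ≤ v ≤ x} / #{v : 200 ≤ v ≤ 2000} (percent).

Counts are integers over closed intervals; there is no interpolation.
Consequences used throughout the tests: ADC-R is non-decreasing in x,
bounded in [0, 100], invariant to any spatial rearrangement of in-mask
voxels, and invariant to strictly increasing transforms of none (it
depends on absolute ADC values, unlike the rank statistics downstream).
Whether boundary voxels (exactly 200 or 2000) are kept is a convention;
we keep them (both intervals closed). The choice is measure-zero for
continuous data but is fixed for reproducibility. NaN or negative
voxels inside the mask fail the band test and are counted in the
exclusion tallies (`excluded_low`/`excluded_high`), never silently
dropped. Percentages are carried at full floating precision; rounding
to one decimal happens only in display columns.

Mask erosion is deliberately not re-implemented: the mask is an input,
produced by whatever brain-extraction pipeline the user trusts. The
fallback segmentation (keep voxels in (0, 3500]) exists only so
unmasked synthetic volumes can be processed; it is documented as not
equivalent to skull-stripping.

## Outcome and rules

Outcome is binary: poor = Cerebral Performance Category 3–5 at six
months, good = CPC 1–2. The positive class is poor outcome, and
ADC-R(x) is oriented so larger values are worse.

Cutoffs are derived at 100% specificity (zero false-positive rate), the
operating point required when a test result may inform withdrawal of
life-sustaining therapy: c = max of the marker over good-outcome
derivation subjects, rule "marker > c" (strict). A poor-outcome subject
tied exactly with the good maximum is rule-negative — ties count
against sensitivity. On the derivation sample the rule has FP = 0 by
construction; on validation cohorts specificity may fall below 100%.

## Statistics

* **AUC** — empirical Mann–Whitney form: mean over all (pos, neg) pairs
  of 1/½/0 for greater/tied/smaller. Equals the trapezoidal area under
  the empirical ROC (asserted against scikit-learn's `roc_auc_score`
  and a brute-force pairwise oracle in the tests).
* **DeLong variance/covariance** — structural components
  V10(i) = mean kernel over negatives, V01(j) = mean over positives;
  var = S10/m + S01/n with sample (n−1) variances. Paired comparisons
  (two markers, same subjects) use the structural-component covariance;
  cross-cohort comparisons of the same marker use the unpaired form
  var_a + var_b. z is referred to the standard normal, two-sided.
  Degenerate case: zero variance with zero AUC difference (e.g. a
  marker against itself) returns p = 1; zero variance with a non-zero
  difference is an error rather than a fabricated p. Near-perfect
  separation (AUC → 1) shrinks the variance toward 0 and the normal
  approximation degrades — a property of the DeLong test itself, which
  is why the calibration test uses moderately-overlapping
  distributions.
* **Confidence intervals** — AUC: Wald, auc ± 1.96·√var, clipped to
  [0, 1]. Proportions (sensitivity/specificity/PPV/NPV): exact
  Clopper–Pearson via beta quantiles (statsmodels `proportion_confint`,
  method "beta"); at k = n the lower bound is (α/2)^(1/n), which is the
  closed form the published all-success bounds (95.8% at n = 86, 87.7%
  at n = 28, 94.5% at n = 65) follow to the printed decimal — this is
  what fixed the CI-method choice. Ratios with zero denominator are
  reported as not-available (NaN), never as 0.
* **Group comparisons** — Mann–Whitney U (tie-corrected asymptotic;
  exact enumeration for untied samples ≤ 8 per group) for two groups;
  Kruskal–Wallis (tie-corrected, df = 2) for three, with pairwise
  Mann–Whitney post hoc flagged at the Bonferroni level α/3 ≈ 0.0167.
  Categorical 2×2 tables use Yates-corrected χ², switching to Fisher's
  exact when any expected cell is < 5; 2×k tables use plain χ².
  α = 0.05, all tests two-sided.
* **AUC bands** — 0.50–0.69 poor, 0.70–0.79 fair, 0.80–0.89 good,
  0.90–1.00 excellent, below 0.50 "worse than chance"; boundaries
  belong to the upper band.

No multiplicity correction is applied across the 19 thresholds of the
derivation table; the per-threshold DeLong p-values against the
reference are descriptive, mirroring standard practice for this table
layout.

## Study design

One site's subjects are split into derivation and internal validation
by simple (unstratified) random sampling — round(0.70·n) to derivation —
under a dedicated split seed; whether such splits are stratified is
rarely reported, so unstratified is the default and a stratified-by-
outcome variant sits behind `stratified_split`. The second site is the
external validation cohort and is never split. The reference threshold
for DeLong comparisons defaults to x = 600 (configurable). Leakage is
structurally impossible — cutoffs are functions of the derivation
records only — and a test asserts that perturbing validation data
leaves them bit-identical. The two-rule comparison table contrasts the
literature rule ADC-R(650) > 10% with the derived zero-FPR rule at 650
in all three cohorts, reporting raw TP/FP/FN/TN so every percentage can
be recomputed from counts. Published versions of such tables sometimes
disagree with their own counts; this pipeline reports the one
self-consistent value computed from counts.

## Synthetic cohorts

Each phantom brain is an ellipsoidal mask (semi-axes 0.45 of each grid
dimension) on a default 24³ grid at 7 mm isotropic — a deliberately
coarse grid (~7200 brain voxels) chosen so a 448-subject study runs in
seconds; the statistic only sees the voxel-value histogram, so grid
resolution trades Monte-Carlo noise against runtime, nothing else.
In-mask values are an iid three-component truncated-normal mixture:

| tissue | mean | sd | truncation | weight |
|---|---|---|---|---|
| lesion | 450 | 90 | [200, 700] | f (per subject) |
| CSF | 2600 | 400 | [1800, 3500] | 0.10 |
| parenchyma | 800 | 100 | [400, 1400] | 1 − f − 0.10 |

Lesion parameters sit in the cytotoxic-oedema band that makes
thresholds 450–650 clinically meaningful; CSF deliberately straddles
the 2000 cap so the exclusion filter has real work to do. The lesion
burden f is Beta(2, 60) (mean ≈ 3%) for good outcome and Beta(4, 8)
(mean ≈ 33%) for poor outcome, rejection-truncated to [0, 1 − csf].
These defaults were calibrated once so that a 224-subject derivation
cohort yields a zero-FPR cutoff for ADC-R(600) in the low-teens percent
range; the cutoff realised for a given seed is the good-group empirical
maximum of a Beta-driven quantity, so it varies by a few points across
seeds (e.g. 16.2% at one seed, 11.7% at another).

Rendering places lesion values as 1–5 contiguous nearest-to-seed-point
blobs and CSF as a central pool; since ADC-R is spatially blind this
only serves realism and future spatial extensions, and a test asserts
the rendered volume's statistic equals the raw multiset's exactly.
`expected_adc_r` gives the closed-form mixture value from truncated-
normal CDFs and is the oracle against which empirical profiles are
checked (within four conditional-binomial standard errors, plus a 2/n
discreteness guard for thresholds whose expected counts are near zero).

Randomness: one master seed; subject i's stream is seeded by
(seed, i), so cohort composition or ordering cannot change a subject's
image. Outputs (manifests, volumes, report CSVs) are byte-reproducible
under fixed seeds.

What the phantoms do **not** emulate: acquisition noise (Rician),
partial-volume voxels, scanner/vendor effects, spatially structured
lesion topology (watershed patterns), brain atrophy, or time-dependent
ADC pseudo-normalisation. Passing tests therefore demonstrate the
correctness of the quantification and statistical machinery under the
assumed mixture model — not clinical performance on real maps, where
group separation is far weaker (the synthetic design's AUC ≈ 0.998
versus ≈ 0.91 reported on patient data, and correspondingly higher
sensitivity at the zero-FPR point).

## Problem sizes

The default test and acceptance runs use: the full 320 + 128 study
replica once at 24³ resolution; 50-subject generator-oracle agreement
at 20³; 1000-replicate DeLong calibration at 100 + 100 markers per
cohort; 200 random derivation cohorts for the zero-FPR guarantee; and
50-seed cross-cohort comparisons at 16³ with 40 + 40 subjects per
cohort. These sizes keep the whole suite under a minute while leaving
every Monte-Carlo bound several standard errors wide.

## Known limitations

* The fallback segmentation is a positivity threshold, not brain
  extraction; using it on real data will inflate the denominator.
* Wald AUC intervals can degenerate at AUC = 1 (zero DeLong variance);
  the pipeline reports the point estimate with a collapsed interval
  rather than switching to a different interval family.
* Fisher's exact test is implemented for 2×2 tables only; larger
  sparse tables fall back to χ² without exactness.
* The baseline-characteristics table recognises a fixed covariate
  vocabulary (age, sex, arrest characteristics, no-flow/low-flow
  times); unknown columns are ignored with a warning.
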