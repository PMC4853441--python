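# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data generator and the numerical choices behind `fluencymap`,
in the order the pipeline runs them.

## Behavioral model

Fluency trials yield counts: correct, non-repeated words, compared
case-insensitively after whitespace trimming, with correctness an
injectable predicate (language-specific judgments are not reproducible in
code and are left to the caller). Phonemic fluency is the sum of the two
letter trials and is missing when either trial is missing.

Demographic adjustment is *sample-referenced*: the regression
`raw ~ 1 + age + sex + education` is fit on the cohort itself, not on an
external normative sample, and `z = residual / s` with
`s² = RSS / (n − p)` (p = number of regressors including the intercept;
the choice of denominator is recorded in the output metadata). Education
enters as a single linear ordinal covariate on the 7-category Dutch
scale; sex is its 0/1 code. Consequences worth knowing:

* `mean(z) = 0` exactly, and `sd(z) = 1` when the sd uses `ddof = p`.
* z is invariant to positive affine rescaling of the raw score.
* When demographics are constant the fit collapses to plain
  standardization `(raw − mean)/sd`.
* A rank-deficient design or zero residual variance is an error, not a
  silent degenerate fit.

Dichotomization uses strict `<` against a normative 5th-percentile
cutoff supplied as configuration (`NormTable`); a score at the cutoff is
not impaired. Correlations between measures are pairwise-complete Pearson
r with two-tailed p, the per-pair n reported, because missingness differs
per test.

## Voxel-based lesion-symptom mapping

Tested voxels: lesion count ≥ `min_count` (default 3) *and* at least one
intact subject. No separate brain mask is modeled — the count threshold
subsumes it, since voxels outside the brain are never lesioned.

Per tested voxel the lesioned and intact groups are compared on z.
Subjects with a missing score are excluded voxel-wise, not listwise, so
each voxel uses every scored subject. The default statistic is the
pooled-variance (Student) two-sample t, matching the classic VLSM
implementations; Welch is available by flag. The statistic is signed
positive when the lesioned group performs worse, and the default p value
is one-tailed in that direction: a lesion associated with *better*
performance is not a discovery. Two-tailed mode is a flag; the FDR is
computed over whichever p values the tails setting produces, and this
assumption is recorded in the run manifest. Zero-variance or
under-populated voxels (a group below 2 usable subjects) are kept in the
map with statistic 0, p 1, and a degenerate flag, so the map stays total.

The t computation is vectorized through lesion-matrix inner products
(group membership differs per voxel, so a one-shot library call does not
apply) and is contractually identical to a per-voxel scipy loop, which
the tests verify to 1e-10. The Brunner–Munzel statistic uses combined-
sample midranks computed once — missingness is per-test, so the combined
sample is constant across voxels — and a per-voxel pass for the
within-group rank variances, with the t approximation and
Welch–Satterthwaite-type df; it matches `scipy.stats.brunnermunzel`
(alternative "less") to 1e-8. The t approximation for BM is unreliable
below roughly 10 subjects per group; the statistic is computed anyway and
the caveat lives here.

FDR: Benjamini–Hochberg step-up, no dependency correction, over the
tested voxels only. The realized cutoff (largest `p(k) ≤ k·q/m`) is
reported alongside q in the sidecar; an empty survivor set yields cutoff
0. Monotonicity in q is a tested invariant.

## Subtraction maps

Group overlays split lesion prevalence by impairment flag; subjects with
an undefined flag are excluded and counted. The subtraction value is the
exact percentage-point difference; display rounding is half-up to integer
percent (16.67 → 17). No inferential statistic is attached — the map is a
qualitative robustness check against the VLSM result.

## ROI regression

Regions are selected per outcome when they contain ≥ `min_sig` (default
100) significant voxels; the union of selected regions is then modeled
for *both* outcomes, so the output table reports every selected region
under every outcome. Regional lesion volume is lesioned-voxel count ×
voxel volume, in ml (1000 mm³ = 1 ml).

The hierarchical fit uses statsmodels OLS with listwise deletion. ΔR² is
tested by the partial F test, which for one added regressor equals the
coefficient's two-sided t test (asserted to 1e-10 in the tests). The CI
for B is t-based, 95 %, two-sided. Because z is pre-adjusted for the same
demographics, the base model's R² is ~0 by construction in the
unadjusted variant; it becomes informative once total lesion volume is
added. A constant regional volume (e.g. all zeros) returns the base fit
with ΔR² = 0 rather than a rank error; genuine collinearity (regional
volume proportional to total volume) is an error with a diagnostic.

Two table ambiguities are resolved by emitting both candidate numbers:
patients-with-lesion counts are reported over all subjects and over the
analyzed subset, and the percent column is percent-of-tested with both
raw counts always printed.

## Synthetic cohort generator

What it emulates: a first-ever ischemic stroke cohort of n = 93 with
spatially contiguous unilateral lesions, a territory-like prevalence
core, right-hemisphere predominance, an infratentorial compartment,
fluency scores on the raw-count scale, auxiliary language/memory tests
with per-test missingness, and demographic effects on performance.

* **Space.** Deterministic 32³ toy template (1 mm³ voxels): an
  ellipsoidal supratentorial brain plus an inferior-posterior
  infratentorial blob, parcellated into 8 labeled regions (left/right ×
  frontal/temporal/parietal analogues, a dorsal left middle-frontal
  analogue, infratentorial). World x < 0 is left.
* **Lesions.** One per subject, grown by stochastic region growing
  (iteratively absorb a random frontier voxel) from a seed point drawn
  with Gaussian weight (σ = 5 voxels) around a per-hemisphere
  middle-cerebral-artery-like core, confined to one compartment; volume
  uniform in 60–900 voxels (0.06–0.9 ml at toy scale). Location
  probabilities 0.40 left / 0.47 right / 0.13 infratentorial mirror the
  emulated study's 34/40/12 split.
* **Behavior.** `raw = baseline − Σ_v w(v)·lesion(v)·voxel_ml +
  β_age(age−60) + β_sex·sex + β_edu(edu−5) + N(0, σ)`, rounded and
  clipped at 0. Baselines 23.1 animals / 7.7 + 8.0 letter words; noise σ
  7 (animals) and 3 per letter trial; demographic effects small and
  negative for age, positive for education. Default ground-truth weights
  (raw points per ml on the toy scale): semantic {left temporal 80, left
  inferior frontal 50}, phonemic {left middle frontal 60, left inferior
  frontal 30} — a shared ventral-frontal substrate plus one distinct
  region per outcome, the structure the pipeline is meant to recover.
  Auxiliary tests are linear in the two fluency losses plus noise, with
  missingness of exactly 4/8/2/8 subjects.
* **Norm cutoffs.** The packaged `default_norms()` fixes cutoffs near the
  5th percentile of the lesion-free generative distribution (semantic 10,
  phonemic 8), so cohort impairment rates above ~5 % are lesion-driven;
  the defaults yield ~14–24 % impaired, comparable to stroke cohorts.

Weights are quoted per ml *on the toy scale* and are deliberately larger
than plausible per-ml effects on a real 1 mm MNI grid, because toy
lesions are ~100× smaller in ml than real infarcts.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic vascular-territory shapes, CT/MR
segmentation noise, registration error, lesion-size/location confounds
beyond territory clustering, non-Gaussian behavioral noise, and practice
or aphasia-related missingness mechanisms (missingness is completely at
random).

### Mislocalization

Because lesions are spatially extended, voxels *near* a causal region are
lesioned by largely the same subjects as voxels inside it, and inherit a
genuine association with the deficit. This is the classic VLSM
mislocalization phenomenon, and it is why "all significant voxels lie in
the causal region" is not an achievable criterion at study scale: with
n = 93 and 0.06–0.9 ml lesions, 2–12 % of out-of-region tested voxels
reach significance next to a strongly detected region. The sensitivity/
specificity property is therefore tested under conditions where the
per-voxel groups decorrelate (n = 400, lesions 60–300 voxels, one causal
region), where mean sensitivity ≈ 0.86 and the out-of-region significant
fraction ≈ 0.035 over five seeds. At study scale the recovery claims are
made at the region level: causal regions are selected and their
regression p values separate by orders of magnitude from non-causal ones.

## Pipeline and problem sizes

`run_full_analysis` sequences the stages from a single `RunConfig`
(min_count 3, q 0.05, t statistic, one-tailed, min_sig 100,
total-volume adjustment off/on/both) and writes NIfTI maps, CSV tables
and a JSON manifest sufficient to re-run identically; reruns are
bit-identical. Laterality classification is voxel-based: a lesion with
> 50 % of its voxels in the infratentorial mask is infratentorial;
otherwise all voxels strictly one side of a configurable midline band
(default 0 mm) give that hemisphere, and voxels on both sides give
"multiple".

Simulation-based checks run at: 200 cohorts (n = 93, 32³) for null FDR
control, 5 cohorts of n = 400 for the sensitivity/specificity property,
200 regression replicates (n = 93) for CI coverage, and single fixed-seed
cohorts for the dissociation and end-to-end recoveries. One full
synthetic cohort plus pipeline takes well under a second; the whole suite
runs in a few minutes on one CPU.

## Known limitations

* No permutation-based FWER alternative; BH-FDR only, without dependency
  correction.
* The voxel test is unadjusted (behavior is adjusted instead); covariate
  models at the voxel level are out of scope.
* No image registration or resampling: all volumes must share one grid
  exactly.
* The BM small-sample caveat above; the t test is the default for the
  same reason.
* Whether FDR should run over one- or two-tailed p values is a modeling
  choice; one-tailed is the default and is flagged in every manifest.
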