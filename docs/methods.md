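# Methods

`pimsel` scores preimplantation embryos from DNA methylation profiles and
evaluates embryo-selection strategies retrospectively. This note documents
the statistical model, the parameters that matter, the synthetic-cohort
generator used throughout the test suite, and the numerical choices made
where the design was genuinely open.

## The scoring model

**Whole-genome level and ML-score.** An embryo's whole-genome methylation
level `ML` is the unweighted mean of per-CpG methylation fractions
(methylated reads / total reads) over all sequenced CpGs. Clinical evidence
places the live-birth optimum near `ML = 0.26`; the *ML-score* is the
absolute deviation `|ML − 0.26|`. The optimum is a configuration parameter
(`optimum_ml`, default 0.26) imported from prior clinical work — the
package deliberately does not re-estimate it.

**Logistic calibration.** A binomial GLM (logit link) of live birth
(1 = birth, 0 = failed) on ML-score converts the deviation into an expected
birth probability. Predictions use the inverse logit; standard errors use
the delta method (`se(p) = p(1−p)·se(η)`). For display, the lower band
`p − se` is clipped at 0; predictions themselves always lie in (0, 1). The
reference prediction grid is ML-score 0 to 0.30 in steps of 0.01.

**Patient-level selection statistics.** For a patient with ≥ 2 embryos,
`H = max(ML-score) − min(ML-score)` measures embryo heterogeneity and
`S = ML-score(selected) − min(ML-score)` measures how far the historical
selection sat above the best embryo. With the quality-difference threshold
`t = 0.03` (a configuration default, taken from the calibrated model's
confidence band rather than re-derived — the derivation is not an
algorithm), patients split into *similar* (H ≤ t), *superior* (H > t,
S ≤ t) and *inferior* (H > t, S > t) selection groups. Boundary values sit
on the "no difference" side: only a difference strictly greater than `t`
counts. Group outcome tables are compared with one-sided Fisher exact
tests; maternal-age balance is checked with a plain two-sided t-test (no
age modelling).

**Epimutations.** Promoters are symmetric ±1000 bp windows around the TSS
(strand only locates the TSS). A promoter's methylation level in an embryo
is the unweighted mean beta over its covered CpGs; cells with summed CpG
coverage below 30 reads are treated as missing (the filter is applied per
embryo–promoter cell). Promoters observed in fewer than 10% of samples of
either outcome group are excluded. Against the birth-group baseline
(mean and sample SD over *all* birth embryos, with no leave-one-out —
a birth embryo's own value is part of its baseline):

    AM = |value − mean_birth|        RM = AM / sd_birth

and a call requires `AM > 0.1` and `RM > 3`. A zero-SD baseline with
`AM > 0` yields `RM = +∞`, reducing the call to the absolute criterion
(an `sd_floor` knob can bound the denominator instead). Per-embryo
frequency = calls / covered promoters; per-promoter group frequency =
epimutated samples / covered samples. Differential promoters are tested
per promoter with the two-sided Fisher exact test; "higher in failed"
means positive frequency difference and p < 0.05. No multiple-testing
correction is applied by default; a Benjamini–Hochberg option exists.

**TSS-score classifier.** Feature selection keeps promoters whose
birth-vs-failed difference reaches p < 0.05 in a one-way ANOVA *or* a
two-sided Wilcoxon rank-sum test (union rule; with two groups the ANOVA is
equivalent to an equal-variance t-test). The classifier is scikit-learn's
`GradientBoostingClassifier` with library-default hyperparameters; because
single fits are seed-sensitive at this sample size, an ensemble of
`n_repeats > 10` fits (default 20) with distinct seeds is averaged.
Missing cells are imputed with training-set medians (all-missing features
fall back to 0.5). Cross-validation is repeated stratified 5-fold with
feature selection and imputation recomputed inside every training fold —
the test suite demonstrates that selecting features on the full set first
visibly inflates null AUCs, which is why the leaky variant exists only as
a diagnostic flag.

**Noise-label cleaning.** Clinical labels are noisy (failures can be
maternal rather than embryonic). Each cleaning iteration computes repeated
cross-validated scores `P`, assigns every embryo the noise probability
`N = |R − P|` (R the 0/1 recorded label), and removes the failed-labelled
embryo with maximal N; birth-labelled embryos are never removed; ties break
on the lexicographically smallest embryo id. The loop stops after
`max_removals` removals (default 5 — an early stop against over-filtering)
and records each iteration's cross-validated AUC as a learning curve.

**Combined score and selection.** The final score is the weighted mean
`(1·TSS + 2·GLM-probability)/3` — "linear transformed ML-score" is the
GLM-predicted birth probability, the only linear-model output on a
probability scale commensurate with the TSS-score. The 1:2 weighting is a
configuration knob (the 2:1 reading is selectable). In simulated selection
each eligible test patient (exactly one birth embryo, ≥ 1 failed) has the
top-scoring embryo "selected"; ties break on higher GLM probability, then
lower ML-score, then embryo id. Per patient,
`DI = score(birth) − mean(score(failed))`; a one-sample t-test of the DIs
against zero summarises discriminability (all-zero DIs: t = 0, p = 1;
zero variance with nonzero mean: the limiting p of 0 is reported).

**Train/test split.** Test embryos are all embryos of patients with ≥ 2
transfers whose final transfer produced a live birth (these patients
guarantee one birth embryo and permit retrospective selection); everyone
else trains. The split is patient-disjoint by construction.

**AUC.** Computed with the rank-sum (Mann–Whitney) estimator, ties
contributing ½; cross-checked against scikit-learn in the tests.

## The synthetic-cohort generator

No public embryo-methylome cohort exists at this scale, so the test suite
runs entirely on simulated cohorts (`synthetic_cohort`). The generator
reproduces the structure the pipeline assumes:

* latent whole-genome level `ML = 0.26 + s·|N(0, 0.05)|` with random sign
  `s` — unimodal around the optimum with a tail of large deviations. The
  half-normal is a stand-in (no distributional form is established for
  clinical embryos) and is configurable;
* true outcome `Bernoulli(logit⁻¹(1.5 − 30·|ML − 0.26|))` — birth
  probability ≈ 0.82 at the optimum, ≈ 0.5 at an ML-score of 0.05;
* promoter baselines `Beta(1.3, 3.7)` (mean 0.26, mostly lowly methylated);
  each embryo's promoter level adds its genome-wide deviation and
  `N(0, 0.03)` noise, so the genome-wide mean computed from CpGs tracks the
  latent level;
* a prone subset of promoters (default 10%) carries planted epimutations:
  a ±0.20 methylation shift per prone promoter with probability 0.15 in
  truly failed embryos and 0.02 in birth embryos. Concentrating
  epimutations on a recurrent subset is what creates promoter-level
  (classifier and differential-test) signal; uniformly scattered
  epimutations would be invisible at the promoter level;
* recorded labels flip with probability 0.03 (the truth table records which);
* per-CpG coverage is Poisson (mean 8 reads), methylated counts binomial —
  the simplest model consistent with count-based coverage filtering;
* patients receive 1–4 embryos i.i.d.; one embryo per patient is marked
  "selected" uniformly at random; transfer orders are a random permutation;
  maternal ages are N(33.7, 3.5²) clipped to [25, 43].

What the generator does **not** emulate: read-level bisulfite data,
chromosome structure and genomic covariates of methylation, age-dependent
aneuploidy, correlated (imprinting-like) epimutation blocks, batch effects,
or clinic-level selection policies. Passing tests therefore demonstrate
that the *pipeline machinery* is correct and recovers planted effects under
its own model assumptions — not that the clinical performance figures
transfer to real cohorts.

## Problem sizes used by the test suite and acceptance script

Chosen to exercise every stage at meaningful scale:

* end-to-end runs: 64 patients / 160 embryos, 2000 promoters × 6 CpGs plus
  4000 background CpGs; cleaning with 2 removals and 11-repeat CV in the
  reproducibility check (the smallest legal ensemble; every stage still
  executes), 5 removals in the acceptance script;
* GLM recovery: 50 cohorts of 160 embryos at known coefficients;
* noise-cleaning recovery: 20 replicate strong-signal cohorts (60
  promoters, 50% prone, shift 0.3, failed rate 0.6 vs birth 0.01), 126
  training embryos with 5 injected flips, 94 held-out embryos;
* null controls: 500-promoter cohorts for selection-rate calibration, 20
  replicates; 10 replicates for null cross-validated AUC.

## Known limitations

* The noise-cleaning AUC benefit is direction-tested only; with 5 flips in
  126 embryos the expected held-out improvement is small (≈ +0.01 under the
  planted conditions), far from a guarantee on real data.
* Exact-test p-values are conservative at small counts; the differential
  promoter list is uncorrected by default, mirroring the screening usage.
* The 0.03 quality threshold and 0.26 optimum are imported constants;
  sensitivity to them is not analysed here.
* `GradientBoostingClassifier` defaults are version-dependent; run logs
  record library versions, and determinism is guaranteed only within one
  environment.
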