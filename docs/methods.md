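# Methods

## Mixture model

A bulk sample's methylation beta value at library probe *j* is modelled as
a linear combination of two reference profiles,

    y_j = w_F · fetal_j + w_A · adult_j + ε_j,

where `fetal_j` and `adult_j` are the mean betas of fetal-lineage and
adult-lineage cells at that CpG and `w_F` is the fetal-cell-origin (FCO)
fraction of interest. The weights are estimated per sample by constrained
least squares over the non-missing library probes:

    minimize  Σ_j (y_j − w_F fetal_j − w_A adult_j)²
    subject to  w_F ≥ 0,  w_A ≥ 0,  w_F + w_A ≤ 1.

**Why sum ≤ 1 rather than = 1.** Tumors plausibly contain cell states
matching neither reference profile; the inequality lets the model report
an unexplained remainder 1 − w_F − w_A instead of forcing it into the two
components, and it keeps an FCO of 0 with w_A < 1 representable. This is a
design choice of the package, documented rather than derivable from first
principles.

**Solver.** With only two variables the quadratic program is solved
exactly: the unconstrained normal-equations solution is accepted when it
is feasible; otherwise the optimum lies on one of the three boundary
segments (w_F = 0, w_A = 0, w_F + w_A = 1), each of which is a
one-dimensional least-squares problem clipped to [0, 1]. The candidate
with minimum residual sum of squares wins, ties broken by smaller w_F then
smaller w_A. The method is deterministic, has no iterative tolerance, and
is verified in the test suite against an exhaustive grid search at step
10⁻³ (agreement within 2·10⁻³ on the fetal weight).

**Missingness.** Probes missing in a sample are dropped before the fit
(pairwise deletion, no imputation); at least 2 usable probes with
somewhere-differing profiles are required, otherwise the mixture is
declared unidentifiable. Reported fractions are clipped to [0, 1] after a
10⁻⁸ feasibility check; the external reporting unit is percent with one
decimal.

**Stability.** `stability_probe_dropout` re-estimates w_F with every
k-probe subset removed (k up to 5). Enumeration is exhaustive while
C(L, k) ≤ 10,000; beyond that a seeded random sample of 10,000 subsets is
used, since C(27, 5) = 80,730 is needlessly large for routine checks.

## Quality control

A sample enters the analysis only if at least `min_present` (default 25)
of the library's CpGs (canonically 27) are observed. Library probes absent
from the input platform are retained as all-missing rows so the QC
denominator stays at the library size. Probe identifiers are matched
exactly and case-sensitively; betas of exactly 0 or 1 are legal (clipped
normalized exports produce them).

## Group comparison

Per cohort (the `study` column of the sample sheet), three procedures test
whether FCO differs between tumor and nontumor samples:

1. **Wilcoxon rank-sum** on the raw fractions. For pooled n ≤ 10 without
   ties the null is enumerated exactly over all C(m+n, m) assignments;
   otherwise the normal approximation with midranks, tie correction and
   continuity correction is used (scipy's implementation).
2. **Adjusted OLS**: FCO regressed on group status (coded nontumor = 0,
   tumor = 1, so the coefficient is tumor minus nontumor) plus covariates.
   Requested covariates (default age, gender, race, vital status) are
   screened per cohort: dropped when absent, when more than 50% missing,
   or when they carry a single non-missing level (e.g. gender in an
   all-female cohort), with reasons recorded. Categoricals are
   dummy-coded with the first sorted level as reference; rows are
   complete-case; rank deficiency is a hard error naming the collinear
   columns.
3. **Randomization test**: group labels are permuted uniformly at random
   B times (default 50,000) with covariates staying attached to samples,
   the model is refit and the group t-statistic recorded. The two-sided
   empirical p is #{|t*| ≥ |t_obs|}/B. Two-sidedness is via |t| on the
   symmetric statistic, not tail doubling. With zero exceedances the p is
   reported at the floor 1/B and rendered "<1/B" ("<2E-05" at
   B = 50,000); the plain count/B estimator (no +1 correction) is used
   precisely so that the floor is expressible. Refits use the
   Frisch–Waugh partialled-out form — the nuisance design is
   orthogonalized once by QR and each permutation costs O(n·p) — which the
   tests verify against per-permutation statsmodels refits. An
   `exhaustive` mode enumerates all C(n, n_tumor) distinct labelings for
   small cohorts, giving the exact permutation p. Identical (data, B,
   seed) is bit-reproducible. An absolute tolerance of 10⁻¹² on the
   exceedance comparison absorbs floating-point dust when the observed
   statistic is numerically zero.

Cohorts with fewer than 3 samples in either group, or with no FCO
variation at all (e.g. uniformly zero fractions in both groups, as happens
in prostate-like data), return NA results with a recorded reason instead
of raising.

**Residual diagnostics** provide the numeric inputs for normal-QQ and
spread-location plots: internally studentized residuals
e_i/(s·√(1 − h_ii)) and theoretical normal quantiles at the (i − 0.5)/n
plotting positions. An exact fit (residual scale below 10⁻¹⁰ of the fitted
scale) reports all-zero standardized residuals.

## Sensitivity analyses

- **Correlations** of FCO with age, purity and infiltration percentages:
  Spearman by default (rank-based, robust to the zero-inflation of FCO
  estimates), Pearson selectable; both appear in the standard output
  table. p-values use the t approximation; zero variance yields a flagged
  NA.
- **Purity-adjusted model**: OLS of FCO on purity plus screened
  covariates, sharing the comparison module's OLS core (one code path).
- **IQR screen**: cohorts with zero FCO interquartile range (quartiles by
  linear interpolation, the common default) are excluded from stage and
  subtype analyses — there is no variation to test.
- **Stage association**: linear trend of FCO on stage coded 1–4, with
  sub-stages (IIIa/IIIb) collapsed to the major stage. A linear trend was
  chosen over ANOVA and is labelled as such.
- **Probe extraction** returns tidy long-format betas for requested CpGs
  (absent probes warn, not fail), suitable for external plotting.

## Synthetic cohorts

`simulate_cohort` generates what the pipeline assumes: per-sample true
fractions f_i from group-specific truncated normals on [0, 1]; observed
betas inverse-logit(logit(f_i·fetal_j + (1−f_i)·adult_j) + ε) with
ε ~ N(0, noise_sd), exact 0/1 mixtures nudged by 10⁻⁶ before the logit;
independent per-cell masking; and covariates (age ~ N(62, 13) truncated to
[18, 95] — the scale of large tumor-registry cohorts — gender, race,
vital status, with optional linear effects of age/gender on the true
fraction). Logit-scale noise keeps betas in bounds without clipping
artifacts and is the standard methylation noise model; an additive
clipped-Gaussian alternative sits behind `noise_model="additive"`.

Defaults: 27 probes, mean fetal–adult separation delta = 0.5, 50 samples
per group, tumor fractions ~ TN(0.05, 0.05), nontumor ~ TN(0.20, 0.10)
(nontumor above tumor, the empirically observed direction), noise_sd =
0.05, missing_rate = 0.01. `simulate_reference` jitters per-probe
separations around delta and alternates the methylation direction by probe
parity, so delta = 1 produces strictly alternating 0/1 profiles. One
global seed spawns per-component substreams (library, truth, noise,
missingness, covariates), so each ingredient is individually reproducible.

**What the simulation does not emulate**: array chemistry (type I/II probe
bias, M/U intensities), batch and normalization effects, spatially
correlated missingness, and real biological heterogeneity beyond the
two-profile mixture. Passing tests therefore establish correctness of the
estimator and tests under the model's own assumptions, not performance on
arbitrary real 450K data.

## Problem sizes and numerical choices

The bundled checks run at deliberately modest scale chosen to exercise the
claims without waste: oracle agreement on 100 random 5-probe instances at
grid step 10⁻³; truth recovery at n = 200 with 27 probes; type-I error
calibration over 500 null cohorts of 20+20 samples at B = 1,000;
floor behavior at B = 50,000 with 30 samples per group. The calibration
band [0.03, 0.07] around the nominal 0.05 corresponds to roughly three
binomial standard errors at 500 replicates.

## Known limitations

- Two reference populations only; the design would generalize to K > 2
  profiles but the fetal/adult dichotomy is the use case.
- No confidence intervals on the estimated fractions.
- No multiple-testing correction across cohorts (per-cohort p-values are
  reported as-is).
- Purity and infiltration are consumed as input covariates; their
  estimation is out of scope, as are IDAT parsing and normalization.
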