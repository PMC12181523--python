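# Methods

## Sleep phenotyping

A sleep episode is a continuous device-logged period with per-stage minutes
(light, deep, REM, awake) that tile its wall-clock span exactly; the device
emits only episodes of span ≥ 60 min, and one minute is the time quantum —
sub-minute timestamps are rejected rather than rounded. Timestamps are
naive local time: the target cohorts are single-site and Japan has no DST,
so wall-clock arithmetic cannot silently shift day boundaries.

Episode TST = light + deep + REM (awake excluded). The 24-h grouping rule
is *wake-date*: an episode belongs to the calendar date of its end. This
keeps a 22:00–04:00 nocturnal sleep on the same day as the naps that
follow it; a noon-to-noon window rule is available (`day_rule="noon-noon"`)
for sensitivity analyses. The main episode of a day is the one with
maximal TST (not span — consistent with the TST-centric outcome
definitions; `main_rule="span"` is available); ties break deterministically
to the earliest start. Daytime windows are start ≥ 09:00 and end < 19:00
(strict), morning additionally end ≤ 12:00, afternoon additionally start
≥ 12:00. An episode ending exactly at noon is counted as morning so the
morning/afternoon split is exhaustive at the boundary; an episode
straddling noon is daytime-only. Main episodes are never counted toward
any daytime window even when they fall inside one, and secondary episodes
outside 09:00–19:00 count toward secondary TST but no sub-window.

QC: days with 24-h TST < 120 min are dropped (strict inequality: a 119-min
day is dropped, a 120-min day retained), then participants with < 90
surviving days. Averages are arithmetic means over valid days — days
without any secondary sleep contribute zeros, they are not dropped — and
standardization uses the n−1 denominator.

## Synthetic study generator

The generator's defaults reproduce the target cohort: 77 participants aged
80+, 365 observation days, main-sleep TST 374.04 ± 54.2 min and
secondary-sleep TST 6.1 ± 7.8 min/day across participants, ~87% of
participants ever napping, 4 Olink-style panels × 92 assays with 13
proteins measured on two panels (368 assays, 355 distinct proteins), 1%
per-measurement QC-warning rate, and covariates at the cohort moments
(age 87.6 ± 4.2, 58.4% female, BMI 22.6 ± 3.5, 4968.5 ± 2846.7 daily
steps, cystatin C 1.2 ± 0.3 mg/L, hypertension 37.7%, metabolic disease
10.4%, arrhythmia/heart failure 3.9%).

For truncated covariates (age ≥ 80; BMI, steps, cystatin > 0) the
underlying normal parameters are solved numerically so the *truncated*
distribution has the stated mean and SD — the published numbers are
observed cohort moments, so naive truncation at those moments would bias
the mean (for age, by ≈ +0.34 years).

Sleep is driven by two correlated per-participant latents: one sets the
participant's mean main-sleep TST, the other (correlated at
`main_secondary_corr`, default −0.3, matching the observed inverse
main/secondary relationship) sets nap propensity. The nap latent's normal
quantile is mapped through a zero-inflated gamma calibrated so the
population mean and SD of mean daily secondary TST hit 6.1 and 7.8 min;
the zero mass (1 − napper_fraction) captures participants who never nap,
and the gamma (shape ≈ 0.77) the strong right skew among nappers. Each day
has one nocturnal main episode (wake ≈ 06:30) and, with the participant's
propensity, at most one nap of span 60 + Exp(21) min (capped at 240)
placed post-wake, late morning, or in the afternoon. Stage minutes
partition each span as light/deep/REM/awake ≈ 55/20/15/10% with Dirichlet
jitter (awake capped at 15%); only the non-awake sum matters downstream.
Episode placement is constructed so episodes never overlap and naps end
before the next night's sleep begins.

NPX values are `intercept_g + β_g·z(secondary TST) + Σ_c γ_cg·covariate_c
+ ε`, with ε ~ N(0, 1 NPX) by default, small per-assay covariate loadings
(γ ~ N(0, 0.15)) so that covariate adjustment is consequential and
testable, and β_g = 0 for all but `n_signal_assays` assays (default 10 at
|β| = 0.6 NPX per SD with alternating sign). Effects are planted on the
participant-level average phenotype — the association design is
cross-sectional — and specifically on the phenotype as recomputed from the
generated logs, so pipeline recovery tests measure inference error, not
generator/phenotyper disagreement. Planted gene-set terms receive disjoint
cores of ≥ 3 signal proteins each (distinct biological processes share few
genes) plus random fillers to a default size of 10 genes; decoy terms are
uniform draws from the 355-protein background.

What the generator does *not* emulate: raw accelerometry or the device's
sleep-staging, assay-specific dynamic ranges and LOD censoring, batch or
plate effects, correlated protein modules beyond the shared covariate
loadings, and longitudinal drift. Passing recovery tests therefore show
the pipeline's statistical machinery is correct under the stated
generative model, not that real-data effect sizes will be as clean.

A single run seed fans out to per-stage generators by fixed offsets
(`default_rng([seed, stage])`), so stages rerun in isolation reproduce.

## Association stage

The per-assay model treats NPX as the response and the standardized sleep
outcome as the predictor, adjusted for age, sex, BMI, standardized daily
steps, three binary comorbidities and cystatin C. The LASSO screen
reverses the orientation (sleep as outcome, all assays plus covariates as
predictors) — both orientations are part of the workflow's design.

The coordinate-descent solver minimizes
`(1/2n)‖y − Xb‖² + λ Σ_j w_j|b_j|` with per-coefficient penalty weights
(`w = 0` keeps confounders unpenalized) on a Gram-matrix representation
with active-set sweeps; a numba-compiled kernel is used when available,
with an identical pure-NumPy fallback. Convergence is declared when the
largest scale-weighted coordinate step falls below 1e-8 (1e-6 inside the
screen, where selection is insensitive to tighter optimization). For the
screen, unpenalized covariates are handled by Frisch–Waugh partialling;
during cross-validation the projection is refit on each training fold and
held-out folds are predicted with the joint model, so no information
crosses fold boundaries. The λ grid has 100 log-spaced points from λ_max
down to 0.01·λ_max; the path stops refining once a solution carries more
nonzeros than samples (saturated, non-unique regime). Folds are assigned
by a seeded shuffle; `cv-min` (default) takes the CV-error minimizer,
`cv-1se` the largest λ within one SE. Missing NPX cells are median-imputed
for the screen only; the per-assay OLS fits use available cases, matching
the varying per-assay sample counts after QC exclusion.

Variance moderation follows the scaled-F hierarchical model: with
`e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`, the prior df solves
`ψ′(d₀/2) = var(e) − mean(ψ′(d_g/2))` (Brent inversion of the trigamma)
and `s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`; when the observed spread
does not exceed the sampling floor, d₀ = ∞ and all variances collapse to
s₀² (normal reference distribution). Assays with zero residual variance
are excluded from hyperparameter estimation but still shrunk. A screened
set of size one has no ensemble to borrow from: the ordinary t is reported
with a warning. BH adjustment is the exact step-up
`q_(i) = min_{j≥i} p_(j)·m/j`, applied within each outcome's screened set;
two-sided p-values; significance at q < 0.05. The quadratic sensitivity
model adds the centered square of the standardized outcome and tests that
coefficient's moderated t.

**Post-selection caveat.** Screening and testing use the same data, so
null assays that survive the screen have winner-biased test statistics
and BH within the screened set does not control FDR at its nominal level:
in simulations at the default conditions the empirical FDR among
discoveries is ≈ 0.2 at q < 0.05, while the same inference applied to all
assays without screening is calibrated (empirical FDR ≈ 0.05–0.07), and
under a global null the screen selects (almost) nothing so false
discoveries remain rare. Interpret q-values from the two-step workflow as
ranking scores within the short-list rather than exact FDR guarantees; a
selection-free run (skip the screen, BH over all assays) is the
conservative alternative and is trivially available through the same
per-assay API.

## Enrichment stage

Term tests use the accumulative hypergeometric tail with N = measured
distinct proteins (assays duplicated across panels collapse to one
background entry), K = term ∩ background, n = query size, k = overlap.
Filters: p < 0.01, k ≥ 3, enrichment factor (k/n)/(K/N) > 1.5; terms with
K < 3 cannot pass and are skipped. Similarity between passed terms is
Cohen's kappa on membership indicator vectors over the query genes (the
background universe is available as an option); clustering is
average-linkage (single/complete available) on distance 1 − κ, cut at
distance 0.7 so subtrees with similarity > 0.3 form clusters; the
minimum-p term represents each cluster (ties: larger overlap, then
lexicographic id). Kappa of two degenerate identical memberships is 1 by
convention.

## Numerical and testing choices

Hypergeometric tails come from scipy's implementation and are verified
against exhaustive enumeration for all populations N ≤ 12; BH against a
definitional brute force; the LASSO against the orthonormal-design
soft-threshold closed form and an independent solver on all-penalized
problems; variance moderation against reference values from an
independent implementation of the same hierarchical model, frozen into
the test suite. Stochastic acceptance checks run the full pipeline on
50 simulated cohorts (77 participants, 120 observation days — above the
90-day QC floor — 368 assays, 10 planted effects at |β| = 0.6, noise SD
1): ≥ 8/10 planted assays are recovered at q < 0.05 in well over 80% of
seeds; the global-null and quadratic-term rejection rates sit at their
nominal levels; planted terms pass the enrichment filters and represent
their clusters in ≥ 90% of cases. The empirical-FDR check on the two-step
workflow fails by design of the workflow itself (see the post-selection
caveat above); it is asserted at the nominal level regardless, and its
failure is the honest, documented outcome.

## Known limitations

- The two-step screen-then-test design is reported as specified but is
  not a valid post-selection inference procedure (above).
- Day-level (longitudinal) variation is summarized away before modeling;
  mixed-effects extensions are out of scope.
- The generator's QC-warning process is independent per measurement; real
  Olink QC failures cluster by sample and plate.
- Parsing targets the package's own delimited dialects, not vendor-native
  exports.
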