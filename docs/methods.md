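# Methods

## The model

Every trait is analyzed under the nested linear mixed model

    y_ijkl = mu + block_l + b_i + f_ij + e_ijkl

where `b_i ~ N(0, v_pop)` is the effect of source population i,
`f_ij ~ N(0, v_fam)` the effect of full-sib family j nested in population i,
and `e_ijkl ~ N(0, v_res)` the residual. Block is a fixed effect (plants
were randomized into contiguous spatial blocks in the garden); urbanization
metrics, subtransect membership and their interaction enter as additional
fixed effects in the cline and corridor analyses.

Because families are full sibs, total genetic variance is estimated as
`2·v_fam` (full sibs share half the additive variance plus dominance and
maternal components; the factor 2 is the conventional full-sib broad-sense
scaling). The derived statistics are

    H2   = 2 v_fam / (v_fam + v_pop + v_res)
    Q_ST = v_pop / (v_pop + 2 (2 v_fam))
    CV_G = sqrt(2 v_fam) / trait mean
    PVE  = v / (v + v_res)          (per random effect)

`H2` can exceed 1 when `2·v_fam` exceeds the total phenotypic variance; it
is reported as computed, never capped, so that summaries remain comparable
across traits. `Q_ST` equals 1 when all genetic variance lies among
populations and 0 when none does; with both variances zero it is undefined
and propagated as not-available rather than silently zero. `CV_G` uses the
mean of the analyzed (possibly transformed) response by default; a raw-scale
mean can be supplied via the stored `trait_mean`.

## REML evaluation and optimization

The marginal covariance is block diagonal by population; each block is
`sigma² (I + U Delta U')` with U the family indicators plus a column of
ones and `Delta = diag(gamma_fam, ..., gamma_pop)` the variance *ratios*
relative to the residual. The restricted log-likelihood is evaluated with
the Woodbury identity on the (families+1)-dimensional core matrices,
batched across populations, with `sigma²` profiled out in closed form.
One evaluation therefore costs a few small batched matrix operations
regardless of the number of plants, and the analytic gradient with respect
to the two ratios reuses the same factorization.

Maximization runs L-BFGS-B on the log ratios. Because boundary estimates
(a variance component at exactly 0) are routine in real common-garden
data, every fit also evaluates the boundary candidates explicitly — the
family-free edge, the population-free edge, and the corner — each with its
own one-dimensional search, and keeps the best of all candidates. A fitted
ratio below 1e-8 is reported as a boundary zero and flagged. If the
interior search fails to converge it is restarted from jittered points (up
to five times) and polished with Nelder–Mead; a fit that still fails is
returned with `converged=False` rather than raising. The profiled scale is
floored at 1e-12 so a constant response collapses cleanly to the
zero-variance corner.

`reml_objective` exposes the unprofiled restricted log-likelihood at any
candidate `(v_pop, v_fam, v_res)` via the identity
`ll(v) = ll_profiled(gamma) − dof/2·[log(v_res/sigma2_hat) +
sigma2_hat/v_res − 1]`, so the optimizer can be audited against grids and
perturbations.

## One-sided tests of variance components

The LRT statistic for a component is twice the difference of restricted
log-likelihoods between the full fit and the fit with that component
removed, floored at zero (the full candidate set contains the reduced
model, so the difference is nonnegative by construction). The χ²₁ upper
tail is halved because the alternative is one-sided; a statistic of 0
reports p = 0.5. This is the standard approximation to the boundary
mixture ½χ²₀ + ½χ²₁.

The parametric bootstrap simulates responses from the fitted reduced model
(Gaussian random effects and residuals at the reduced REML estimates),
refits full and reduced models on each simulated response, and reports
`p = (1 + #{sim ≥ obs}) / (1 + n_sim)`. The +1 correction keeps p strictly
positive. The bootstrap p is not halved by default — the simulated null
distribution already respects the boundary — but a `halve` flag exposes
the alternative convention. Bootstrap refit failures are excluded with a
warning; more than 10% failures raises an unreliable-result error. Within
bootstrap refits the optimizer runs with relaxed tolerances and a warm
start from the observed fit; the observed statistic itself always uses the
strict settings.

A note on calibration checks: because roughly half the null LRT statistics
are exactly 0, the reported bootstrap p has a point mass at 1 and is
*sub*-uniform (conservative), as it should be. The calibration study
therefore checks uniformity of the exact randomized p-value
`(#{sim > obs} + U·(1 + #{sim = obs}))/(1 + n_sim)`, which is Uniform(0,1)
under the null for a discrete statistic, while the rejection rate is
computed from the reported, conservative p.

## Cline and corridor models

Fixed-effect χ² tests are maximum-likelihood likelihood-ratio drops rather
than Wald statistics: the model is refitted under ML with and without the
term. Type II drops each main effect from the no-interaction model; type
III uses sum-to-zero contrasts and drops each term, mains included, from
the full model. Numeric covariates are centered so that main effects (and
type III tests in the presence of an interaction) are evaluated at the
covariate mean rather than at the gradient's origin — without centering,
the subtransect main effect would be tested at distance 0 km and its
type-I error inflates badly whenever an interaction is retained.

The corridor analysis restricts to the two urban subtransects, fits full
(metric + subtransect + interaction) and reduced models, and selects by
AIC with `k` = fixed-effect count + 3 variance parameters; ties go to the
reduced model. Type III tests are used only when the selected model
contains the interaction with p ≤ 0.1; otherwise type II tests on the
reduced model are reported. Marginal R² is the variance of the
fixed-effect predictions over fixed + population + family + residual
variance. The Benjamini–Hochberg step-up adjustment is applied across
traits within one analysis table.

## Multivariate test

Population BLUPs (conditional means of the population effects at the REML
estimates, computed from the same Woodbury pieces) form a populations ×
traits response matrix. Each trait contributes the Gaussian
likelihood-ratio statistic `n·log(RSS0/RSS1)` of regressing its column on
the urbanization metric; the global statistic is the sum over traits, and
the null distribution is generated by permuting the metric across
populations with one permutation shared by all columns, preserving the
inter-trait correlation of the rows. Population-level (not family-level)
BLUPs are used because the hypothesis concerns divergence among
populations; a `level="family"` flag exposes the alternative. Traits with
zero population variance contribute all-zero columns (retained, flagged);
populations missing from a trait's fit are imputed at the BLUP prior mean
of 0 and counted.

## The synthetic-data generator

The generator emulates the study design, not the ecology: 52 populations
by default (19 urban-corridor, 17 urban non-corridor, 16 rural) along a
67 km gradient, ~4 families per population and family sizes drawn from a
truncated-at-1 Poisson with mean 4.55 (a stand-in — the source design
reports only the mean and range of family sizes), four blocks with
near-equal membership. The urbanization score is a decreasing affine
function of distance plus Gaussian noise calibrated by fixed-point
iteration so the squared metric correlation approximates the configured
0.709, clipped to [−3.56, 3.37]; urban subtransects occupy the near half
of the gradient and the rural subtransect the far half.

Traits are generated from the nested linear predictor (grand mean, block
offsets fixed per truth, optional distance/score slopes, a corridor offset
and a corridor-by-distance interaction slope) plus Gaussian population,
family and residual deviates. Binary traits default to a latent-Gaussian
threshold at 0, which keeps variance components interpretable on one
scale; a logit link is available. Counts are log-link Poisson on the
latent predictor (a positive `v_residual` adds log-normal
overdispersion). Zero-inflated traits combine an independent occurrence
layer with a log-normal (or shifted-Poisson) positive part, matching the
hurdle decomposition used at analysis time. An optional missing-at-random
mask models the varying per-trait sample sizes of real gardens.

What passing tests on these data do **not** show: robustness to
non-Gaussian residuals beyond the implemented links, spatial correlation
within blocks, genotype-by-year variation (no repeated measures), or
non-random missingness. Variance components for non-Gaussian traits are
extracted from Gaussian fits of the (possibly transformed) response — the
same pragmatic choice the motivating analysis made — so latent-scale and
observed-scale heritabilities are conflated for binary/count traits.

## Study sizes used by the validation suite

The replication studies in `qgarden.studies` use a balanced 20 populations
× 5 families × 4 plants design for estimator checks and test calibration
(200 replicates; bootstrap n_sim = 99), a 40-population three-subtransect
design for cline studies, 36 urban populations (18 + 18) for corridor
studies, and 20 traits × 40 populations for the multivariate studies with
199 permutations. The cline power study uses a slope of one population-SD
per score unit; the corridor power study one total-trait-SD per
metric-SD (~0.12 per km). These sizes mirror the motivating study's scale
while keeping a full validation run to minutes on one CPU.

## Known limitations

- No crossed random effects, random slopes, or heteroscedastic residuals;
  no generalized (binomial/Poisson-likelihood) mixed model fitting.
- The halved-χ² test is an asymptotic approximation; at very small numbers
  of populations or families the parametric bootstrap is the safer choice.
- AIC counts variance parameters even when estimated on the boundary.
- The binomial meta-test across traits assumes independent trials;
  correlated traits inflate its type-I error, and reports carry that
  caveat rather than a correction.
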