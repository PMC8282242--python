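# Methods

## Model

An epigenetic clock is a sparse linear model on CpG beta values
(fractions methylated, in [0, 1]) with an invertible transform of
chronological age as the dependent variable:

    F(age_i) = b0 + x_i' b,     DNAm age_i = F^-1(b0 + x_i' b)

fit by elastic-net penalized least squares,

    min_{b0,b} (1/(2n)) sum_i (y_i - b0 - x_i'b)^2
               + lambda * ( alpha*||b||_1 + (1-alpha)/2 * ||b||_2^2 ),

with the intercept unpenalized and mixing parameter alpha = 0.5 by default
(midway between ridge and lasso; not tuned). The penalty lambda is chosen by
internal 10-fold cross-validation at the minimum mean out-of-fold squared
error ("lambda.min"); the one-standard-error alternative is deliberately not
the default because the clock's purpose is prediction accuracy.

### Solver

The solver is cyclic coordinate descent on internally standardized
predictors (mean 0, population 1/n standard deviation 1), with the
closed-form update

    b_j <- S(b_j + x_j'r/n, lambda*alpha) / (1 + lambda*(1-alpha)),

warm starts along a descending 100-point log-uniform lambda path from
lambda_max = max_j |x_j'y_c|/(n*alpha) (the smallest penalty that zeroes
every coefficient) down to lambda_max * min_ratio (0.01 when n < p, 0.0001
otherwise), and an active-set strategy (iterate on the nonzero set, confirm
with a full sweep). Convergence: max absolute coefficient change < 1e-7,
cap 1e5 sweeps. Returned coefficients are back-transformed to the original
predictor scale. Zero-variance predictors are excluded with coefficient 0;
non-finite inputs are rejected.

Correctness is established against independent oracles rather than another
elastic-net library: an L-BFGS-B minimization of the identical objective in
the smooth split positive/negative-part formulation (objective agreement to
1e-6 on random n=20, p=50 instances across alpha in {0.25, 0.5, 1}), the
exact soft-threshold closed form on orthonormal designs, and the ridge
linear-algebra closed form (both to 1e-8). One deliberate difference from
the widely used R implementation: that library internally standardizes the
response, which implicitly divides the effective L2 penalty by sd(y); we
keep the objective exactly as written above, so coefficients at a given
(lambda, alpha) coincide with that library only when sd(y) = 1. Objective
scaling by 1/(2n) keeps lambda comparable across sample sizes.

### Age transforms

- identity: y = age (used for single-taxon blood clocks).
- log-linear: y = log((age+1)/(adult+1)) for age <= adult, else
  (age-adult)/(adult+1). Continuous and once-differentiable at the species
  "adult age" (both branches have slope 1/(adult+1)); compresses juvenile
  ages where methylation changes fastest. Default adult ages: 20 (human),
  15 (elephants) — configurable; no analysis asserts these values.
- relative: y = age / maxLifespan, in [0, 1]. The maximum lifespan is a
  mathematical parameter, not a biological claim; defaults 85 (elephants)
  and 122 (human) are configuration entries. Values above 1 (an animal
  older than the configured maximum) are flagged, not errors.

All inverses are exact closed forms; a negative inverse age (possible only
by floating-point noise or an extreme linear predictor) clamps to 0 with a
warning. Round-trip error is below 1e-10 over a dense [0, 120]-year grid.

### Cross-validation

LOOCV refits the entire procedure — internal penalty selection included —
once per held-out sample; LOFO10 uses 10 folds stratified so each fold
carries every species in proportion (per-stratum fold sizes differ by at
most 1, via seeded shuffle and round-robin deal with a random rotation).
Nothing computed from a held-out sample (standardization, lambda grid,
penalty choice, coefficients) enters its own prediction. Metrics — Pearson
R and median absolute error — are always computed in years after the
inverse transform, never on the transformed scale. Fold seeds are spawned
from the root seed, so reruns are bit-for-bit identical.

Epigenetic age acceleration defaults to the raw difference (DNAm age minus
chronological age); the residual from regressing DNAm age on age is offered
as an option (mean 0, uncorrelated with age by construction).

## EWAS

The age screen is the classical marginal Pearson-correlation test per
probe: t = r*sqrt(n-2)/sqrt(1-r^2), two-sided Student-t p (identical to
the univariate-regression p), signed z = sign(r)*Phi^-1(1-p/2). p values
are floored at the smallest positive double and z capped accordingly so
ordering by |z| stays well defined. Pairwise-complete observations per
probe; zero-variance probes yield r = NaN, p = 1, z = 0 and stay in the
output so probe sets align across cohorts. Cohorts combine by Stouffer's
method with w_i = sqrt(n_i) (unweighted switchable); no genomic-control or
inflation correction is applied.

Top-CpG selection keeps rows with p below the threshold (default 1e-5),
ranks by |z| within each direction with lexicographic probe-id tie-breaks
(so the output is invariant to input order), and truncates at 500 per
direction. Cross-cohort concordance labels a probe "shared" when both
cohorts pass the threshold with the same z sign, "divergent" when both pass
with opposite signs; probes present in only one cohort are excluded and
counted. The sex screen fits ordinary least squares of beta on sex + age
per probe (df = n-3) and reports the sex term; the interaction screen adds
sex*age (df = n-4) and reports the interaction term. Both run on beta
values by default (an M-value option exists) — betas keep effect sizes in
methylation-fraction units at the cost of mild heteroscedasticity, which
the calibration tests show does not inflate type-I error at these settings.

## Random-forest integrity check

Species and sex predictors are scikit-learn random forests (500 trees,
sqrt(p) features per split, bootstrap resampling). The module's own
contract is the out-of-bag protocol: each sample is scored only by trees
whose bootstrap excluded it, and samples with no out-of-bag vote are
removed from the error denominator. On cleanly separable synthetic species
data the OOB error is 0; this is a plate-map sanity check, not a claim that
methylation is a practical sexing method.

## Synthetic data generator

For sample i and probe j:

    logit(mu_ij) = baseline_j + slope_j*g_j(age_i) + sex_delta_j*1[female]
                   + species_delta_j*1[non-reference species] + eps_ij

with eps ~ N(0, noise_sd) and beta = expit(.) clipped to [0.001, 0.999].
g_j is age/max_age or log(age+1)/log(max_age+1) (half of age probes each),
both monotone. Baselines are N(-2, 1) on CpG-island probes and N(1, 1)
elsewhere, mimicking unmethylated islands against a methylated genome.
Age-probe slope signs are positive with probability `cgi_hyper_bias`
(default 0.8) at CGI/promoter probes and with probability
1 - cgi_hyper_bias elsewhere, reproducing promoter/island hypermethylation
against a genome-wide hypomethylation majority. Sex probes sit on a single
"X_like" scaffold; species probes carry a fixed-magnitude random-sign
offset.

The `clocklike` preset fixes the study conditions used throughout testing:
83 + 57 samples of two elephant species with ages 2.36-73.6 and 1.20-48.5
years, 2,000 probes with 200 age-informative ones, age_effect_sd 1.5 and
noise_sd 0.4 logit units, female fraction 0.79 (zoo herds are
female-dominated). The `null` preset (60 samples, 500 probes, all effects
zero) supplies pure noise for leakage and calibration checks; 500 probes is
a deliberate compromise — large enough that penalty selection faces a real
multiplicity burden, small enough that a 20-replicate LOOCV study runs in
minutes. Ages are uniform within range by default (simpler power
structure); a zoo-skewed mid-life mixture is available.

What the generator does **not** emulate: probe-level SNP confounding,
batch/chip effects, spatially correlated probes, non-monotone
trajectories, and the heavy age skew of real zoo cohorts. Passing recovery
tests therefore demonstrates the pipeline's statistical machinery, not
field performance on real arrays.

## Numerical and design notes

- lambda_max is inflated by a relative 1e-9 so summation-order floating-
  point noise cannot activate a coefficient at the top of the path.
- Multi-species clocks place all species in one design matrix with no
  species indicator: one formula serves every species.
- Missing betas are representable (NaN / "NA") but modelling steps reject
  them unless per-probe mean imputation within the training set is
  explicitly enabled.
- Matrix orientation is fixed (rows = probes); the reader transposes only
  on an explicit flag, never by shape heuristics.
- All randomness flows from one root seed through named substreams
  (simulation, folds, forests), all below 2^31.

## Known limitations

- **Null-data LOOCV correlations are biased negative.** On pure-noise data
  the selected model is nearly empty, so each leave-one-out prediction is
  approximately the training mean of the other samples — exactly
  anti-correlated with the held-out age — plus a self-influence term
  (dropping sample i shifts every selected coefficient away from sample
  i's own deviation). At n = 60 the LOOCV R on null data is typically
  -0.2 to -0.8 rather than 0, for this package and for the standard R
  elastic-net implementation alike. Leakage, by contrast, would push R
  positive; the leakage tests therefore bound R from above.
- Sex and interaction screens assume a linear age trend within sex.
- The solver handles dense matrices only, single-threaded; a full LOOCV at
  140 samples x 2,000 probes takes a few minutes on one core.
- Clock accuracy numbers quoted anywhere in this repository are properties
  of the synthetic presets, not of any real elephant dataset.
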