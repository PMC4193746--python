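# Methods

## Model and assumptions

The data are per-variant summary associations: for each of J genetic
variants, regression coefficients (with standard errors) on each of K
continuous risk factors, scaled per 1 SD of the risk factor, and a log odds
ratio (with SE) for a binary outcome.  The model treats the observed
coefficients as multivariate-normal draws about latent true associations
ξ, with the outcome's true association constrained to the causal
combination Σ_v β_v ξ_vj.  The β_v are the targets: direct causal log odds
ratios per SD of each risk factor, holding the other modelled risk factors
fixed.

Validity rests on the usual instrumental-variable conditions extended to
several risk factors: every variant's association with the outcome is
mediated entirely by the K modelled risk factors, and no variant is
associated with confounders.  Variants may be associated with any subset
of the risk factors.  Violations (pleiotropy) show up as excess
heterogeneity (below); they bias the estimates if unbalanced.

### Covariance structure

Within one variant, the K+1 coefficient errors are correlated with
correlation matrix **P** (entries ρ_LH, ρ_LT, ρ_LY, ... for the lipid
case).  These correlations are not published for consortium data; the
default values (−0.1, 0.2, 0.1, −0.1, −0.1, 0.1) are phenotypic
correlations of the lipid fractions and log disease risk, which stand in
for the coefficient-error correlations when exposure and outcome samples
overlap.  Because they are a guess, `sensitivity_scan` refits the model
with all off-diagonals scaled by 2, 1.5, 1, 0.5, 0, −0.5 and −1; on data
of the lipid analysis's scale the estimates move by well under 0.01 on the
log-OR scale across the whole range.

Across variants, coefficients are correlated through linkage
disequilibrium.  The joint covariance is taken as the separable form

    Cov(coef_vj, coef_wk) = ld_jk · P_vw · sigma_vj · sigma_wk.

Only the two marginal structures are identified by the available inputs
(the within-variant blocks and the pure-LD cross-correlation of one
variable); the separable product is the unique covariance consistent with
both, and it makes the likelihood factorize over LD blocks (connected
components of the nonzero-LD graph), so evaluation costs O(Σ b³) over
block sizes b rather than O((J(K+1))³).  Supplied LD values are treated as
signed correlations of allele counts.

Numerical guard: if a block's correlation matrix has an eigenvalue below
1e-8 (possible with inconsistent user-supplied LD), its off-diagonals are
shrunk toward zero by the smallest factor restoring 1e-8.  With realistic
LD (|r| < 0.25 in the lipid data) this path is never taken.

## Fitting

Priors are independent N(0, 1000²) on every unknown (all β and all ξ) —
vague enough that the posterior is numerically the likelihood, used purely
as a computational device, not a subjective analysis.  Uniform box priors
(e.g. ±3 or ±2) are available; on well-identified data they give results
identical to the stated precision, and the package enforces the bounds
exactly (rejection sampling from the truncated conditionals).

The sampler is a blocked Gibbs scheme exploiting that the model is
conditionally linear-Gaussian in both directions:

* ξ | β, data — multivariate normal per LD block (the block design matrix
  is I_m ⊗ [I_K; β']), assembled by broadcasting precomputed slices of each
  block's precision matrix;
* β | ξ, data — a K-dimensional multivariate normal.

Both conditionals are sampled exactly, so there is no step-size tuning, no
rejection (outside the uniform-prior bounds check), and warm-up is short.
All chains advance together through batched linear algebra, and the entire
random stream derives from one seed: identical settings reproduce results
bit for bit.  Defaults are 4 chains × 25,000 retained draws after 2,000
warm-up sweeps — far beyond what the fast-mixing conditionals need, cheap
at this model size; the replicate studies in the test-suite use 2 chains ×
500–2,000 draws, which keeps Monte-Carlo error well below the reported SEs.

Summaries per risk factor: posterior mean ("estimate"), posterior SD
("SE"), equal-tailed 95% credible interval, and a two-sided p-value equal
to twice the posterior mass on the opposite side of zero from the mean,
floored at 2/n_draws (reported as "< 2/n", never 0).  Convergence is
monitored by split-chain R-hat (threshold 1.01) and effective sample size
(arviz); failures attach explicit warnings.  A posterior SD comparable to
the prior scale flags non-identifiability (e.g. J < K).

`fit_wls_oracle` provides the closed-form limit — inverse-variance
weighted least squares of Y on the X columns with weights 1/σ_Y², no
intercept — exact when exposure SEs are negligible and variants
independent.  It validates the sampler (agreement within Monte-Carlo
error when SE_X is scaled by 1e-4) and supplies starting values.

## Heterogeneity test and pruning

If the model holds, outcome associations should match the fitted causal
combination up to sampling error.  The test compares the restricted model
against an alternative with a free outcome mean η_j per variant, both
evaluated at posterior-mean point estimates (not profiled maxima — a
deliberate convention; the point-estimate version is what the statistic's
published usage evaluates, and a profiled variant would only be smaller).
The restricted point estimates are the MCMC posterior means; the
unrestricted model is linear-Gaussian, so its posterior mean is computed
in closed form.  The statistic is 2(ℓ_H1 − ℓ_H0), referred to χ² with
J_active − K degrees of freedom; tiny negative values from round-off are
clamped at zero, anything below −1e-6 raises.

The far tail matters (published statistics reach p ≈ 8×10⁻¹⁹): the
survival function is computed via the regularized incomplete gamma
function, accurate to below 10⁻³⁰⁰.

Block decomposition: the statistic splits exactly into per-LD-block
contributions.  Each block is referred to χ²(block size): the K estimated
causal parameters are attributed to the global test only, since no single
block "owns" them; the alternative (subtracting a share of K per block) is
not used.  Pruning at a percentile (98th/95th/90th) removes every variant
of every block whose contribution exceeds that percentile of its χ² —
whole blocks, because contributions are only defined per block.  Pruning
is a single pass; refitting after pruning is the caller's explicit step,
so the sequence of analyses stays auditable.  Applying several percentiles
to the same initial fit yields nested pruned sets.

## Scores and design calculations

The lipid score s_j = Σ_v β̂_v X_vj is each variant's expected outcome
association under the fitted model; plotting observed Y_j against s_j
shows pleiotropy as deviation from the identity line through the origin.
Scores are sign-equivariant under risk-allele re-orientation (which flips
Y, all X, and the LD signs of flipped variants, leaving all SEs and
magnitudes unchanged).

Variance explained by a single variant defaults to f(1−f)β² for effect β
(in SD units) at frequency f — the convention under which the standard
HDL-c worked example (β = 0.29 SD, f = 2.6% → R² = 0.002) reproduces; it
corresponds to a single-dose (carrier-indicator) coding.  The additive
diploid convention 2f(1−f)β² is available via `convention="additive"`
(giving 0.004 for the same inputs); which of the two the worked example's
source intended is not stated, so the reproducing convention is the
default and both are exposed.

Power for a case-control MR design uses the standard normal
approximation: with N = cases + controls, case fraction φ, and instruments
explaining R² of the risk factor, the test statistic for log odds ratio
ln(OR) per SD is ~N(|ln OR|·√(N·R²·φ(1−φ)), 1), giving two-sided power
Φ(z − z_{1−α/2}) + Φ(−z − z_{1−α/2}).  It is symmetric in OR ↔ 1/OR and
returns α when R² = 0 (with a warning).

## Standard errors from p-values

Published tables often give p-values instead of SEs.  These are inverted
assuming a two-sided normal Wald test: SE = |β| / Φ⁻¹(1 − p/2) — the GWAS
convention.  Two edge rules: p exactly 1 (β = 0; the SE is unidentified)
falls back to the mean SE of the same variable across the other variants;
p-values below the normalized double-precision floor (~2×10⁻³⁰⁸, possibly
supplied as decimal strings) are handled by evaluating the normal quantile
in extended precision (mpmath) at a working precision scaled to the
p-value's magnitude, so no manual high-precision step is needed.

## Synthetic data generator

`generate_dataset` emulates the generating assumptions of the model at
consortium scale.  Defaults: J = 185 variants, K = 3 risk factors, true
β = (0.4, −0.1, 0.3) (the magnitude of the published multivariable lipid
estimates), exposure sample 188,578, outcome sample 22,233 cases / 64,762
controls, LD below 0.25.  Per variant, an allele frequency f ~ U(0.05,
0.5) sets the information content: SEs follow large-sample scaling
1/√(n·2f(1−f)) for exposures and 1/√(N·φ(1−φ)·2f(1−f)) for the outcome
log-OR, which lands on the magnitudes of published coefficient tables
(≈0.004 and ≈0.015).  True associations ξ are zero with probability 0.3
per (variant, factor) — not every variant associates with every risk
factor — otherwise N(0, 0.05²), i.e. strong instruments typical of
genome-wide-significant loci.  LD blocks are AR(1)-structured with a
per-block correlation drawn below `max_ld` (positive definite by
construction).  Pleiotropy is planted as outcome-mean offsets of
`pleiotropy_scale` outcome SEs in a random fraction of variants,
sign-balanced by default.  Observed coefficients are drawn through the
same separable covariance the likelihood assumes.

What it does not emulate: allele-frequency-dependent effect sizes,
winner's-curse selection of variants, sample overlap beyond the constant
**P**, non-normal coefficient errors, and real LD topology (blocks are
small and synthetic).  Passing tests therefore demonstrate correctness of
the method under its own assumptions and its operating characteristics
(bias, coverage, type-I error, pruning sensitivity) at realistic
signal-to-noise — not robustness to the ways real GWAS data depart from
the model.

## Problem sizes and numerical choices in the test suite

Replicate studies use reduced but statistically adequate sizes, chosen so
Monte-Carlo error stays well inside the tested tolerances: parameter
recovery uses 200 replicates of J = 150 with 2 chains × 700 draws;
heterogeneity calibration 500 replicates of J = 50 with 2 × 500 draws;
planted-pleiotropy detection 100 replicates (500 planted variants).
Fixed seeds make every test deterministic.  Equal-tailed intervals use
empirical quantiles; the WLS oracle inverts normal equations guarded by an
SVD rank check that names collinear factors.

## Known limitations

* Estimates are direct effects conditional on the modelled risk factors;
  they do not include pathways through unmodelled or mediating factors.
* The within-variant correlation matrix **P** is an input, not estimated;
  the sensitivity scan is the mitigation.
* The heterogeneity statistic is evaluated at posterior means, so with
  very short chains Monte-Carlo noise inflates it slightly; the default
  chain lengths make this negligible.
* Exclusion lists and LD matrices are taken at face value: no allele
  harmonization against a reference panel is attempted, and allele labels
  are carried as metadata only.
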