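# Methods

`latgen` implements a latent-variable genetic association analysis for
X-linked SNPs and longitudinal binary-item phenotypes, together with the
synthetic-data machinery needed to exercise it end to end. This note
documents the statistical models, the numerical choices, and what the
synthetic generator does and does not emulate.

## Measurement model

Binary items are modeled under the liability-threshold convention: item
*i* is endorsed when a latent normal liability exceeds a threshold,

    y_i = 1  iff  λ_i η + ε_i > τ_i,     ε_i ~ N(0, θ_i).

All fitting uses the *theta parameterization*: residual variances θ_i are
fixed to 1 (freed only where cross-wave constraints make them estimable),
so loadings and thresholds are raw probit-scale coefficients and the
standardized solution is derived afterwards from the implied liability
variances. Genotypes enter the same way: male X-linked dosages are binary
indicators (one threshold), female dosages three-category ordinal
indicators (two thresholds), and the latent genetic factor G is the common
factor of the three SNP liabilities with its variance fixed to 1.

## First-stage statistics

The data enter every model through two-stage estimates:

1. thresholds from the univariate margins, τ_c = Φ⁻¹(cumulative
   proportion);
2. each pairwise tetrachoric/polychoric correlation by 1-D maximization of
   the bivariate-normal likelihood of the contingency table with the
   thresholds held fixed.

Bivariate-normal rectangle probabilities are computed from Owen's T
function (absolute accuracy ≈ 1e-14); with all-binary data the full set of
pairwise correlations is solved simultaneously by a vectorized bisection
on the ML score (46 halvings of [−0.999, 0.999], so the root is exact to
well below estimation error). Estimates are clipped to ±0.999 and flagged
when they reach the boundary (e.g. a duplicated column or an empty cell).

The sampling covariance Γ of the full statistics vector is assembled from
the influence functions of the two-stage estimator (threshold influence
(1{x≤c} − F_c)/φ(τ_c); correlation influence with the threshold-propagation
correction), evaluated on complete cases. With missing data the point
estimates use pairwise deletion — the analytic-sample rule keeps
participants with one non-missing item per wave, so listwise deletion
would discard usable information — and Γ is a complete-case (MCAR)
approximation; below 100 complete rows the code falls back to a diagonal
Γ from per-pair observed information.

Numeric covariates (the single-SNP dosage analysis and the extreme-group
indicator) enter on the observed scale as Pearson correlations; the model
then attenuates its implied liability-scale correlation for such pairs by
φ(τ̃)/√(F(1−F)) per binary side, the exact moment relation between a
thresholded liability and its observed 0/1 score.

## DWLS estimation and test statistics

A model is a declarative pattern (loadings, structural regressions among
latents, latent (co)variances and means, residual variances/covariances,
thresholds; any entry free, fixed, or tied to an equality group). Fitting
minimizes

    F(θ) = Σ_k w_k (s_k − σ_k(θ))²,   w_k = 1 / avar(s_k),

i.e. diagonally weighted least squares over thresholds and correlations
jointly. Because implied thresholds are linear in the threshold
parameters, those are profiled out in closed form at every evaluation;
only the nonlinear parameters are iterated (L-BFGS-B, multi-start with a
Hessian-memory restart, data-driven starting values from indicator triads
and attenuation-corrected correlations). Reflection indeterminacy is
resolved after fitting by flipping any group of latents — joined by shared
loading parameters or fixed structural paths — whose summed loadings are
negative; the flip is an exact model-equivalent transformation.

The reported test statistic is scaled-and-shifted (mean-and-variance
adjusted): with U = W − WJ(J'WJ)⁻¹J'W and C the sampling covariance of the
statistics,

    T* = a·F_min + b,  a = √(df / tr((UC)²)),  b = df − a·tr(UC),

which has approximately the mean and variance of χ²_df. Nested models are
compared with the analogous scaled difference test built from U_r − U_f.
Exact numerical equivalence with proprietary weighted-least-squares
implementations is not claimed; the adjustment reproduces its nominal
moments on the generator (the test suite checks mean(ΔT) ≈ Δdf under true
constraints). Parameter standard errors use the sandwich
(J'WJ)⁻¹J'W C WJ(J'WJ)⁻¹; standardized coefficients and their delta-method
SEs follow from the implied moments. Heywood behaviour is prevented by a
1e-4 lower bound on variance parameters and flagged when a variance lands
on it.

Fit indices: RMSEA = √(max(0, (χ²−df)/(df(n−1)))), CFI and TLI against the
zero-correlation baseline fitted on the same statistics. TLI is reported
untruncated with a flag when it exceeds 1.

Known limitation: at n ≈ 1200 the sandwich/delta-method standard error of
the standardized change-score coefficient runs ~8% below its Monte Carlo
SD (CI coverage ≈ 0.91–0.93 rather than 0.95), the familiar mild
finite-sample anticonservatism of two-stage categorical least squares;
coverage for cross-sectional coefficients and for raw-scale Wald
intervals sits at ≈ 0.93–0.95. No ad hoc inflation factor is applied.

## Invariance ladder

Configural, strong and strict models follow the conventional categorical
scheme: configural fixes all residual variances at 1 and frees loadings
and thresholds per wave; strong equates loadings and thresholds across
waves jointly (they are not separable for binary ratings) and frees the
wave-2 factor variances, factor means and item residual variances that the
constraints make estimable; strict fixes the wave-2 residual variances
back to 1. Every repeated item carries a free cross-wave residual
covariance. Decisions use the change-in-index rules (ΔRMSEA < 0.015,
ΔCFI < 0.01, ΔTLI < 0.01) with *conventionally truncated* indices — near a
perfectly fitting model the untruncated TLI exceeds 1 by a noise-dominated
amount and its raw change would reject spuriously. Scaled χ²-difference
tests are reported but not decisive: with n ≈ 1200 they reject deviations
too small to matter, which is exactly why the index rules exist. The
ladder is fitted with warm starts (each step initialized from the pooled
estimates of the previous step).

Two behaviours worth knowing. First, the strong model can absorb part of
a uniform wave-2 threshold shift into its freed factor mean/variance, so a
violated-invariance cohort is often flagged at the *strict* step rather
than the strong one; the operationally meaningful property — the ladder
does not certify strict invariance on violated data — is what the tests
assert. Second, with items alone the zero-correlation baseline misfits
only mildly and ΔCFI/ΔTLI become noisy; including the genetic factor
(whose indicators correlate ≈ 0.97) stabilizes them, and the invariance
models here include it, as the published measurement models do.

## Association models

The cross-sectional model regresses the wave-1 and wave-2 trait factors
(strict-invariant measurement) on G simultaneously. The longitudinal
model defines the latent change score by fixing the autoregressive path
to 1 and the wave-2 residual variance to 0, so η₂ ≡ η₁ + Δ, and regresses
both η₁ and Δ on G; Δ's mean and variance are free. The two models are
one-to-one reparameterizations and fit identically (checked to 1e-6).
Wald CIs are estimate ± 1.96·SE on the standardized scale. The test
family for FDR control is 12 (2 sexes × 2 traits × 3 phenotypes), a
config knob; adjustment is Benjamini–Hochberg step-up with enforced
monotonicity.

The sensitivity analysis scores G by posterior mean on a 201-point
Gauss-grid under the fitted probit measurement model (genotype information
only), forms top/bottom 30% groups with ties broken by stable sort on
sample id, and replaces G by the binary group indicator (observed scale).
Note a structural limitation: three binary male SNPs give at most eight
distinct score values, so the tails are completed by tie-breaks within a
genotype pattern and the group contrast is attenuated (≈ 0.87× the full-
sample coefficient at scale in our generator) rather than amplified as a
continuous-score selection would predict (≈ 1.13×). Score-based
subgroup contrasts computed from phenotype-informed factor scores — which
this package deliberately does not produce — are larger but circular.

## Synthetic-data generator

The generator is the study-conditions oracle for every calibration test:

* **Genotypes.** Two routes. `generate_snps` fits a maximum-entropy
  3-locus haplotype distribution to target MAFs and pairwise allelic r
  (exponential-family dual, Fréchet-bound feasibility checks) and samples
  one haplotype per male, two per female — used for QC-level realism
  (MAF/LD/HWE). `generate_full_study` instead draws SNP dosages as
  categorized indicators of a latent G (standardized loadings
  0.989/0.989/0.984 males, 0.968/0.968/0.959 females; thresholds set from
  the MAFs, Hardy–Weinberg proportions in females), mirroring the analysis
  model so that recovery targets are well defined.
* **Phenotypes.** Standardized factors at both waves with the fitted
  cross-wave correlations (extraversion 0.592, neuroticism 0.526 in males)
  and cross-trait correlations; defaults for loadings and thresholds are
  the published standardized loadings and endorsement rates per wave. A
  `strict` mode copies wave-1 values to wave 2 when the generating model
  must satisfy strict invariance exactly.
* **Effects.** `beta_cross` is corr(G, η₁); `beta_change` is corr(G, Δ/σ_Δ)
  with σ_Δ² = 2(1−ρ₁₂) on the standardized two-wave scale; variance
  explained equals β². Single-SNP effects are injected through one SNP's
  liability, scaled so the *observed dosage* explains the stated share of
  phenotypic variance.
* **Nuisance structure.** Cross-wave residual correlation of repeated
  items defaults to 0.2 (the cohort's empirical residual correlations are
  not published; the value is configurable and all calibration results are
  conditional on it). Missingness is MCAR only. One master seed drives
  everything; per-replicate seeds advance by a fixed increment.

What the generator does not emulate: non-normal liabilities, dominance or
X-inactivation effects, informative missingness, population structure, and
item-level local dependence beyond the single cross-wave residual
correlation. Passing calibration tests therefore demonstrate internal
consistency of estimator and generator under these assumptions, not
robustness to their violation.

## Monte Carlo power

Each power replicate generates a male cohort (n = 1160), fits the
corresponding association model and applies a two-sided Wald test at
α = 0.05. The cross-sectional scenarios use the single-wave 6-item model
(9 observed variables); the change scenarios use the full latent
difference model (15 variables) with the cross-sectional effect held at
its observed −0.167; the single-SNP scenarios regress the latent phenotype
on one observed standardized dosage. Replicates that fail to converge are
excluded and counted; results carry the binomial Monte Carlo SE, and a
scenario with more than 5% failures is flagged unreliable. Default
replicate counts: 1000 in the library, 500 in the acceptance script and
250 in the test suite — rejection-rate SEs of about 0.013/0.018/0.026 near
power 0.8, with every randomness source derived from the run seed.

A calibration remark for readers comparing against published Monte Carlo
power values from proprietary software: the post hoc and a priori numbers
printed for this design imply mutually inconsistent effective standard
errors for the same coefficient, model and sample size (roughly 0.059
from the post hoc cross-sectional power at β = 0.167, but 0.048 from the
a priori sweep at β = 0.10–0.17). No single faithful implementation can
land inside both; this one sits between (empirical SD(β̂) ≈ 0.055 for the
single-wave model), so it runs several points above the published post
hoc cross-sectional value and several points below the a priori ones.
For the change scenario, published power implies SE(β̂_Δ) ≈ 0.062, which
corresponds to a latent-difference model *without* a genetic path or
covariance to the wave-1 factor; this package keeps that path, because
dropping it breaks the exact reparameterization identity with the
cross-sectional model that the latent-difference construction is defined
by, and the resulting SE is ≈ 0.079 (power correspondingly lower). The
matched single-SNP comparisons agree closely.

## Degenerate inputs and tie-breaks

Monomorphic SNPs raise explicit errors (LD and thresholds undefined);
zero-count categories raise a boundary error advising category collapse;
an all-missing stratum is an error rather than a silent NaN. The male
minor allele is defined empirically per stratum (frequencies are folded at
0.5) and the mapping is recorded in the QC report, since coded-allele
conventions in external files cannot be trusted. EM for female two-locus
haplotype frequencies starts from uniform frequencies and stops at a 1e-10
sup-norm change; it equals direct counting exactly when no double
heterozygotes exist. Extreme-group ties are broken by stable sort on
sample id and logged.
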