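# Methods

This note documents the models, parameter choices and numerical
conventions behind `ditchnet`, and what the synthetic experiments do and
do not establish about field data.

## Synthetic mesocosm generator (`synth`)

**Design.** 36 ditches in a randomised complete block layout: 9 blocks,
each holding exactly one ditch per dose (0, 0.1, 1, 10 μg/L).  Every ditch
is sampled in two periods, *before* (always at dose 0) and *after*
(at its assigned dose).  Counts are individuals per metre of ditch (the
sampling protocol isolates a one-metre compartment); no other area
normalisation is applied anywhere.

**Marginals.** Each of the 85 taxa has a zero-inflated negative-binomial
(ZINB) count distribution: structural absence probability π_s, NB mean μ_s
and dispersion k = 1.5 (variance μ + μ²/k; Poisson is too thin-tailed for
invertebrate counts).  The rank-abundance series is geometric
(μ_s ∝ e^(−0.09 s)) and π_s rises with rarity
(0.10 + 0.85·(s/84)^0.8).  These constants were calibrated analytically so
a control ditch yields ≈ 30 observed taxa and ≈ 1000 individuals, the
community size the analysis is designed around.  The per-taxon abundance
distribution of the real system is unknown; the ZINB-copula form is an
explicit modelling assumption, not an estimate.

**Coherence mechanism.** Inter-taxon association enters through a Gaussian
copula with latent factors: z = Λf + ε with unit marginal variance, mapped
through Φ and the ZINB quantile function.  Each taxon loads on one of
three factors with |loading| = 0.85 (sign negative with probability 0.25),
creating coherent sub-guilds.  Structural zeros occupy the lower copula
tail, so presence/absence co-varies along with abundance.  The analysis
only requires tunable *rank* correlation, which the copula provides
without distorting marginals.

**Dose action.** Marginally, non-release taxa are thinned by logistic
survival 1/(1+(dose/EC50_s)^h) with per-taxon EC50 ~ LogNormal(ln 2, 0.8)
μg/L and h = 1; ~10% of taxa are "release" taxa (multiplier
1 + 0.5·dose/(dose+EC50), emulating short-generation taxa that profit from
competitor release) — these are assigned predator/other feeding modalities
so the detritivore guilds remain the sensitive ones.  Structurally, all
loadings are attenuated by exp(−r·log10(1+dose)) with decoherence rate
r = 2.0, chosen so dose 0 is exactly unattenuated and the 10 μg/L
community is essentially uncorrelated (attenuation ≈ 0.12, pairwise latent
correlation ≈ 0.01).

**Measurement model.** Abundant taxa are not fully counted in the field:
a homogenised subsample is counted until ≥ 50 individuals of the taxon or
25% of the sample has been processed.  This is modelled per taxon as a
hypergeometric draw from the subsample fraction
f = max(50/count, 0.25), scaled back by 1/f and rounded half-up; counts
reached before either trigger pass through exactly.  The estimator is
unbiased up to rounding.

**Processes.** Ecosystem processes follow the causal structure the path
model is meant to recover: organic-matter consumption and plant growth
increase linearly with shredder + gatherer-collector (SGC) biomass;
floating algal bed (FLAB) presence is Bernoulli with logit
b0 − b1·SGC/SGC_ref (defaults 1.5, 4.0; SGC_ref = mean SGC, so slopes are
per control-level unit); phytoplankton chlorophyll-A drops by a fixed
amount when FLAB is present; periphyton tracks grazer biomass.  Gaussian
noise is scaled to each response's deterministic mean; continuous
responses are clipped at zero.

**Dissipation.** C(t) = c0·e^(−kt) with k = ln2/DT50 and mean-one
multiplicative log-normal noise of coefficient of variation `noise_cv`.

## Community statistics (`metrics`)

Bray–Curtis and Jaccard dissimilarities come from
`scipy.spatial.distance`; samples with zero total are flagged as undefined
pairs rather than silently imputed.  The PERMANOVA is the sequential
(type-I) Gower-centred partition: SS per term from cumulative projection
traces tr(H_j G), pseudo-F against the residual, permutation p with the
add-one estimator (1+b)/(1+m).  The repeated-measures structure of the
field design ("ditch as random factor") is handled by *restricting
permutations within blocks* (default `strata="block"`); the alternative
unrestricted mode is available.  The same reasoning replaces the field
analysis' linear mixed models for univariate metrics with a one-way ANOVA
plus additive block term — at this balanced design the inferential target
is identical and no variance-component estimation is needed.  A saturated
fit (zero residual SS) is reported as F = ∞ rather than an arbitrary
number; `treatment_effect_test` flags zero residual variance instead of
returning an F.

Beta-dispersion embeds samples by principal coordinates, keeping negative
eigenvalue axes: squared distance to the group centroid is the real-axis
part minus the imaginary-axis part, clipped at zero (the standard
correction), with a label-permutation F test.  Accumulation curves are
Monte-Carlo means over random sample orderings; the exact
rarefaction expectation Σ_s(1 − C(N−N_s,k)/C(N,k)) is used as the test
oracle.

## Networks (`network`)

Spearman ρ uses average (mid) ranks.  A pair is *computable* only if both
count vectors vary across the nine replicates; "potential correlations" is
the number of computable pairs.  (The published potential-pair counts are
not C(n,2) of any integer taxon count, so the original denominator is not
recoverable; computability is the definition adopted here, and it
naturally explains non-triangular counts.)  Thresholds are strict
(|ρ| > 0.67, > 0.80), matching the published wording, and the significance
threshold is the t-approximation value 0.67, not the exact permutation
critical value (≈ 0.683).  Connectance and median R² are reported at 2 dp
with half-up rounding.  The rare-species filter removes taxa with ≤ 5
individuals summed over a treatment's nine replicates.

## Null model (`nullmodel`)

π_s is the observed fraction of zero control replicates; λ_s = mean
count/(1−π_s) (moment matching), so per-taxon and total expectations equal
the control's.  A documented alternative spreads a single λ uniformly over
taxa, matching only the total; it is not the default because the
correlations are computed on abundance structure that uniform λ destroys.
Null communities use the same nine-replicate geometry as observed
treatments so counts are commensurable.  The threshold grid is 0.50–0.99
step 0.01; envelopes are the 0.025/0.975 ensemble quantiles of the count
distribution per threshold.  The χ² comparison uses the 2×2 table
{correlated, uncorrelated} × {observed, null-median} with continuity
correction (the construction is under-specified in the field literature;
this is the documented default).  Curve smoothing is a centred moving
average over 5 grid points (raw values are always emitted); a
locally-weighted smoother would add a dependency without changing any
decision.  Verdicts require *both* the envelope position and χ² p < 0.05
to call a community coherent (above) or degraded (below); anything else is
indistinguishable.

## Ecosystem function (`ecofunction`)

Trait affinities (10-point scores) are normalised to weights summing to 1
per taxon; taxa with all-zero affinities are excluded and listed.
Component models: Gaussian responses are fitted by maximum-likelihood
linear mixed models with a block random intercept; when the variance
component collapses to the boundary (common with 9 blocks) or the fit
fails, the model falls back to fixed block effects and reports the BIC of
the fitted form — this avoids the boundary-estimate instability of forcing
a random intercept.  FLAB presence is a plain logistic regression;
complete separation is flagged (coefficients are still reported from a
quasi-Newton fit).  Standardised coefficients are β·sd(x)/sd(y); for the
binomial path the response scale is the latent logistic scale
sd(y*) = √(var(η) + π²/3), the standard convention when none is stated.
The d-separation basis set contains one claim per non-adjacent pair,
conditioned on the union of both variables' parents, tested as the partial
slope in the corresponding component regression (response = the
topologically later variable, with its family); claim p-values are clipped
at 1e-300 before Fisher's C.  Model BIC is the sum of component BICs.

A deliberate property of the full synthetic pipeline: the copula
correlates the feeding groups with each other, while the a-priori diagram
(like the field model) draws no consumer–consumer links, so the global
d-separation test typically *rejects* on pipeline data while accepting on
data generated from the diagram itself.  The structure-recovery tests use
the latter; the former is shown in `examples/05` as an interpretable
rejection.

## Problem sizes and tolerances

Simulation-based checks run at sizes chosen to keep Monte-Carlo error well
inside the asserted margins: 200 runs for null-model calibration (envelope
refreshed every 20 runs, 200 null communities each), 100 runs for envelope
position and path-sign recovery, 500 noisy decay fits, 800/1000 runs for
permutation-test type-I rates with 99 permutations per test (the add-one
p at 99 permutations gives an exact 5% level under exchangeability).
Oracle-equivalence checks (Spearman vs rank-then-Pearson, χ² vs the
textbook formula) assert agreement to 1e-12/1e-10; rarefaction to 0.03
taxa at 20 000 orderings.

## Known limitations

- The generator omits abiotic covariates (temperature, nutrients,
  hydrology) and any temporal dynamics beyond the two periods; passing
  tests show the *statistical machinery* behaves correctly under the
  assumed data-generating process, not that the ZINB-copula is the right
  model for real ditches.
- ZIP parameters are moment estimates, not maximum likelihood, by design
  (the null is a calibration device, not a fitted model).
- The published potential-correlation denominators cannot be reproduced
  exactly (definition unrecoverable, see above); connectance arithmetic is
  verified against the published counts instead.
- Fixed-effect fallbacks mean the reported BIC is not always comparable
  across components fitted in different forms; comparisons are only made
  between candidate structures fitted the same way.
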