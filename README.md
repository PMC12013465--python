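# ditchnet

Co-occurrence network coherence and ecosystem-function analysis for
replicated freshwater mesocosm experiments.

## The problem

Insecticides such as neonicotinoids reach surface waters at concentrations
that rarely extinguish whole species, yet may still dismantle the web of
dependencies between invertebrate taxa and, through it, ecosystem
functioning.  Simple descriptors (taxon richness, Shannon diversity) are
often blind to this: taxa are replaced rather than lost.  `ditchnet`
implements the two-tiered analysis used to expose such damage in
experimental ditch ('mesocosm') studies:

1. **Statistical coherence of co-occurrence networks.**  For each treatment
   (dose), the Spearman rank correlation ρ of every taxon pair across the
   nine replicate ditches is computed after removing rare taxa (≤ 5
   individuals per treatment).  Pairs with |ρ| > 0.67 (two-sided p < 0.05
   at n = 9 under the t approximation, t = ρ√((n−2)/(1−ρ²))) are
   *significant* correlations; |ρ| > 0.80 are *strong*.  *Connectance* is
   each count as a percentage of the control's potential (computable)
   pairs.  The observed network is compared to a null ensemble of
   communities whose taxa are drawn independently from zero-inflated
   Poisson (ZIP) marginals fitted to the control — π_s from the observed
   non-occurrence frequency, λ_s by moment matching so that
   Σ(1−π_s)λ_s reproduces the control's mean total abundance — using the
   0.025–0.975 envelope of the null count distribution and a
   continuity-corrected χ² test.  A coherent community has more (and
   stronger) correlations than random; a degraded one is indistinguishable
   from, or below, its null.

2. **Ecosystem function via a piecewise path model.**  Counts become
   biomass through the aquatic-invertebrate allometry
   mass [mg] = 0.11·length[mm]^1.79 and feeding-preference trait weights,
   giving per-ditch biomass for the functional feeding groups (shredder,
   gatherer-collector, grazer, filter feeder, predator).  A piecewise
   structural equation model encodes the a-priori hypothesis that the
   insecticide acts only on the feeding groups and reaches ecosystem
   processes (organic-matter consumption, floating algal beds, periphyton,
   phytoplankton, plant growth) only through them.  Components are fitted
   separately (Gaussian with a block random intercept, logistic for FLAB
   presence), paths reported as standardised coefficients, and the global
   structure tested by d-separation: Fisher's C = −2Σln pᵢ ~ χ² with 2k df.

Because the corresponding field data are not redistributable at desk
scale, the package ships a first-class synthetic generator (`synth`) that
reproduces the study conditions: 36 ditches = 4 doses (0, 0.1, 1, 10 μg/L)
× 9 randomised blocks, an ~85-taxon pool with ~30 taxa and ~1000
individuals per control ditch, dose-dependent mortality with release taxa,
and — the key knob — a latent-factor Gaussian copula whose loadings decay
with dose, so the *coherence* of the community is tunable independently of
its abundances.  Insecticide dissipation follows first-order kinetics
(DT50 = ln2/k, DT90 = ln10/k).

## Worked example

```python
import ditchnet as dn

table = dn.sample_community(dn.default_community_params(), dn.generate_design(1), seed=2)
print(dn.network_summary(table))
```

```
 treatment_ugL  n_potential  n_significant  n_strong  median_r2_significant  connectance_significant_pct  connectance_strong_pct
           0.0         1326            319       158                   0.64                        24.06                   11.92
           0.1         1225            130        41                   0.57                         9.80                    3.09
           1.0          861             58        11                   0.54                         4.37                    0.83
          10.0          561             38         7                   0.53                         2.87                    0.53
```

Reading the table: with increasing dose the community loses potential
pairs (taxa fall under the rare filter), loses significant and strong
correlations much faster than potential pairs, and median R² (= ρ² of the
significant pairs) drifts down — correlations that survive are weaker.
Comparing against the control-fitted ZIP null (`fit_zip`, `sample_null`,
`coherence_verdict`) classifies the control as `coherent-above-null`
(observed 158 strong correlations vs a null median of 16, χ² p ≈ 2e-28)
and the 10 μg/L community as `indistinguishable` from random assembly
(7 vs 16, p = 1): the stressor has erased the community's statistical
coherence.  The `examples/` directory walks through each capability
(simulation, community metrics, networks, null model, ecosystem function),
and the `ditchnet` CLI chains them:

```bash
ditchnet simulate --seed 1 --out data/
ditchnet analyze --dataset data/ --out report/
ditchnet report --report report/
```

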