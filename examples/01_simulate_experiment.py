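"""Simulate a 36-ditch mesocosm experiment and inspect the communities.

Four insecticide doses (0, 0.1, 1, 10 ug/L) x nine randomised blocks,
sampled before and after application.  Dose thins most taxa (logistic
survival per taxon) while a few short-generation "release" taxa increase.
"""

import ditchnet as dn

design = dn.generate_design(seed=1)
params = dn.default_community_params()
table = dn.sample_community(params, design, seed=2)

print(f"{design.n_ditches} ditches, {design.n_blocks} blocks, doses {design.concentrations}")
after = table.subset(period="after")
for dose in design.concentrations:
    sub = after.subset(treatment=dose)
    counts = sub.counts.to_numpy()
    print(
        f"dose {dose:>4} ug/L: mean richness {(counts > 0).sum(axis=1).mean():5.1f} taxa, "
        f"mean abundance {counts.sum(axis=1).mean():7.1f} per m ditch"
    )
# Richness stays near ~30 while total abundance declines with dose: the
# community is restructured (taxon turnover) more than it is thinned.
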