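"""Zero-inflated-Poisson null model: is a community's network non-random?

The null preserves each control taxon's occurrence probability and the
control's mean total abundance but draws taxa independently, destroying
all co-occurrence structure.  An observed network is "coherent" when it
has significantly more correlations than the null ensemble's envelope.
"""

import ditchnet as dn
from ditchnet import nullmodel

table = dn.sample_community(dn.default_community_params(), dn.generate_design(1), seed=2)

fc0 = dn.filter_rare(table, treatment=0.0)
zp = dn.fit_zip(fc0)
print(f"fitted ZIP null: {len(zp.taxa)} taxa, expected total {zp.expected_total:.0f} per replicate")

draws = dn.sample_null(zp, n_communities=1000, seed=5)
ensemble = dn.null_count_distribution(draws)

for dose in (0.0, 10.0):
    net = dn.spearman_matrix(dn.filter_rare(table, dose))
    obs = nullmodel.observed_counts_on_grid(net, ensemble.grid)
    curve = dn.relative_curve(obs, ensemble)
    at80 = curve[curve["threshold"] == 0.80].iloc[0]
    verdict = dn.coherence_verdict(net, ensemble)
    print(f"\ndose {dose} ug/L:")
    print(
        f"  at |rho|>0.80: observed {at80['observed']:.0f} vs null median "
        f"{at80['null_median']:.0f} ({at80['relative_pct']:.0f}% of null)"
    )
    for cls, v in verdict.items():
        print(f"  {cls}: {v['verdict']} (chi-square p = {v['p']:.3g})")
# The control sits far above the null envelope (biological organisation);
# the top dose is statistically indistinguishable from random assembly.
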