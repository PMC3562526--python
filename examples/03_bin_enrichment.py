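"""Wilcoxon rank-sum enrichment of functional bins.

The simulator plants one annotation bin ('cell_wall') on the up-regulated
probe-sets; the rank-sum test should flag it as strongly up-shifted while
generic background bins stay non-significant.
"""

import xspecies as xs
from xspecies.postanalysis import wilcoxon_bin_enrichment
from xspecies.synth import make_annotation

cfg = xs.SimulationConfig(n_probe_sets=400, de_fraction=0.1, seed=3)
layout, gdna, rna, truth = xs.simulate(cfg)
annotation = make_annotation(layout, truth, cfg, enriched_bin="cell_wall")

masked = xs.apply_mask(layout, xs.build_mask(gdna, layout, 75.0))
de = xs.de_test(xs.rma(rna, masked))

results = wilcoxon_bin_enrichment(dict(de.frame.log2fc), annotation, min_bin_size=3)
print(f"{'bin':12s} {'n':>4s} {'p_raw':>10s} {'p_adj':>10s}  direction")
for r in sorted(results, key=lambda r: r.p_adj):
    print(f"{r.bin:12s} {r.n_members:4d} {r.p_raw:10.2e} {r.p_adj:10.2e}  {r.direction}")
print("\nA tiny adjusted p for 'cell_wall' with direction 'up' means its member genes")
print("sit far above the rest in the log2 fold-change ranking, as planted.")
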