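"""Choose a gDNA masking threshold by maximizing the DE count.

Simulates a cross-species experiment in which half the probes have diverged
targets (their binding attenuated to 5%), sweeps the gDNA intensity
threshold, and shows that an intermediate threshold detects more
differentially expressed probe-sets than no masking at all.
"""

import xspecies as xs

cfg = xs.SimulationConfig(
    n_probe_sets=500, divergence_fraction=0.5, attenuation=0.05,
    de_fraction=0.1, de_log2fc=1.0, noise_sd=0.2, seed=7,
)
layout, gdna, rna, truth = xs.simulate(cfg)

thresholds = [float(t) for t in range(0, 301, 25)]
curve = xs.retention_curve(gdna, layout, thresholds)
result = xs.optimize_mask_threshold(gdna, rna, layout, thresholds)

print("threshold  pairs  sets  DE-count")
for t, n_pairs, n_sets, de in zip(thresholds, curve.n_pairs_retained,
                                  curve.n_sets_retained, result.de_counts):
    marker = "  <-- best" if t == result.best_threshold else ""
    print(f"{t:9.0f}  {n_pairs:5d}  {n_sets:4d}  {de:8d}{marker}")

print(f"\nBest threshold {result.best_threshold:g}: {result.best_count} DE probe-sets "
      f"vs {result.de_counts[0]} with no mask.")
print("Probe-pairs drop out quickly once the threshold passes the attenuated mode of")
print("the gDNA signal, probe-sets survive much longer (a set needs only 2 good pairs),")
print("and removing the diverged probes raises the number of detectable DE genes.")
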