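"""Call differentially synthesized proteins from a replicate ratio table.

Orients label-swapped replicates, applies the >=3-replicate detection
filter, runs the one-sample t-test of log2(mutant/wt) against 0 and
summarizes the volcano-plot coordinates.
"""

from translatomics import (
    SimConfig,
    filter_detected,
    gen_proteome,
    orient_ratios,
    summarize_regulation,
    test_differential,
    volcano_coords,
)

config = SimConfig(seed=7, n_proteins=1000, frac_regulated=0.06)
quant, truth = gen_proteome(config)

oriented = orient_ratios(quant)          # all columns now mean log2(mutant/wt)
kept, filtered = filter_detected(oriented, min_reps=3)
results = test_differential(kept, alpha=0.05)

summary = summarize_regulation(results)
print(f"detected in >=3 replicates: {summary['n_tested']} "
      f"(filtered: {len(filtered)})")
print(f"called regulated at p<0.05: {summary['n_up']} up, {summary['n_down']} down")
print(f"planted regulated: {(truth != 'null').sum()} "
      f"({(truth == 'up').sum()} up) -> the up:down asymmetry is recovered")

coords = volcano_coords(results)
x, y = max(coords, key=lambda c: c[1])
print(f"strongest volcano point: log2FC={x:+.2f}, -log10(p)={y:.1f} "
      f"(x=1 means a twofold change)")
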