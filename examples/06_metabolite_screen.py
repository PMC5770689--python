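"""Median-normalize a metabolite peak table and call presence / flux.

Detects the planted mutant-only metabolite in the cell compartment and
classifies medium metabolites as consumed or secreted against the
unconditioned-medium reference.
"""

from translatomics import (
    SimConfig,
    gen_metabolome,
    median_normalize,
    presence_calls,
    uptake_secretion,
)

peaks, truth = gen_metabolome(SimConfig(seed=5))
normalized = median_normalize(peaks)

calls = presence_calls(normalized)
mutant_only = [c.metabolite for c in calls
               if c.pattern == "mutant-only" and c.consistent_across_timepoints]
print(f"metabolites screened: {len(calls)}")
print(f"mutant-only at every timepoint: {mutant_only} "
      f"(planted: {truth['mutant_only']})")

flux = uptake_secretion(normalized)
consumed = sorted(flux.index[(flux == 'consumed').all(axis=1)])
secreted = sorted(flux.index[(flux == 'secreted').all(axis=1)])
print(f"consumed in both genotypes: {consumed}")
print(f"secreted in both genotypes: {secreted}")
# Calls on unplanted metabolites can fluctuate with only two replicates
# per condition; the planted shifts (0.4x / 2.5x) are called reliably.
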