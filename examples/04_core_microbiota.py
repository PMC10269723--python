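"""Detect the core microbiota of a sample x OPU count table.

An OPU is core when it occurs in more than 90% of samples (strict
convention; a >= toggle covers the other convention surveys use).  The
summary also reports how much of each sample's community the core set
carries, as mean +/- sd of its summed relative abundance.
"""

import opucore as oc

sim = oc.simulate_dataset(oc.SimConfig(seed=11))
table = sim.abundance

core = oc.detect_core(table, oc.CoreConfig(prevalence_threshold=0.90, strict=True))
mean_rich, sd_rich = oc.richness_stats(table)

print(f"table: {len(table.samples)} samples x {len(table.opus)} OPUs")
print(f"core OPUs (prevalence > 90%): {len(core.core_opus)} -> {list(core.core_opus)}")
print(f"core share of the community : {core.mean_abundance_pct:.2f} "
      f"+/- {core.sd_abundance_pct:.2f} % per sample")
print(f"richness: {mean_rich:.1f} +/- {sd_rich:.1f} OPUs per sample")
print(f"matches the planted core set: {sorted(core.core_opus) == sim.truth.core_set}")
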