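"""Amplicon length-window filtering and retention accounting.

Full-length 16S amplicons outside the 1,200–1,600 bp window are discarded;
the summary reports how many reads survive, as surveys report it
(retained count and percentage of raw reads).
"""

import opucore as oc

# simulated per-read lengths around the ~1,445 bp mode of full-length 16S
lengths = oc.simulate_read_lengths(oc.SimConfig(seed=11))
summary = oc.run_qc(lengths, oc.QcConfig(min_len=1200, max_len=1600))
print(f"simulated run : kept {summary.retained_count}/{summary.raw_count} reads "
      f"({summary.retention_pct}%)")

# the same arithmetic applied to a survey's printed read counts
printed = oc.qc_retention_summary(1_408_058, 1_035_221)
print(f"printed counts: kept {printed.retained_count}/{printed.raw_count} reads "
      f"({printed.retention_pct}%)")
# retention_pct is rounded half-even to two decimals, the convention used
# when surveys print percentages next to read counts.
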