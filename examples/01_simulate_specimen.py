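"""Simulate one trisomy-16 POC specimen and inspect its two channels.

Builds the miniature genome (1/20 hg19, 20-kb bins), simulates a specimen
carrying a constitutional trisomy 16 at ~10^6 reads, and prints the observed
chr16 depth ratio (expected 1.5 for three copies) and the BAF mode structure.
"""

import numpy as np

from poccnv import KaryotypeSpec, build_genome, simulate_specimen
from poccnv.simulate import FLAT_BIAS, whole_chromosome_event

genome = build_genome()
truth = KaryotypeSpec(
    sex="XX", events=[whole_chromosome_event(genome, "whole_chrom_gain", "chr16")]
)
# flat GC bias so raw depth ratios are interpretable without correction
# (02_call_cnvs.py shows the corrected pipeline under the default bias)
counts, baf = simulate_specimen(
    genome, truth, total_reads=1_000_000, gc_bias=FLAT_BIAS, seed=1
)

sl = genome.chrom_slice("chr16")
other = genome.autosomal_mask & ~genome.chrom_mask("chr16")
ratio = counts.counts[sl].mean() / counts.counts[other].mean()
print(f"total reads        : {counts.counts.sum():,}")
print(f"chr16 depth ratio  : {ratio:.3f}   (trisomy expectation: 1.5)")

on16 = baf.chrom == "chr16"
mid = baf.baf[on16][(baf.baf[on16] > 0.2) & (baf.baf[on16] < 0.8)]
print(f"chr16 mid-band BAF : mean |baf - 1/3 or 2/3| = "
      f"{np.minimum(np.abs(mid - 1/3), np.abs(mid - 2/3)).mean():.3f} "
      f"(trisomy shifts heterozygous modes to 1/3 and 2/3)")
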