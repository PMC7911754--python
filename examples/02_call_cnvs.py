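"""GC-correct a run of specimens and segment one profile with CBS.

Simulates a run of nine diploids plus one specimen with a 1.5-Mb duplication,
applies the three-step GC correction, segments the duplication carrier, and
prints the resulting segments.  The duplicated interval should appear as one
segment near log2(3/2) = 0.585 while the rest of the genome stays near 0.
"""

from poccnv import Event, KaryotypeSpec, build_genome, correct_counts, segment_cbs, simulate_specimen

genome = build_genome()
dup = KaryotypeSpec(events=[Event("segmental_dup", "chr4", 3_000_000, 4_500_000)])
run = [
    simulate_specimen(genome, KaryotypeSpec(), 1_000_000, seed=s)[0] for s in range(9)
]
run.append(simulate_specimen(genome, dup, 1_000_000, seed=99, specimen_id="dup_carrier")[0])

profiles = correct_counts(run, genome)
segments = segment_cbs(profiles[-1], genome, seed=7)

print("segments on chr4 of the duplication carrier:")
for seg in segments:
    if seg.chrom == "chr4":
        print(f"  {seg.chrom}:{seg.start:>9,}-{seg.end:>9,}  "
              f"mean log2 = {seg.mean_log2:+.3f}  ({seg.n_bins} bins)")
print("(the elevated segment marks the simulated 3.0-4.5 Mb duplication)")
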