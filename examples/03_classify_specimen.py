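"""Classify simulated specimens into reporting categories.

Runs the full per-specimen pipeline (correction, CBS, BAF detectors,
classification) on three specimens with known truth — a 40% mosaic trisomy
21, a triploid, and a normal — and prints the reported category for each.
Criteria sizes are scaled 1/20 to match the miniature genome.
"""

from poccnv import KaryotypeSpec, ReportingCriteria, build_genome, simulate_cohort
from poccnv.classify import classify_cohort
from poccnv.simulate import SimulatedSpecimen, SpecimenMeta, simulate_specimen, whole_chromosome_event

genome = build_genome()
criteria = ReportingCriteria().scaled(20)

truths = {
    "mosaic_t21": KaryotypeSpec(
        events=[whole_chromosome_event(genome, "whole_chrom_gain", "chr21", 0.4)]
    ),
    "triploid": KaryotypeSpec(ploidy="triploid"),
    "normal": KaryotypeSpec(),
}
specimens = []
for i, (name, truth) in enumerate(truths.items()):
    counts, baf = simulate_specimen(genome, truth, 1_000_000, seed=10 + i, specimen_id=name)
    meta = SpecimenMeta(name, "RPL", 2, 31.0, "snp_array")
    specimens.append(SimulatedSpecimen(meta, truth, counts, baf))

for res in classify_cohort(specimens, genome, criteria, cbs_n_perm=200, seed=3):
    extra = ""
    if res.whole_events:
        e = res.whole_events[0]
        extra = f"  ({e.chrom} {e.direction}, fraction {e.mosaic_fraction:.2f})"
    print(f"{res.specimen_id:>10} -> {res.category}{extra}")
print("(mosaic aneuploidy and triploidy both report as mosaic_or_triploidy)")
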