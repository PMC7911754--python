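# poccnv

Low-coverage CNV-seq karyotyping and cohort statistics for products-of-conception
(POC) specimens.

Roughly half of early miscarriages carry a chromosomal abnormality, and clinical
laboratories karyotype POC tissue with two molecular channels: a read-depth
channel (low-coverage whole-genome "CNV-seq", ~3–5 M reads binned at 20 kb) and
an allelic channel (SNP-array B-allele frequencies, needed for triploidy and
loss of heterozygosity, which depth alone cannot see). `poccnv` implements that
analysis end to end as a tested Python library, with a synthetic-data generator
standing in for clinical specimens so every stage is verifiable against known
ground truth:

* **Read-depth calling** — per-bin read counts, a three-step GC correction
  (LOESS of log depth on GC, intra-run median normalisation, linear-model
  regression on a run reference), and circular binary segmentation (CBS) with a
  permutation test for each split. A segment at log2 ratio *r* in a diploid
  background implies an abnormal-cell fraction *m* = 2·(2^*r* − 1) for gains and
  2·(1 − 2^*r*) for losses, so constitutional trisomy sits at log2(3/2) ≈ 0.585
  and monosomy at −1.
* **Specimen classification** — fixed reporting criteria (deletions ≥ 1 Mb,
  duplications ≥ 2 Mb, LOH ≥ 5 Mb, mosaicism ≥ 30%, mosaic CNVs ≥ 5 Mb, and
  exclusion above 30% maternal cell contamination estimated from STR markers)
  reduce each specimen to one category: `normal`, `autosomal_trisomy`,
  `autosomal_monosomy`, `monosomy_x`, `mosaic_or_triploidy`,
  `partial_imbalance`, or `other`.
* **Cohort statistics** — miscarriage-count-stratified summary tables, age
  stratification, recurrent-CNV clustering by reciprocal overlap, and
  carrier-frequency tests between sporadic-abortion (SA) and
  recurrent-pregnancy-loss (RPL) groups (Fisher's exact test by exact
  hypergeometric tail summation, or Pearson chi-square when all cell counts
  allow it).
* **Enrichment** — hypergeometric over-representation P(X ≥ k) of a query gene
  list against GMT gene sets with Benjamini–Hochberg adjustment.

Packaged fixtures carry the printed count tables of a 1556-case POC series
(540 SA / 1016 RPL; 895 abnormal) so the cohort arithmetic can be recomputed
exactly.

## Worked example

```python
from poccnv import KaryotypeSpec, build_genome, simulate_specimen
from poccnv.simulate import FLAT_BIAS, whole_chromosome_event

genome = build_genome()                      # 1/20-scale hg19, 20-kb bins
truth = KaryotypeSpec(events=[whole_chromosome_event(genome, "whole_chrom_gain", "chr16")])
counts, baf = simulate_specimen(genome, truth, total_reads=1_000_000,
                                gc_bias=FLAT_BIAS, seed=1)
```

Running `python examples/01_simulate_specimen.py` (the same computation) prints

```
total reads        : 1,000,000
chr16 depth ratio  : 1.504   (trisomy expectation: 1.5)
chr16 mid-band BAF : mean |baf - 1/3 or 2/3| = 0.058 (trisomy shifts heterozygous modes to 1/3 and 2/3)
```

The depth ratio is 3/2 because chr16 carries three copies, and heterozygous BAF
values cluster at 1/3 and 2/3 instead of 1/2 — the two signatures the pipeline
uses. The other scripts in `examples/` walk through segmentation
(`02_call_cnvs.py`), classification (`03_classify_specimen.py`), the cohort
tables and the 16q24.3 recurrent-duplication association test
(`04_cohort_tables.py`, which prints Fisher p = 3.80e-04 for 19/1016 RPL vs
0/540 SA carriers), and gene-set enrichment (`05_enrichment.py`).

A thin CLI mirrors the pipeline stages:

```sh
poccnv simulate --n 20 --seed 7 --out sim/
poccnv call --out segs/ sim/*.counts.tsv
poccnv classify --out res/ sim/POC0000.counts.tsv
poccnv reproduce-tables --out tables/
```

## Layout

```
src/poccnv/        library (genome, simulate, cnvseq, classify, cohort,
                   enrichment, io, cli)
src/poccnv/data/   packaged count fixtures and a synthetic toy GMT
examples/          one short narrative script per capability
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    models, parameters, and design notes
```
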