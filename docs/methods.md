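# Methods

This note documents the models implemented in `poccnv`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where more than one reasonable option existed.

## Genome model

All profiles share one coordinate frame: fixed-width half-open bins (default
20 kb — the standard resolution for 3–5 M-read CNV-seq) tiling each
chromosome, with a GC fraction per bin and a cytoband table for call labels.
Two presets exist: `hg19` (GRCh37 lengths, ~155,000 bins) and `miniature`
(every chromosome at 1/20 hg19 length, ~7,750 bins). The miniature preset is
the default and the scale at which the test suite and acceptance script run:
it preserves every structural property that matters (24 chromosomes,
realistic relative sizes, smooth GC variation, p/q banding) while keeping a
500-specimen cohort analysis to a few minutes. Reporting-criteria size
thresholds are scaled by the same factor (`ReportingCriteria.scaled(20)`)
when working at miniature scale; fractions are scale-free.

The simulated GC field is a moving-average-smoothed Gaussian field squashed
into [0.3, 0.6] (the bulk of the human distribution); a fixed `gc_seed` makes
the genome fully deterministic. Synthetic cytobands place a centromere at 40%
of each chromosome and number bands outward from it, ISCN-style; an explicit
band table can be supplied instead.

## Synthetic specimens

**Depth channel.** Per-bin expected rate is `copy/2 · f(gc)`, where `copy`
blends event copy number by mosaic fraction (a 40% mosaic trisomy gives
copy 2.4) and `f` is the GC-bias multiplier. Counts are drawn multinomially
over bins, i.e. Poisson depth conditioned on the exact read total, so the sum
of counts equals the requested total by construction and analytic
expectations stay exact. Negative-binomial overdispersion is available
(gamma-multiplied rates) but off by default, keeping the oracles analytic.
The default depth is 10^6 reads per specimen (~130 reads/bin at miniature
scale), emulating the per-bin depth regime of 3 M uniquely mapped reads on
the full genome.

**GC bias.** `f(gc) = 1 − β·((gc − 0.4)/0.2)²`, floored at 0.05: a unimodal
quadratic with its optimum at GC 0.4, where β is the fractional rate loss one
half-width (0.2 GC units) from the optimum. β defaults to 0.5, which produces
an uncorrected |correlation| of ~0.5–0.9 between log2 depth and GC at the
default depth — strong enough that correction is demonstrably necessary,
weak enough to be realistic.

**Allelic channel.** Biallelic markers (default 25/Mb, 40% heterozygous) with
BAF beta-distributed around the allelic dose (concentration 50, i.e. SD ≈
0.07 at BAF 0.5). Ploidy and events act on genotype dose: triploidy leaves
relative depth flat but moves heterozygous modes to 1/3 and 2/3; a mosaic
event at fraction m moves them to (1 ± m·I)/(2 + m) with the affected
haplotype drawn per marker. No markers are placed on chrY. LOH regions can be
planted directly (`loh_regions`), forcing homozygous genotypes.

**Maternal cell contamination.** Mixing with a 46,XX diploid maternal profile
keeps the read total exact: each fetal read survives with probability 1 − f
and the removed reads are redrawn from the maternal rate profile. BAF mixes
convexly. The STR channel simulates 15 markers (mother heterozygous at ≥ 8,
6 alleles per marker) with Dirichlet dose-share noise (concentration 200,
matching peak-height ratio noise of capillary STR assays); at a marker where
the mother carries an allele the fetus lacks, that allele's dose share per
maternal copy is f/2 in expectation. The simulated specimen profile carries
the called fetal genotype — clinically, fetal genotypes at STR loci are
determined jointly during interpretation; modelling that inference is out of
scope, and at f = 0.5 it is ill-posed from doses alone.

**Cohort generator.** Specimens are drawn i.i.d. from a category spectrum
that defaults to the packaged series' observed spectrum (42.5% normal, 36.8%
autosomal trisomy, 11.1% partial imbalance, 5.8% monosomy X, 3.0%
mosaic/triploidy, 0.5% monosomy, 0.3% other), with the SA/RPL split (34.7% /
65.3%), miscarriage-count distribution, per-stratum maternal-age means (SD
4.2 years, clipped to 21–48) and the ~62/38 SNP-array/CNV-seq platform split
of the same series. Mosaic aneuploidies draw fractions uniformly from
[0.3, 0.8]; segmental events draw 0.5–2 Mb (miniature scale) uniformly placed;
the "other" category is emulated as XYY. Triploid specimens are always
assigned the SNP-array platform: triploidy is invisible to depth alone, so
only the allelic-channel arm can contribute such calls — drawing triploid
truth on the BAF-less platform would plant ground truth that no correct
pipeline could recover.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: mappability and replication-timing artefacts,
duplicate/chimeric reads, segmental-duplication pileups, reference bias,
population LD structure in marker genotypes, vanishing-twin mixtures, and
degraded-sample noise. Results on real specimens depend on those factors;
the tests certify the algorithms, not a clinical validation.

## GC correction

Three steps, mirroring multi-sample low-coverage practice:

1. **LOESS** of log2 count on GC (span 0.3), fitted on usable autosomal bins
   and subtracted. The fit is two-pass: bins whose first-pass residual
   exceeds 3 robust SDs (MAD-based) are excluded from the second fit, so a
   large CNV concentrated in one GC range cannot bend the trend toward
   itself. The outlier-free bin set also serves as the centring set for all
   medians, so a trisomic chromosome does not drag its own specimen's centre.
2. **Intra-run normalisation**: each specimen is shifted so its autosomal
   median matches the run median.
3. **Reference regression**: each specimen's residuals are regressed (OLS)
   on a per-bin leave-one-out median reference across the other specimens of
   the run (or a supplied diploid baseline) and residualised; this removes
   bias shared across the run that a GC-only fit cannot capture. The
   leave-one-out form keeps a specimen's own CNVs out of its reference.

Bins with zero count or GC outside [0.2, 0.8] are masked, not imputed — at
low coverage an imputed bin fabricates signal. Sex chromosomes are normalised
against the dosage expected for the inferred sex (called from the fraction of
non-zero chrY bins): XX expects chrX at ratio 1 with chrY masked; XY expects
both at single-copy dosage, adjusted onto the diploid scale. A
single-specimen run without a reference degrades to median-centering with a
warning. Corrected profiles have |autosomal median log2| < 0.01.

## Segmentation (CBS)

Recursive circular binary splitting. For a segment of n bins, the statistic
for an arc (i, j) is the absolute difference between arc and complement
means scaled by √(1/k + 1/(n−k)); the data variance is constant under
permutation of bin order and is omitted, which is monotone-equivalent to the
classical pooled-t form for the permutation decision and cheaper. The best
arc over all (i, j) is tested by permutation (default 1,000 shuffles, seeded
Fisher–Yates), a split is accepted at p < α (default 0.01), and the
algorithm recurses; adjacent output segments whose means differ by less than
`merge_tol` (0.1 log2 units) are re-merged. `min_width` is 2 bins.
Defaults mirror the canonical published CBS defaults, including leaving
split-undoing off. The permutation loop aborts early only when the
exceedance count already implies p ≥ α, which cannot change any
accept/reject decision; truly significant splits always run the full
permutation budget. Chromosomes shorter than 2·`min_width` usable bins are
returned as a single flagged segment. The kernels are numba-compiled;
segmentation of a 7,750-bin genome takes ~0.1–2 s depending on `n_perm`.

Cohort-scale runs (hundreds of specimens) use `n_perm = 200`; the smallest
attainable p is then 1/201 ≈ 0.005 < α, so split acceptance is unchanged for
clear events, and null chromosomes abort after a handful of shuffles. α and
all other defaults are unchanged.

## Mosaic fraction and classification

Segment means invert to abnormal-cell fractions under the diploid dosage
model (m = 2·(2^r − 1) for gains, 2·(1 − 2^r) for losses; baseline 1 copy
instead of 2 for sex chromosomes in XY), clipped to [0, 1.5] with values
above 1.1 flagged as multi-copy (tetrasomy candidates). A chromosome whose
same-direction altered segments (fraction ≥ 0.30) cover ≥ 90% of its usable
length is a whole-chromosome event; fractions ≥ 0.9 are constitutional,
below that mosaic. The 90% coverage rule and the 0.9 constitutional
boundary are package decisions — the boundary between aneuploidy and a very
large partial imbalance has to be drawn somewhere, and 90% tolerates masked
bins and edge noise without admitting half-chromosome events.

Triploidy is called genome-wide from mid-band BAF markers (0.15–0.85) by
comparing a single heterozygous mode at 1/2 against equal-weight modes at
1/3 and 2/3 (Gaussian mixtures sharing one free σ, fitted by EM on σ); the
triploid model must win by a BIC margin of ≥ 10 (strong-evidence
convention). At least 200 mid-band markers are required, else indeterminate.
LOH regions are maximal runs of markers outside (0.2, 0.8) spanning ≥ 5 Mb
at normal depth. Specimens on the CNV-seq platform skip both detectors (no
allelic channel), mirroring two-platform clinical reality.

Category priority when findings coexist: triploidy or mosaic
whole-chromosome aneuploidy → `mosaic_or_triploidy`; constitutional
autosomal gain → `autosomal_trisomy` (even alongside sex-chromosome
polyploidy); autosomal loss → `autosomal_monosomy`; X loss in an XX-expected
specimen → `monosomy_x`; tetrasomy or sex-chromosome-only aneuploidy →
`other`; surviving sub-chromosomal calls → `partial_imbalance`; else
`normal`. When the depth channel calls a trisomy but the chromosome's BAF
looks cleanly diploid, the result is flagged `discordant_channels` and depth
wins — CNV-seq-only specimens never had an allelic channel, so depth is the
channel every specimen shares. Specimens whose STR-based contamination
estimate exceeds 30% are excluded (`category = None`); the estimate is twice
the mean per-copy dose share of maternal-specific alleles over informative
markers, indeterminate below 3 informative markers (flagged, not excluded).

## Cohort statistics

Stratified tables follow clinical reporting conventions: whole-cohort
percentages to 2 decimals, abnormal-category percentages as integers of the
abnormal total, all rounding half-up. Age bins are closed on the left
(<30, 30–34, ≥35). Empty cells report an undefined rate, never 0.

Recurrent-CNV clustering is single-linkage under ≥ 50% reciprocal overlap
within the same call type; a cytoband-equality mode is available since
clinical series usually report recurrence by band. The representative region
is the intersection of members (falling back to the member nearest the
median midpoint if a linkage chain empties the intersection). A cluster is
recurrent at n ≥ 2. Association between carrier frequencies uses Fisher's
exact test — minimum-likelihood two-sided, summed in exact integer
arithmetic over the hypergeometric outcome distribution — whenever any
expected *or observed* cell count is below 5 (a zero observed cell makes the
χ² approximation unreliable even when Cochran's expected-count rule is
met), and the Pearson chi-square (no continuity correction) otherwise. No
multiple-testing correction is applied to recurrent-CNV tests by default,
matching uncorrected p < 0.05 reporting practice in this literature; a BH
option exists in the enrichment module and can be applied externally.

## Enrichment

Over-representation only: p = P(X ≥ k) for X hypergeometric over the
universe, BH-adjusted across sets, sorted by adjusted p with ties broken by
set id. The universe defaults to the union of all set members (configurable);
query symbols outside it are dropped with a warning. Upper-tail p-values of
a discrete test are super-uniform, not uniform; the test suite verifies
calibration through the standard randomised continuity correction, which is
exactly uniform iff the implemented tails are correct.

## Numerical and testing notes

* All randomness flows through explicit seeds; fixed seeds give bit-identical
  outputs (including CLI file outputs).
* Problem sizes used by the test suite and acceptance script: CBS/oracle
  agreement on 100–200 random signals of ≤ 400 bins; GC-correction checks on
  runs of 4–6 specimens at 10^6 reads; category recovery on a 500-specimen
  cohort (tests) or 250-specimen cohort (acceptance script) plus a targeted
  batch of 30 whole-chromosome mosaics at fractions 0.30–0.50 — the cohort
  spectrum alone yields only ~1–3 such mosaics per 500 specimens, too few to
  estimate a sensitivity.
* Mosaic sensitivity near fraction 0.30 is intrinsically ~50% at the
  boundary: the reporting criterion is a hard 0.30 threshold and the
  fraction estimate has SD ≈ 0.013 at default depth, so truths within
  ~0.03 of the boundary straddle it. Sensitivity over the whole 0.30–0.50
  band is ~85–90%.
* Spurious CBS splits surviving the merge step occur at roughly the α level
  per tested segment; with canonical defaults (no split-undoing) this puts
  exhaustive-oracle breakpoint agreement at ~98–100% on 400-bin signals.
* Fisher p-values are exact rationals converted to float at the end; the
  test oracle enumerates outcome probabilities as `Fraction`s through an
  independent formula.

## Known limitations

* Tetraploidy is invisible to both modelled channels (depth flat, BAF modes
  at 0 / 1/2 / 1) and is only ever reported via the multi-copy flag when a
  relative imbalance exists; pure tetraploidy classifies as normal.
* The depth model has no position-specific artefacts, so specificity
  estimates from simulation are optimistic.
* Parental origin, meiotic/mitotic origin, and clinical pathogenicity
  interpretation are out of scope; pathogenicity annotation is a pluggable
  table, not a database lookup.
* The BAF channel models a single homogeneous tissue; confined placental
  mosaicism (different fractions in different biopsies) is not represented.
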