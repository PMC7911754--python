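"""Specimen-level karyotype classification under fixed reporting criteria.

One specimen's segmented depth profile (plus, on the SNP-array platform, its
BAF channel and STR-based maternal-contamination estimate) is reduced to a
single reporting category:

``normal | autosomal_trisomy | autosomal_monosomy | monosomy_x |
mosaic_or_triploidy | partial_imbalance | other``

The reporting criteria mirror standard POC molecular-karyotyping practice:
deletions are reported from 1 Mb, duplications from 2 Mb, loss of
heterozygosity from 5 Mb, mosaicism from a 30% abnormal-cell fraction (CNV
mosaics additionally require 5 Mb), and specimens with maternal cell
contamination above 30% are excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cnvseq import CopyRatioProfile, Segment, correct_counts, segment_cbs
from .errors import InvalidConfigError
from .genome import GenomeModel, is_autosome
from .simulate import BafProfile, SimulatedSpecimen, StrMarkerSet

log = logging.getLogger("poccnv")

CONSTITUTIONAL_FRACTION = 0.9  # mosaic fraction at/above which an event is constitutional
WHOLE_CHROM_COVERAGE = 0.9  # fraction of usable chromosome length for a whole-chrom call
TETRASOMY_FRACTION = 1.1  # estimated fraction above which a gain is multi-copy


@dataclass(frozen=True)
class ReportingCriteria:
    """Size and fraction thresholds a finding must meet to be reported."""

    min_del_size: int = 1_000_000
    min_dup_size: int = 2_000_000
    min_loh_size: int = 5_000_000
    min_mosaic_fraction: float = 0.30
    min_mosaic_cnv_size: int = 5_000_000
    mcc_exclusion: float = 0.30

    def __post_init__(self) -> None:
        if min(self.min_del_size, self.min_dup_size, self.min_loh_size, self.min_mosaic_cnv_size) <= 0:
            raise InvalidConfigError("criteria sizes must be positive")
        for frac in (self.min_mosaic_fraction, self.mcc_exclusion):
            if not 0.0 < frac < 1.0:
                raise InvalidConfigError("criteria fractions must be in (0, 1)")

    def scaled(self, factor: float) -> "ReportingCriteria":
        """Criteria with size thresholds divided by ``factor`` (for scaled-down
        genomes); fractions are scale-free and unchanged."""
        return ReportingCriteria(
            min_del_size=max(1, int(self.min_del_size / factor)),
            min_dup_size=max(1, int(self.min_dup_size / factor)),
            min_loh_size=max(1, int(self.min_loh_size / factor)),
            min_mosaic_fraction=self.min_mosaic_fraction,
            min_mosaic_cnv_size=max(1, int(self.min_mosaic_cnv_size / factor)),
            mcc_exclusion=self.mcc_exclusion,
        )


@dataclass(frozen=True)
class CnvCall:
    chrom: str
    start: int
    end: int
    type: str  # dup | del
    size: int
    mosaic_fraction: float
    cytoband: str

    def __post_init__(self) -> None:
        if self.size != self.end - self.start:
            raise InvalidConfigError("CnvCall size must equal end - start")


@dataclass(frozen=True)
class WholeChromEvent:
    chrom: str
    direction: str  # gain | loss
    mosaic_fraction: float
    coverage: float
    constitutional: bool
    tetrasomy: bool


@dataclass
class SpecimenResult:
    specimen_id: str
    category: str | None  # None when QC-excluded
    calls: list[CnvCall] = field(default_factory=list)
    qc_flags: dict = field(default_factory=dict)
    inferred_sex: str = "XX"
    whole_events: list[WholeChromEvent] = field(default_factory=list)
    mcc_estimate: float | None = None
    triploidy_margin: float | None = None
    loh_regions: list[tuple[str, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# maternal cell contamination
# ---------------------------------------------------------------------------

def estimate_mcc(specimen_str: StrMarkerSet, maternal_str: StrMarkerSet) -> float | None:
    """Estimate the maternal contamination fraction from an STR profile pair.

    At each informative marker (one where the mother carries an allele absent
    from the fetal genotype) the maternal-specific allele's observed dose
    share, normalised per maternal allele copy, has expectation ``mcc/2``; the
    estimate is twice the mean over informative markers, clipped to [0, 1).
    Returns ``None`` (indeterminate) with fewer than 3 informative markers.
    """
    maternal = {m.marker: m for m in maternal_str.markers}
    per_marker: list[float] = []
    for m in specimen_str.markers:
        mat = maternal.get(m.marker)
        if mat is None or m.doses is None:
            continue
        fetal_alleles = set(m.genotype)
        specific = [a for a in mat.genotype if a not in fetal_alleles]
        if not specific:
            continue
        share = sum(m.doses.get(a, 0.0) for a in set(specific))
        per_marker.append(share / len(specific))
    if len(per_marker) < 3:
        return None
    return float(np.clip(2.0 * np.mean(per_marker), 0.0, 0.999))


# ---------------------------------------------------------------------------
# whole-chromosome events
# ---------------------------------------------------------------------------

def _fraction_from_mean(mean_log2: float, base: float) -> tuple[str, float]:
    """(direction, abnormal-cell fraction) for a segment mean with the given
    baseline copy number (2 for diploid regions, 1 for XY sex chromosomes)."""
    if mean_log2 >= 0:
        return "gain", float(np.clip(base * (2.0 ** mean_log2 - 1.0), 0.0, 3.0))
    return "loss", float(np.clip(base * (1.0 - 2.0 ** mean_log2), 0.0, 3.0))


def detect_whole_chromosome_events(
    segments: list[Segment],
    genome: GenomeModel,
    sex: str = "XX",
    min_fraction: float = 0.30,
    coverage: float = WHOLE_CHROM_COVERAGE,
) -> list[WholeChromEvent]:
    """Call whole-chromosome gains/losses from a segmented profile.

    A chromosome whose same-direction altered segments (fraction >=
    ``min_fraction``) cover at least ``coverage`` of its usable length is a
    whole-chromosome event; the event fraction is the bin-weighted mean.
    Fractions >= 0.9 are constitutional, below that mosaic; gains whose
    estimated fraction exceeds 1.1 are flagged as multi-copy (tetrasomy
    candidates).
    """
    out: list[WholeChromEvent] = []
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        total = sum(s.n_bins for s in segs)
        if total == 0:
            continue
        base = 2.0 if (is_autosome(chrom) or sex == "XX") else 1.0
        for direction in ("gain", "loss"):
            hit_bins = 0
            weighted = 0.0
            for s in segs:
                d, m = _fraction_from_mean(s.mean_log2, base)
                if d == direction and m >= min_fraction:
                    hit_bins += s.n_bins
                    weighted += m * s.n_bins
            if hit_bins / total >= coverage:
                m = weighted / hit_bins
                out.append(
                    WholeChromEvent(
                        chrom=chrom,
                        direction=direction,
                        mosaic_fraction=round(m, 4),
                        coverage=round(hit_bins / total, 4),
                        constitutional=m >= CONSTITUTIONAL_FRACTION,
                        tetrasomy=direction == "gain" and m > TETRASOMY_FRACTION,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# BAF-channel detectors
# ---------------------------------------------------------------------------

def _fixed_mean_mixture_ll(x: np.ndarray, means: tuple[float, ...]) -> float:
    """Max log-likelihood of an equal-weight Gaussian mixture with fixed means
    and one shared free sigma (EM on sigma only)."""
    mu = np.array(means)
    sigma = max(float(np.std(x)), 0.02)
    for _ in range(25):
        d2 = (x[:, None] - mu[None, :]) ** 2
        logp = -0.5 * d2 / sigma**2 - np.log(sigma)
        logp -= np.log(len(means))
        mx = logp.max(axis=1, keepdims=True)
        resp = np.exp(logp - mx)
        resp /= resp.sum(axis=1, keepdims=True)
        sigma = max(float(np.sqrt(np.sum(resp * d2) / x.size)), 0.01)
    d2 = (x[:, None] - mu[None, :]) ** 2
    comp = -0.5 * d2 / sigma**2 - np.log(sigma) - 0.5 * np.log(2 * np.pi) - np.log(len(means))
    mx = comp.max(axis=1)
    return float(np.sum(mx + np.log(np.sum(np.exp(comp - mx[:, None]), axis=1))))


def detect_triploidy(
    baf: BafProfile, min_markers: int = 200, bic_margin: float = 10.0
) -> tuple[str, float | None]:
    """Genome-wide diploid-vs-triploid call from mid-band BAF markers.

    Compares a single heterozygous mode at 1/2 against two modes at 1/3 and
    2/3 (equal-weight Gaussian mixtures, shared sigma) by BIC; the triploid
    model must win by at least ``bic_margin``.  Returns
    ``("indeterminate", None)`` when fewer than ``min_markers`` mid-band
    markers are available.
    """
    mid = baf.baf[(baf.baf > 0.15) & (baf.baf < 0.85)]
    if mid.size < min_markers:
        return "indeterminate", None
    ll2 = _fixed_mean_mixture_ll(mid, (0.5,))
    ll3 = _fixed_mean_mixture_ll(mid, (1.0 / 3.0, 2.0 / 3.0))
    # one free parameter (sigma) in both models: BIC difference = 2*(ll3-ll2)
    margin = 2.0 * (ll3 - ll2)
    return ("triploid" if margin >= bic_margin else "diploid"), float(margin)


def detect_loh(
    baf: BafProfile,
    criteria: ReportingCriteria | None = None,
    profile: CopyRatioProfile | None = None,
    genome: GenomeModel | None = None,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> list[tuple[str, int, int]]:
    """Maximal runs with no heterozygous marker, at normal depth, >= min size.

    A heterozygous marker is one with BAF inside ``het_band``.  When a profile
    and genome are supplied, candidate runs whose mean |log2 ratio| exceeds
    0.2 are dropped (copy-number loss, not copy-neutral LOH).
    """
    criteria = criteria or ReportingCriteria()
    out: list[tuple[str, int, int]] = []
    for chrom in np.unique(baf.chrom):
        sel = baf.chrom == chrom
        pos = baf.pos[sel]
        non_het = np.flatnonzero(
            ~((baf.baf[sel] > het_band[0]) & (baf.baf[sel] < het_band[1]))
        )
        if non_het.size == 0:
            continue
        # split consecutive non-het marker indices into maximal runs
        breaks = np.flatnonzero(np.diff(non_het) > 1) + 1
        for run in np.split(non_het, breaks):
            start, end = int(pos[run[0]]), int(pos[run[-1]]) + 1
            if end - start < criteria.min_loh_size:
                continue
            if profile is not None and genome is not None:
                sl = genome.chrom_slice(str(chrom))
                bins = (genome.bin_start[sl] >= start) & (genome.bin_start[sl] < end)
                vals = profile.log2_ratio[sl][bins]
                vals = vals[np.isfinite(vals)]
                if vals.size and abs(float(np.mean(vals))) > 0.2:
                    continue  # copy-number loss, not copy-neutral LOH
            out.append((str(chrom), start, end))
    return out


# ---------------------------------------------------------------------------
# CNV calls and classification
# ---------------------------------------------------------------------------

def _cytoband_label(genome: GenomeModel, chrom: str, start: int, end: int) -> str:
    short = chrom.removeprefix("chr")
    mid_band = genome.band_at(chrom, (start + end) // 2)
    end_band = genome.band_at(chrom, max(start, end - 1))
    if mid_band == end_band:
        return f"{short}{mid_band}"
    return f"{short}{mid_band}{end_band}"


def calls_from_segments(
    segments: list[Segment],
    genome: GenomeModel,
    criteria: ReportingCriteria,
    whole_events: list[WholeChromEvent],
    sex: str = "XX",
) -> list[CnvCall]:
    """Sub-chromosomal calls surviving the reporting criteria.

    Segments on chromosomes already carrying a whole-chromosome event are not
    re-reported.  A constitutional call (fraction >= 0.9) must meet the
    del/dup size minimum; a mosaic call must meet both the mosaic fraction
    and the mosaic CNV size minima.
    """
    whole_chroms = {e.chrom for e in whole_events}
    calls: list[CnvCall] = []
    for seg in segments:
        if seg.chrom in whole_chroms or seg.flagged_short:
            continue
        base = 2.0 if (is_autosome(seg.chrom) or sex == "XX") else 1.0
        direction, m = _fraction_from_mean(seg.mean_log2, base)
        if m < criteria.min_mosaic_fraction:
            continue
        size = seg.end - seg.start
        if m >= CONSTITUTIONAL_FRACTION:
            min_size = criteria.min_dup_size if direction == "gain" else criteria.min_del_size
        else:
            min_size = criteria.min_mosaic_cnv_size
        if size < min_size:
            continue
        calls.append(
            CnvCall(
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                type="dup" if direction == "gain" else "del",
                size=size,
                mosaic_fraction=round(min(m, 1.0), 4),
                cytoband=_cytoband_label(genome, seg.chrom, seg.start, seg.end),
            )
        )
    return calls


def _baf_depth_discordant(baf: BafProfile | None, chrom: str) -> bool:
    """True when the BAF channel looks cleanly diploid-heterozygous on a
    chromosome the depth channel calls trisomic (modes at 1/2 instead of
    1/3 and 2/3)."""
    if baf is None:
        return False
    sel = baf.chrom == chrom
    mid = baf.baf[sel][(baf.baf[sel] > 0.2) & (baf.baf[sel] < 0.8)]
    if mid.size < 30:
        return False
    return float(np.mean(np.abs(mid - 0.5))) < 0.08


def classify_specimen(
    segments: list[Segment],
    genome: GenomeModel,
    criteria: ReportingCriteria | None = None,
    baf: BafProfile | None = None,
    profile: CopyRatioProfile | None = None,
    str_pair: tuple[StrMarkerSet, StrMarkerSet] | None = None,
    platform: str = "snp_array",
    specimen_id: str = "specimen",
) -> SpecimenResult:
    """Classify one specimen into the reporting taxonomy.

    Priority when findings coexist: triploidy or mosaic whole-chromosome
    aneuploidy -> ``mosaic_or_triploidy``; any constitutional autosomal
    whole-chromosome gain -> ``autosomal_trisomy`` (even alongside
    sex-chromosome polyploidy); autosomal loss -> ``autosomal_monosomy``;
    X loss in an XX-expected specimen -> ``monosomy_x``; tetrasomy or
    sex-chromosome-only aneuploidy -> ``other``; surviving sub-chromosomal
    calls -> ``partial_imbalance``; otherwise ``normal``.  Specimens whose
    maternal-contamination estimate exceeds the exclusion threshold carry
    ``category=None`` and the ``mcc_excluded`` flag.  Specimens on the
    ``cnv_seq`` platform have no allelic channel: triploidy and LOH detection
    are skipped.  Classification is deterministic given segments and BAF.
    """
    criteria = criteria or ReportingCriteria()
    qc: dict = {}
    mcc = None
    if str_pair is not None:
        mcc = estimate_mcc(*str_pair)
        if mcc is None:
            qc["mcc_indeterminate"] = True
        elif mcc > criteria.mcc_exclusion:
            qc["mcc_excluded"] = True
            return SpecimenResult(
                specimen_id=specimen_id, category=None, qc_flags=qc, mcc_estimate=mcc,
                inferred_sex=profile.inferred_sex if profile else "XX",
            )

    sex = profile.inferred_sex if profile is not None else "XX"
    whole = detect_whole_chromosome_events(
        segments, genome, sex=sex, min_fraction=criteria.min_mosaic_fraction
    )
    use_baf = platform == "snp_array" and baf is not None
    trip_call, trip_margin = ("indeterminate", None)
    loh: list[tuple[str, int, int]] = []
    if use_baf:
        trip_call, trip_margin = detect_triploidy(baf)
        loh = detect_loh(baf, criteria, profile=profile, genome=genome)
    calls = calls_from_segments(segments, genome, criteria, whole, sex=sex)

    auto_tri = [
        e for e in whole
        if e.direction == "gain" and e.constitutional and not e.tetrasomy and is_autosome(e.chrom)
    ]
    auto_mono = [
        e for e in whole if e.direction == "loss" and e.constitutional and is_autosome(e.chrom)
    ]
    mosaic_whole = [e for e in whole if not e.constitutional]
    x_loss = [
        e for e in whole
        if e.chrom == "chrX" and e.direction == "loss" and e.constitutional and sex == "XX"
    ]
    sex_aneu = [e for e in whole if not is_autosome(e.chrom) and e.chrom not in [x.chrom for x in x_loss]]
    tetrasomy = [e for e in whole if e.tetrasomy]

    if trip_call == "triploid" or mosaic_whole:
        category = "mosaic_or_triploidy"
    elif auto_tri:
        category = "autosomal_trisomy"
        if use_baf and all(_baf_depth_discordant(baf, e.chrom) for e in auto_tri):
            qc["discordant_channels"] = True  # depth channel wins
    elif auto_mono:
        category = "autosomal_monosomy"
    elif x_loss:
        category = "monosomy_x"
    elif tetrasomy or sex_aneu:
        category = "other"
    elif calls:
        category = "partial_imbalance"
    else:
        category = "normal"

    return SpecimenResult(
        specimen_id=specimen_id,
        category=category,
        calls=calls,
        qc_flags=qc,
        inferred_sex=sex,
        whole_events=whole,
        mcc_estimate=mcc,
        triploidy_margin=trip_margin,
        loh_regions=loh,
    )


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------

def classify_cohort(
    specimens: list[SimulatedSpecimen],
    genome: GenomeModel,
    criteria: ReportingCriteria | None = None,
    run_size: int = 20,
    cbs_alpha: float = 0.01,
    cbs_n_perm: int = 1000,
    cbs_min_width: int = 2,
    seed: int = 0,
) -> list[SpecimenResult]:
    """Run correction, segmentation and classification over a cohort.

    Specimens are corrected in runs of ``run_size`` (intra-run normalisation
    and the reference regression need multi-specimen runs, mirroring batched
    sequencing).  Low-depth specimens (mean usable depth < 10 reads/bin) are
    flagged but still classified.
    """
    criteria = criteria or ReportingCriteria()
    results: list[SpecimenResult] = []
    for lo in range(0, len(specimens), run_size):
        batch = specimens[lo : lo + run_size]
        profiles = correct_counts([s.counts for s in batch], genome)
        for spec, prof in zip(batch, profiles):
            segments = segment_cbs(
                prof,
                genome,
                alpha=cbs_alpha,
                n_perm=cbs_n_perm,
                min_width=cbs_min_width,
                seed=seed + lo,
            )
            res = classify_specimen(
                segments,
                genome,
                criteria,
                baf=spec.baf if spec.meta.platform == "snp_array" else None,
                profile=prof,
                str_pair=spec.str_pair,
                platform=spec.meta.platform,
                specimen_id=spec.meta.specimen_id,
            )
            mean_depth = spec.counts.counts[prof.mask].mean() if prof.mask.any() else 0.0
            if mean_depth < 10:
                res.qc_flags["low_depth"] = True
            results.append(res)
    return results
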