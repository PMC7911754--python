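"""Synthetic specimen and cohort generator with known ground-truth karyotypes.

Emulates the two information channels of products-of-conception (POC)
cytogenomics without any external data:

* a read-depth channel — per-bin counts drawn multinomially over bin rates
  proportional to ``copy/2 · f(GC)`` (Poisson depth conditioned on the exact
  read total), with a unimodal GC-dependent rate multiplier;
* an allelic channel — B-allele frequencies (BAF) at simulated biallelic
  markers, beta-distributed around the genotype dose.  Triploidy leaves
  relative depth flat but moves heterozygous BAF modes to 1/3 and 2/3, which
  is exactly why the allelic channel exists.

Maternal cell contamination (MCC) is modelled as a convex mixture of the
fetal specimen with a 46,XX diploid maternal profile, together with a short
tandem repeat (STR) marker channel from which the contamination fraction is
estimated downstream.

The default cohort abnormality spectrum is the observed POC spectrum of a
large miscarriage series (~42.5% normal, ~36.8% autosomal trisomy, ~5.8%
monosomy X, ~11.1% partial imbalance, ...), so a simulated cohort reproduces
realistic category frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cnvseq import BinnedCounts
from .errors import InvalidConfigError, InvalidSpecError
from .genome import GenomeModel, is_autosome

EVENT_KINDS = ("whole_chrom_gain", "whole_chrom_loss", "segmental_dup", "segmental_del")

CATEGORIES = (
    "normal",
    "autosomal_trisomy",
    "autosomal_monosomy",
    "monosomy_x",
    "mosaic_or_triploidy",
    "partial_imbalance",
    "other",
)

#: Default cohort sampling spectrum: category counts of a 1556-case POC series
#: (895 abnormal), normalised over the whole cohort.
DEFAULT_SPECTRUM: dict[str, float] = {
    "normal": 661 / 1556,
    "autosomal_trisomy": 572 / 1556,
    "autosomal_monosomy": 8 / 1556,
    "mosaic_or_triploidy": 46 / 1556,
    "partial_imbalance": 173 / 1556,
    "monosomy_x": 91 / 1556,
    "other": 5 / 1556,
}

#: SA vs RPL proportions of the same series (540 vs 1016 of 1556).
DEFAULT_GROUP_MIX: tuple[float, float] = (540 / 1556, 1016 / 1556)

# RPL miscarriage-count distribution (2, 3, >=4 losses) of the series.
_RPL_COUNT_WEIGHTS = {2: 586 / 1016, 3: 283 / 1016, 4: 147 / 1016}

# platform split of the series (963 SNP-array vs 593 CNV-seq).
_P_SNP_ARRAY = 963 / 1556


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    kind: str
    chrom: str
    start: int
    end: int
    mosaic_fraction: float = 1.0  # 1.0 = constitutional


@dataclass
class KaryotypeSpec:
    """Ground-truth karyotype of one simulated specimen."""

    sex: str = "XX"  # XX or XY
    events: list[Event] = field(default_factory=list)
    ploidy: str = "diploid"  # diploid | triploid | tetraploid_like
    mcc_fraction: float = 0.0
    loh_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self, genome: GenomeModel) -> None:
        if self.sex not in ("XX", "XY"):
            raise InvalidSpecError(f"sex must be XX or XY, got {self.sex!r}")
        if not 0.0 <= self.mcc_fraction < 1.0:
            raise InvalidSpecError(f"mcc_fraction must be in [0, 1), got {self.mcc_fraction}")
        by_chrom: dict[str, list[Event]] = {}
        for ev in self.events:
            if ev.kind not in EVENT_KINDS:
                raise InvalidSpecError(f"unknown event kind {ev.kind!r}")
            length = genome.chrom_length(ev.chrom)
            if not (0 <= ev.start < ev.end <= length):
                raise InvalidSpecError(
                    f"event {ev.kind} {ev.chrom}:{ev.start}-{ev.end} outside [0, {length})"
                )
            if not 0.0 < ev.mosaic_fraction <= 1.0:
                raise InvalidSpecError(f"mosaic_fraction must be in (0, 1], got {ev.mosaic_fraction}")
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end:
                    raise InvalidSpecError(f"overlapping events on {chrom}")


@dataclass
class BafProfile:
    """B-allele frequencies at simulated biallelic markers."""

    chrom: np.ndarray  # str per marker
    pos: np.ndarray  # int64, strictly increasing within chromosome
    baf: np.ndarray  # float64 in [0, 1]
    markers_per_mb: float

    @property
    def n_markers(self) -> int:
        return int(self.pos.size)


@dataclass(frozen=True)
class SpecimenMeta:
    specimen_id: str
    group: str  # SA | RPL
    miscarriage_count: int
    maternal_age: float
    platform: str  # snp_array | cnv_seq

    def __post_init__(self) -> None:
        if self.miscarriage_count < 1:
            raise InvalidSpecError("miscarriage_count must be >= 1")
        if (self.group == "SA") != (self.miscarriage_count == 1):
            raise InvalidSpecError("group is SA iff miscarriage_count == 1")
        if self.platform not in ("snp_array", "cnv_seq"):
            raise InvalidSpecError(f"unknown platform {self.platform!r}")


@dataclass(frozen=True)
class StrMarker:
    marker: str
    genotype: tuple[str, ...]  # called allele set of the profile's subject
    doses: dict[str, float] | None = None  # observed allele dose shares


@dataclass
class StrMarkerSet:
    markers: list[StrMarker]


@dataclass
class GcBiasCurve:
    """Unimodal GC rate multiplier ``f(gc) = 1 − β·((gc − center)/half_width)²``.

    ``f(center) = 1`` by construction; the curve is floored at ``floor`` so
    rates stay positive.  ``beta`` is the fractional rate loss one half-width
    away from the optimum (default half-width 0.2 GC units).
    """

    beta: float = 0.5
    center: float = 0.4
    half_width: float = 0.2
    floor: float = 0.05

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        u = (np.asarray(gc, dtype=float) - self.center) / self.half_width
        return np.maximum(1.0 - self.beta * u * u, self.floor)


FLAT_BIAS = GcBiasCurve(beta=0.0)


@dataclass
class BafParams:
    markers_per_mb: float = 25.0
    p_het: float = 0.4
    concentration: float = 50.0  # beta concentration of BAF noise


# ---------------------------------------------------------------------------
# expected copy number
# ---------------------------------------------------------------------------

def expected_copy(genome: GenomeModel, spec: KaryotypeSpec) -> np.ndarray:
    """Per-bin expected copy number under the spec (mosaic events blended).

    Triploid and tetraploid-like ploidies scale all chromosomes equally, so
    the *relative* depth profile is flat; the returned array is the
    diploid-equivalent dosage the depth channel can see.
    """
    spec.validate(genome)
    copy = np.full(genome.n_bins, 2.0)
    if "chrX" in genome.chrom_names:
        copy[genome.chrom_slice("chrX")] = 2.0 if spec.sex == "XX" else 1.0
    if "chrY" in genome.chrom_names:
        copy[genome.chrom_slice("chrY")] = 0.0 if spec.sex == "XX" else 1.0
    for ev in spec.events:
        sl = genome.chrom_slice(ev.chrom)
        starts = genome.bin_start[sl]
        hit = (starts >= ev.start) & (starts < ev.end)
        delta = 1.0 if ev.kind in ("whole_chrom_gain", "segmental_dup") else -1.0
        idx = np.flatnonzero(hit) + sl.start
        copy[idx] = np.maximum(copy[idx] + delta * ev.mosaic_fraction, 0.0)
    return copy


def whole_chromosome_event(
    genome: GenomeModel, kind: str, chrom: str, mosaic_fraction: float = 1.0
) -> Event:
    return Event(kind, chrom, 0, genome.chrom_length(chrom), mosaic_fraction)


# ---------------------------------------------------------------------------
# specimen simulation
# ---------------------------------------------------------------------------

def _simulate_counts(
    genome: GenomeModel,
    copy: np.ndarray,
    total_reads: int,
    gc_bias: GcBiasCurve,
    rng: np.random.Generator,
    nb_dispersion: float = 0.0,
    specimen_id: str = "specimen",
) -> BinnedCounts:
    lam = (copy / 2.0) * gc_bias(genome.bin_gc)
    if nb_dispersion > 0.0:
        # gamma-multiplied rates give negative-binomial marginal counts
        lam = lam * rng.gamma(1.0 / nb_dispersion, nb_dispersion, size=lam.size)
    total_rate = lam.sum()
    if total_rate <= 0:
        raise InvalidSpecError("all bin rates are zero")
    counts = rng.multinomial(int(total_reads), lam / total_rate)
    return BinnedCounts(specimen_id=specimen_id, counts=counts, total_reads=int(total_reads))


def _marker_positions(
    genome: GenomeModel, markers_per_mb: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    chroms, positions = [], []
    for chrom, length in genome.chromosomes:
        if chrom == "chrY":
            continue  # no informative biallelic markers modelled on Y
        n = int(round(markers_per_mb * length / 1e6))
        if n == 0:
            continue
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False))
        chroms.append(np.full(pos.size, chrom, dtype=object))
        positions.append(pos.astype(np.int64))
    return np.concatenate(chroms), np.concatenate(positions)


def _simulate_baf(
    genome: GenomeModel,
    spec: KaryotypeSpec,
    params: BafParams,
    rng: np.random.Generator,
) -> BafProfile:
    chrom, pos = _marker_positions(genome, params.markers_per_mb, rng)
    n = pos.size
    # diploid genotype: B-allele count 0/1/2
    p_hom = (1.0 - params.p_het) / 2.0
    b = rng.choice([0, 1, 2], size=n, p=[p_hom, params.p_het, p_hom]).astype(float)
    total = np.full(n, 2.0)

    if spec.sex == "XY":
        on_x = chrom == "chrX"
        b[on_x] = rng.choice([0.0, 1.0], size=int(on_x.sum()))
        total[on_x] = 1.0

    for cl, s, e in spec.loh_regions:
        in_region = (chrom == cl) & (pos >= s) & (pos < e)
        b[in_region] = np.where(b[in_region] >= 1.0, total[in_region], 0.0)

    if spec.ploidy == "triploid":
        # one extra haploid set: heterozygous AB gains a random third allele
        extra_b = np.where(
            b == 1.0, rng.integers(0, 2, size=n).astype(float), b / np.maximum(total, 1.0)
        )
        b = b + extra_b
        total = total + 1.0
    elif spec.ploidy == "tetraploid_like":
        b, total = 2.0 * b, 2.0 * total  # AABB etc.: BAF modes unchanged

    for ev in spec.events:
        in_ev = (chrom == ev.chrom) & (pos >= ev.start) & (pos < ev.end)
        idx = np.flatnonzero(in_ev)
        m = ev.mosaic_fraction
        if ev.kind in ("whole_chrom_gain", "segmental_dup"):
            # the duplicated haplotype carries B with probability b/total
            dup_is_b = rng.random(idx.size) < b[idx] / np.maximum(total[idx], 1.0)
            b_evt = b[idx] + dup_is_b
            t_evt = total[idx] + 1.0
        else:
            lost_is_b = rng.random(idx.size) < b[idx] / np.maximum(total[idx], 1.0)
            b_evt = np.maximum(b[idx] - lost_is_b, 0.0)
            t_evt = np.maximum(total[idx] - 1.0, 0.0)
        num = (1.0 - m) * b[idx] + m * b_evt
        den = (1.0 - m) * total[idx] + m * t_evt
        b[idx] = np.where(den > 0, num / np.maximum(den, 1e-9), 0.0) * total[idx]

    mean = np.where(total > 0, b / np.maximum(total, 1e-9), 0.0)
    mean = np.clip(mean, 0.005, 0.995)
    kappa = params.concentration
    baf = rng.beta(mean * kappa, (1.0 - mean) * kappa)
    return BafProfile(chrom=chrom, pos=pos, baf=baf, markers_per_mb=params.markers_per_mb)


def simulate_specimen(
    genome: GenomeModel,
    truth: KaryotypeSpec,
    total_reads: int = 1_000_000,
    gc_bias: GcBiasCurve | None = None,
    seed: int = 0,
    baf_params: BafParams | None = None,
    nb_dispersion: float = 0.0,
    specimen_id: str = "specimen",
) -> tuple[BinnedCounts, BafProfile]:
    """Simulate one specimen's depth and BAF channels from its ground truth.

    Bin counts are multinomial over rates ``∝ copy/2 · f(gc)`` (their sum
    equals ``total_reads`` exactly); BAF markers are beta-distributed around
    the allelic dose implied by genotype, ploidy and any mosaic events.  A
    non-zero ``truth.mcc_fraction`` mixes in a 46,XX diploid maternal profile.
    """
    if total_reads <= 0:
        raise InvalidConfigError(f"total_reads must be positive, got {total_reads}")
    gc_bias = gc_bias or GcBiasCurve()
    baf_params = baf_params or BafParams()
    rng = np.random.default_rng(seed)
    truth.validate(genome)

    copy = expected_copy(genome, truth)
    counts = _simulate_counts(
        genome, copy, total_reads, gc_bias, rng, nb_dispersion, specimen_id
    )
    baf = _simulate_baf(genome, truth, baf_params, rng)
    if truth.mcc_fraction > 0.0:
        counts, baf, _ = mix_maternal_contamination(
            counts, baf, truth.mcc_fraction, genome, gc_bias=gc_bias, rng=rng
        )
    return counts, baf


# ---------------------------------------------------------------------------
# maternal cell contamination
# ---------------------------------------------------------------------------

@dataclass
class StrParams:
    n_markers: int = 15
    n_alleles: int = 6
    min_het: int = 8  # the mother is heterozygous at at least this many markers
    het_prob: float = 0.6  # heterozygosity of the remaining markers
    concentration: float = 200.0  # Dirichlet concentration of dose-share noise


def simulate_str_pair(
    mcc_fraction: float,
    rng: np.random.Generator | int = 0,
    params: StrParams | None = None,
) -> tuple[StrMarkerSet, StrMarkerSet]:
    """Simulate a (specimen, maternal) STR marker profile pair.

    The specimen's observed allele dose shares are the convex mixture of the
    fetal genotype (weight ``1 − f`` split over its two alleles) and the
    maternal genotype (weight ``f``), with Dirichlet noise; at a marker where
    the mother carries an allele absent from the fetus, that allele's
    expected dose share is ``f/2``.
    """
    if not 0.0 <= mcc_fraction < 1.0:
        raise InvalidSpecError(f"mcc_fraction must be in [0, 1), got {mcc_fraction}")
    params = params or StrParams()
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    f = mcc_fraction
    spec_markers: list[StrMarker] = []
    mat_markers: list[StrMarker] = []
    alleles = [f"a{i}" for i in range(params.n_alleles)]
    for k in range(params.n_markers):
        het = k < params.min_het or rng.random() < params.het_prob
        if het:
            mat = tuple(rng.choice(alleles, size=2, replace=False))
        else:
            a = str(rng.choice(alleles))
            mat = (a, a)
        transmitted = str(rng.choice(mat))
        paternal = str(rng.choice(alleles))
        fetal = (transmitted, paternal)
        doses: dict[str, float] = {}
        for a in fetal:
            doses[a] = doses.get(a, 0.0) + (1.0 - f) / 2.0
        for a in mat:
            doses[a] = doses.get(a, 0.0) + f / 2.0
        keys = sorted(doses)
        shares = np.array([doses[a] for a in keys])
        if params.concentration > 0:
            noisy = rng.dirichlet(np.maximum(shares, 1e-6) * params.concentration)
        else:
            noisy = shares
        spec_markers.append(
            StrMarker(marker=f"m{k}", genotype=tuple(sorted(set(fetal))),
                      doses=dict(zip(keys, noisy.tolist())))
        )
        mat_markers.append(StrMarker(marker=f"m{k}", genotype=tuple(sorted(set(mat)))))
    return StrMarkerSet(spec_markers), StrMarkerSet(mat_markers)


def mix_maternal_contamination(
    counts: BinnedCounts,
    baf: BafProfile,
    mcc_fraction: float,
    genome: GenomeModel,
    gc_bias: GcBiasCurve | None = None,
    rng: np.random.Generator | int = 0,
    str_params: StrParams | None = None,
    baf_params: BafParams | None = None,
) -> tuple[BinnedCounts, BafProfile, tuple[StrMarkerSet, StrMarkerSet]]:
    """Mix a fetal specimen with a 46,XX diploid maternal profile.

    Depth: each fetal read is kept with probability ``1 − f`` and the removed
    reads are redrawn from the maternal diploid rate profile, so the total
    read count is preserved exactly and every bin's expectation is the convex
    mixture.  BAF: the convex combination of fetal and simulated maternal
    BAF.  Also returns the (specimen, maternal) STR marker pair.
    ``mcc_fraction = 0`` returns the inputs unchanged.
    """
    if not 0.0 <= mcc_fraction < 1.0:
        raise InvalidSpecError(f"mcc_fraction must be in [0, 1), got {mcc_fraction}")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    str_pair = simulate_str_pair(mcc_fraction, rng, str_params)
    if mcc_fraction == 0.0:
        return counts, baf, str_pair

    gc_bias = gc_bias or GcBiasCurve()
    f = mcc_fraction
    kept = rng.binomial(counts.counts, 1.0 - f)
    n_mat = int(counts.total_reads - kept.sum())
    maternal_spec = KaryotypeSpec(sex="XX")
    mat_copy = expected_copy(genome, maternal_spec)
    lam = (mat_copy / 2.0) * gc_bias(genome.bin_gc)
    mat_counts = rng.multinomial(n_mat, lam / lam.sum())
    mixed_counts = BinnedCounts(
        specimen_id=counts.specimen_id,
        counts=kept + mat_counts,
        total_reads=counts.total_reads,
    )

    bp = baf_params or BafParams()
    p_hom = (1.0 - bp.p_het) / 2.0
    mat_b = rng.choice([0.0, 0.5, 1.0], size=baf.n_markers, p=[p_hom, bp.p_het, p_hom])
    mat_mean = np.clip(mat_b, 0.005, 0.995)
    mat_baf = rng.beta(mat_mean * bp.concentration, (1.0 - mat_mean) * bp.concentration)
    on_y = baf.chrom == "chrY"
    mixed_baf_vals = (1.0 - f) * baf.baf + f * np.where(on_y, baf.baf, mat_baf)
    mixed_baf = replace(baf, baf=mixed_baf_vals)
    return mixed_counts, mixed_baf, str_pair


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSpecimen:
    meta: SpecimenMeta
    truth: KaryotypeSpec
    counts: BinnedCounts
    baf: BafProfile
    str_pair: tuple[StrMarkerSet, StrMarkerSet] | None = None


def _draw_truth(
    category: str,
    genome: GenomeModel,
    rng: np.random.Generator,
    seg_size_range: tuple[int, int],
) -> KaryotypeSpec:
    autosomes = [c for c in genome.chrom_names if is_autosome(c)]
    sex = "XX" if rng.random() < 0.5 else "XY"
    if category == "normal":
        return KaryotypeSpec(sex=sex)
    if category == "autosomal_trisomy":
        chrom = str(rng.choice(autosomes))
        return KaryotypeSpec(sex=sex, events=[whole_chromosome_event(genome, "whole_chrom_gain", chrom)])
    if category == "autosomal_monosomy":
        chrom = str(rng.choice(autosomes))
        return KaryotypeSpec(sex=sex, events=[whole_chromosome_event(genome, "whole_chrom_loss", chrom)])
    if category == "monosomy_x":
        return KaryotypeSpec(sex="XX", events=[whole_chromosome_event(genome, "whole_chrom_loss", "chrX")])
    if category == "mosaic_or_triploidy":
        if rng.random() < 0.5:
            return KaryotypeSpec(sex=sex, ploidy="triploid")
        chrom = str(rng.choice(autosomes))
        m = float(rng.uniform(0.3, 0.8))
        return KaryotypeSpec(
            sex=sex, events=[whole_chromosome_event(genome, "whole_chrom_gain", chrom, m)]
        )
    if category == "partial_imbalance":
        chrom = str(rng.choice(autosomes))
        length = genome.chrom_length(chrom)
        size = int(rng.integers(seg_size_range[0], seg_size_range[1] + 1))
        size = min(size, int(0.6 * length))  # stay clearly sub-chromosomal
        start = int(rng.integers(0, max(length - size, 1)))
        kind = "segmental_dup" if rng.random() < 0.8 else "segmental_del"
        return KaryotypeSpec(sex=sex, events=[Event(kind, chrom, start, start + size)])
    if category == "other":
        # XYY: sex-chromosome-only whole gain
        return KaryotypeSpec(sex="XY", events=[whole_chromosome_event(genome, "whole_chrom_gain", "chrY")])
    raise InvalidConfigError(f"unknown category {category!r}")


def _draw_meta(
    i: int, rng: np.random.Generator, group_mix: tuple[float, float], platform: str
) -> SpecimenMeta:
    sa = rng.random() < group_mix[0] / (group_mix[0] + group_mix[1])
    if sa:
        count, age_mu = 1, 30.47
    else:
        count = int(
            rng.choice(list(_RPL_COUNT_WEIGHTS), p=list(_RPL_COUNT_WEIGHTS.values()))
        )
        age_mu = {2: 31.63, 3: 32.43, 4: 33.95}[count]
        if count == 4:
            count = int(rng.integers(4, 7))
    age = float(np.clip(rng.normal(age_mu, 4.2), 21.0, 48.0))
    return SpecimenMeta(
        specimen_id=f"POC{i:04d}",
        group="SA" if sa else "RPL",
        miscarriage_count=count,
        maternal_age=round(age, 1),
        platform=platform,
    )


def simulate_cohort(
    genome: GenomeModel,
    n: int,
    spectrum: dict[str, float] | None = None,
    group_mix: tuple[float, float] = DEFAULT_GROUP_MIX,
    seed: int = 0,
    total_reads: int = 1_000_000,
    gc_bias: GcBiasCurve | None = None,
    baf_params: BafParams | None = None,
    seg_size_range: tuple[int, int] = (500_000, 2_000_000),
) -> list[SimulatedSpecimen]:
    """Simulate ``n`` specimens i.i.d. from a category spectrum.

    Ground truth is retained on every specimen for recovery scoring.
    Triploidy specimens are assigned the ``snp_array`` platform (triploidy is
    invisible to the depth-only channel, so only the allelic-channel arm can
    contribute such calls); all other specimens draw their platform from the
    cohort-wide SNP-array/CNV-seq split.
    """
    if n <= 0:
        raise InvalidConfigError(f"cohort size must be positive, got {n}")
    spectrum = dict(spectrum) if spectrum is not None else dict(DEFAULT_SPECTRUM)
    freqs = np.array(list(spectrum.values()), dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise InvalidConfigError(f"spectrum frequencies sum to {freqs.sum():.6f}, expected 1")
    for cat in spectrum:
        if cat not in CATEGORIES:
            raise InvalidConfigError(f"unknown spectrum category {cat!r}")
    rng = np.random.default_rng(seed)
    cats = list(spectrum)
    out: list[SimulatedSpecimen] = []
    for i in range(n):
        category = str(rng.choice(cats, p=freqs))
        truth = _draw_truth(category, genome, rng, seg_size_range)
        platform = (
            "snp_array"
            if truth.ploidy == "triploid"
            else ("snp_array" if rng.random() < _P_SNP_ARRAY else "cnv_seq")
        )
        meta = _draw_meta(i, rng, group_mix, platform)
        counts, baf = simulate_specimen(
            genome,
            truth,
            total_reads=total_reads,
            gc_bias=gc_bias,
            seed=int(rng.integers(0, 2**31 - 1)),
            baf_params=baf_params,
            specimen_id=meta.specimen_id,
        )
        out.append(SimulatedSpecimen(meta=meta, truth=truth, counts=counts, baf=baf))
    return out


def true_category(truth: KaryotypeSpec) -> str:
    """Map a ground-truth spec onto the reporting taxonomy (for scoring)."""
    if truth.ploidy == "triploid":
        return "mosaic_or_triploidy"
    whole = [e for e in truth.events if e.kind.startswith("whole_chrom")]
    if any(e.mosaic_fraction < 0.9 for e in whole):
        return "mosaic_or_triploidy"
    auto_gain = [e for e in whole if e.kind == "whole_chrom_gain" and is_autosome(e.chrom)]
    auto_loss = [e for e in whole if e.kind == "whole_chrom_loss" and is_autosome(e.chrom)]
    if auto_gain:
        return "autosomal_trisomy"
    if auto_loss:
        return "autosomal_monosomy"
    if any(e.kind == "whole_chrom_loss" and e.chrom == "chrX" for e in whole):
        return "monosomy_x"
    if any(not is_autosome(e.chrom) for e in whole):
        return "other"
    if any(e.kind.startswith("segmental") for e in truth.events):
        return "partial_imbalance"
    return "normal"
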