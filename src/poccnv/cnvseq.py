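"""Read-depth CNV calling core: binning, GC correction, circular binary segmentation.

The pipeline starts from per-bin read counts (alignment is upstream and out of
scope).  ``correct_counts`` turns raw counts into log2 copy-ratio profiles via
a three-step GC correction — LOESS of log depth on GC, intra-run median
normalisation, and a linear-model regression against a run reference —
and ``segment_cbs`` partitions each chromosome into constant-copy segments
with a permutation-tested circular binary segmentation (CBS).

Segment means are interpreted through the standard dosage model: a segment at
log2 ratio ``r`` in a diploid background corresponds to a mosaic fraction
``m = 2·(2^r − 1)`` for gains and ``m = 2·(1 − 2^r)`` for losses, so a
constitutional trisomy sits at log2(3/2) ≈ 0.585 and a constitutional
monosomy at −1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._cbs_kernel import max_arc_stat, perm_pvalue
from .errors import BoundsError, InvalidConfigError, SchemaError
from .genome import GenomeModel, is_autosome

log = logging.getLogger("poccnv")

GC_MASK_RANGE = (0.2, 0.8)  # bins with GC outside this range are masked


@dataclass
class BinnedCounts:
    """Raw integer read depth per genome bin for one specimen."""

    specimen_id: str
    counts: np.ndarray  # int64, length == genome.n_bins
    total_reads: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise SchemaError(f"negative bin count in specimen {self.specimen_id}")
        if int(self.counts.sum()) != int(self.total_reads):
            raise SchemaError(
                f"total_reads={self.total_reads} != sum(counts)={int(self.counts.sum())} "
                f"for specimen {self.specimen_id}"
            )


@dataclass
class CopyRatioProfile:
    """GC-corrected log2 copy-ratio per bin; masked bins are NaN and unusable."""

    specimen_id: str
    log2_ratio: np.ndarray  # float64, NaN where masked
    mask: np.ndarray  # bool, True = usable
    inferred_sex: str  # "XX" or "XY"
    correction_metadata: dict = field(default_factory=dict)


@dataclass
class Segment:
    """One CBS output interval (bin indices are chromosome-local, half-open)."""

    chrom: str
    start_bin: int
    end_bin: int
    mean_log2: float
    n_bins: int  # usable bins contributing to the mean
    start: int = 0  # bp
    end: int = 0  # bp
    flagged_short: bool = False


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def count_reads_to_bins(
    read_starts: Mapping[str, Sequence[int]], genome: GenomeModel, specimen_id: str = "specimen"
) -> BinnedCounts:
    """Assign read start positions to genome bins (half-open membership).

    ``read_starts`` maps chromosome name to an array of 0-based start
    positions.  A position outside ``[0, chrom_length)`` raises
    :class:`BoundsError`.
    """
    counts = np.zeros(genome.n_bins, dtype=np.int64)
    for chrom, positions in read_starts.items():
        pos = np.asarray(positions, dtype=np.int64)
        length = genome.chrom_length(chrom)
        if pos.size and (pos.min() < 0 or pos.max() >= length):
            bad = pos[(pos < 0) | (pos >= length)][0]
            raise BoundsError(f"read start {chrom}:{bad} outside [0, {length})")
        sl = genome.chrom_slice(chrom)
        n_chrom_bins = sl.stop - sl.start
        binned = np.bincount(pos // genome.bin_size, minlength=n_chrom_bins)
        counts[sl] += binned
    return BinnedCounts(specimen_id=specimen_id, counts=counts, total_reads=int(counts.sum()))


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------

def infer_sex(counts: BinnedCounts, genome: GenomeModel, min_y_fraction: float = 0.2) -> str:
    """Call XX/XY from the fraction of chrY bins with non-zero depth."""
    if "chrY" not in genome.chrom_names:
        return "XX"
    y = counts.counts[genome.chrom_slice("chrY")]
    if y.size == 0:
        return "XX"
    return "XY" if float(np.mean(y > 0)) >= min_y_fraction else "XX"


def _expected_dosage(genome: GenomeModel, sex: str) -> np.ndarray:
    """Expected copies relative to the diploid autosome (2 everywhere for XX
    except chrY=0; chrX=chrY=1 for XY)."""
    d = np.full(genome.n_bins, 2.0)
    if "chrX" in genome.chrom_names:
        d[genome.chrom_slice("chrX")] = 2.0 if sex == "XX" else 1.0
    if "chrY" in genome.chrom_names:
        d[genome.chrom_slice("chrY")] = 0.0 if sex == "XX" else 1.0
    return d


def correct_counts(
    run: Sequence[BinnedCounts],
    genome: GenomeModel,
    reference: np.ndarray | None = None,
    loess_span: float = 0.3,
) -> list[CopyRatioProfile]:
    """Three-step GC correction of a run of specimens.

    1. LOESS of log2 count against bin GC, fitted on usable autosomal bins of
       each specimen and subtracted (removes the unimodal GC-rate bias).
    2. Intra-run normalisation: each specimen shifted so its autosomal median
       matches the run median.
    3. Linear-model regression of each specimen's residuals on a per-bin run
       reference (median across specimens, or a supplied diploid baseline),
       residualised — removes bias shared across the run that LOESS on GC
       alone cannot capture.

    Bins with zero count or GC outside [0.2, 0.8] are masked.  Sex chromosomes
    are normalised against the dosage expected for the inferred sex (XX: chrX
    at ratio 1, chrY masked; XY: both at 1 after dosage adjustment).  A
    single-specimen run without a reference degrades to median-centering with
    a warning.  The returned profiles have |median autosomal log2| < 0.01.
    """
    if len(run) == 0:
        raise InvalidConfigError("correct_counts requires at least one specimen")
    auto = genome.autosomal_mask
    gc = genome.bin_gc
    gc_ok = (gc >= GC_MASK_RANGE[0]) & (gc <= GC_MASK_RANGE[1])

    resids: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    center_masks: list[np.ndarray] = []  # outlier-free autosomal bins for medians
    sexes: list[str] = []
    metas: list[dict] = []
    for bc in run:
        if bc.counts.size != genome.n_bins:
            raise SchemaError(
                f"specimen {bc.specimen_id}: {bc.counts.size} bins, genome has {genome.n_bins}"
            )
        if bc.total_reads == 0:
            raise SchemaError(f"specimen {bc.specimen_id} has zero total reads")
        sex = infer_sex(bc, genome)
        dosage = _expected_dosage(genome, sex)
        usable = (bc.counts > 0) & gc_ok & (dosage > 0)
        if not np.any(usable & auto):
            raise SchemaError(f"specimen {bc.specimen_id}: no usable autosomal bins")
        l2 = np.full(genome.n_bins, np.nan)
        l2[usable] = np.log2(bc.counts[usable].astype(float))
        fit_mask = usable & auto
        # step 1: LOESS over GC on autosomal bins, evaluated at every usable
        # bin.  Two passes: the first fit flags copy-altered outlier bins
        # (|residual| > 3 robust SD), which are excluded from the second fit so
        # a large CNV concentrated in one GC range cannot bend the trend.
        fitted = lowess(
            l2[fit_mask], gc[fit_mask], frac=loess_span, return_sorted=True, delta=0.002
        )
        trend = np.interp(gc, fitted[:, 0], fitted[:, 1])
        resid1 = l2[fit_mask] - trend[fit_mask]
        med = np.median(resid1)
        mad_sd = 1.4826 * np.median(np.abs(resid1 - med))
        keep = np.abs(resid1 - med) <= 3.0 * max(mad_sd, 1e-6)
        center = fit_mask.copy()
        if keep.sum() >= 50 and not keep.all():
            fitted = lowess(
                l2[fit_mask][keep], gc[fit_mask][keep],
                frac=loess_span, return_sorted=True, delta=0.002,
            )
            trend = np.interp(gc, fitted[:, 0], fitted[:, 1])
            center[np.flatnonzero(fit_mask)[~keep]] = False
        r = l2 - trend
        # dosage adjustment puts sex chromosomes on the diploid scale
        r[usable] -= np.log2(dosage[usable] / 2.0)
        resids.append(r)
        masks.append(usable)
        center_masks.append(center)
        sexes.append(sex)
        metas.append({"sex": sex, "loess_span": loess_span})

    # step 2: intra-run median normalisation (medians over outlier-free bins,
    # so a large CNV cannot drag its own specimen's centre)
    spec_medians = np.array(
        [np.nanmedian(r[c]) for r, c in zip(resids, center_masks)]
    )
    run_median = float(np.median(spec_medians))
    for r, sm in zip(resids, spec_medians):
        r += run_median - sm

    # step 3: regression on the run reference (leave-one-out per-bin median
    # across the other specimens, unless a baseline profile is supplied)
    ext_ref: np.ndarray | None = None
    if reference is not None:
        ext_ref = np.asarray(reference, dtype=float)
        if ext_ref.size != genome.n_bins:
            raise SchemaError("reference profile length does not match genome")
    elif len(run) < 2:
        warnings.warn(
            "single-specimen run without a reference: steps 2-3 degrade to median-centering",
            stacklevel=2,
        )
    stack = np.vstack(resids) if (ext_ref is None and len(run) >= 2) else None

    profiles: list[CopyRatioProfile] = []
    for idx, (r, m, c, sex, meta) in enumerate(
        zip(resids, masks, center_masks, sexes, metas)
    ):
        if ext_ref is not None:
            ref = ext_ref
        elif stack is not None:
            others = np.delete(stack, idx, axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ref = np.nanmedian(others, axis=0)
        else:
            ref = None
        if ref is not None:
            both = c & np.isfinite(ref)
            x, y = ref[both], r[both]
            vx = float(np.var(x))
            slope = float(np.cov(x, y, bias=True)[0, 1] / vx) if vx > 1e-12 else 0.0
            intercept = float(np.mean(y) - slope * np.mean(x))
            r = r - np.where(np.isfinite(ref), intercept + slope * ref, 0.0)
            meta["reference_slope"] = slope
            meta["reference_intercept"] = intercept
        # final centring: log2 ratio vs diploid expectation, median 0 over the
        # outlier-free autosomal bins
        r -= np.nanmedian(r[c])
        out = np.where(m, r, np.nan)
        profiles.append(
            CopyRatioProfile(
                specimen_id=run[idx].specimen_id,
                log2_ratio=out,
                mask=m,
                inferred_sex=sex,
                correction_metadata=meta,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

def _segment_chromosome(
    x: np.ndarray, alpha: float, n_perm: int, min_width: int, rng_seeds: np.ndarray
) -> list[tuple[int, int]]:
    """Recursive circular binary splitting of one chromosome's usable bins.

    Returns half-open (start, end) intervals in usable-bin coordinates.
    """
    out: list[tuple[int, int]] = []
    stack = [(0, x.size)]
    seed_idx = 0
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        n = seg.size
        if n < 2 * min_width:
            out.append((lo, hi))
            continue
        t_obs, i, j = max_arc_stat(seg, min_width)
        if t_obs <= 0.0:
            out.append((lo, hi))
            continue
        seed = int(rng_seeds[seed_idx % rng_seeds.size]) + seed_idx
        seed_idx += 1
        p = perm_pvalue(seg, t_obs, n_perm, alpha, min_width, seed)
        if p < alpha:
            parts = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
            for a, b in parts:
                if b > a:
                    stack.append((a, b))
        else:
            out.append((lo, hi))
    out.sort()
    return out


def segment_cbs(
    profile: CopyRatioProfile,
    genome: GenomeModel,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    merge_tol: float = 0.1,
    seed: int = 0,
) -> list[Segment]:
    """Circular binary segmentation of a corrected copy-ratio profile.

    For each current segment the two-arc mean-difference statistic is
    maximised over all (i, j) split pairs; a split is accepted when its
    permutation p-value (``n_perm`` shuffles of bin order, seeded) is below
    ``alpha``, and the algorithm recurses into the resulting parts.  Adjacent
    output segments whose means differ by less than ``merge_tol`` are
    re-merged.  A chromosome with fewer than ``2·min_width`` usable bins is
    returned as a single flagged segment.
    """
    if n_perm <= 0 or alpha <= 0 or alpha >= 1:
        raise InvalidConfigError("need n_perm > 0 and 0 < alpha < 1")
    segments: list[Segment] = []
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0xC0DE])
    chrom_seeds = ss.generate_state(len(genome.chromosomes) * 64).reshape(
        len(genome.chromosomes), 64
    ) & 0x7FFFFFFF
    for ci, (chrom, _) in enumerate(genome.chromosomes):
        sl = genome.chrom_slice(chrom)
        usable_idx = np.flatnonzero(profile.mask[sl]) + sl.start
        if usable_idx.size == 0:
            continue
        x = profile.log2_ratio[usable_idx]
        if usable_idx.size < 2 * min_width:
            segments.append(_make_segment(genome, chrom, usable_idx, x, 0, x.size, True))
            continue
        pieces = _segment_chromosome(x, alpha, n_perm, min_width, chrom_seeds[ci])
        # merge adjacent segments with near-equal means
        merged: list[tuple[int, int]] = []
        for lo, hi in pieces:
            if merged:
                plo, phi = merged[-1]
                if abs(np.mean(x[plo:phi]) - np.mean(x[lo:hi])) < merge_tol:
                    merged[-1] = (plo, hi)
                    continue
            merged.append((lo, hi))
        for lo, hi in merged:
            segments.append(_make_segment(genome, chrom, usable_idx, x, lo, hi, False))
    return segments


def _make_segment(
    genome: GenomeModel,
    chrom: str,
    usable_idx: np.ndarray,
    x: np.ndarray,
    lo: int,
    hi: int,
    flagged: bool,
) -> Segment:
    sl = genome.chrom_slice(chrom)
    first_bin = int(usable_idx[lo] - sl.start)
    last_bin = int(usable_idx[hi - 1] - sl.start)
    return Segment(
        chrom=chrom,
        start_bin=first_bin,
        end_bin=last_bin + 1,
        mean_log2=float(np.mean(x[lo:hi])),
        n_bins=hi - lo,
        start=int(genome.bin_start[usable_idx[lo]]),
        end=int(genome.bin_end[usable_idx[hi - 1]]),
        flagged_short=flagged,
    )


def estimate_mosaic_fraction(mean_log2: float, direction: str) -> float:
    """Mosaic (abnormal-cell) fraction implied by a segment mean log2 ratio.

    Diploid-baseline dosage model: a gain present in fraction ``m`` of cells
    has ratio ``(2+m)/2``, a loss ``(2−m)/2``; inverting gives
    ``m = 2·(2^r − 1)`` (gain) and ``m = 2·(1 − 2^r)`` (loss).  The result is
    clipped to [0, 1.5]; values above 1.1 indicate a multi-copy event
    (possible tetrasomy) and are flagged by callers.
    """
    if direction == "gain":
        m = 2.0 * (2.0 ** mean_log2 - 1.0)
    elif direction == "loss":
        m = 2.0 * (1.0 - 2.0 ** mean_log2)
    else:
        raise InvalidConfigError(f"direction must be 'gain' or 'loss', got {direction!r}")
    return float(np.clip(m, 0.0, 1.5))
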