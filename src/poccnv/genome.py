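"""Genome model: chromosome sizes, fixed-width bins with GC content, cytobands.

Every depth profile in the package shares one :class:`GenomeModel` coordinate
frame: fixed-width half-open bins (default 20 kb, the resolution at which
low-coverage CNV-seq reads are counted) tiling each chromosome, a GC fraction
per bin, and a cytoband table used to label calls (e.g. ``16q24.3``).

Two presets are provided.  ``"hg19"`` uses the GRCh37 chromosome lengths at
full scale.  ``"miniature"`` (the default, and the scale all tests run at)
shrinks every chromosome to 1/20 of its hg19 length so that a whole genome is
~155 Mb / ~7,700 bins and a simulated cohort is a desk-scale computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, InvalidConfigError

# GRCh37 / hg19 chromosome lengths in bp.
HG19_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}

MINIATURE_SCALE = 20  # miniature preset: hg19 lengths divided by this

SEX_CHROMS = ("chrX", "chrY")


def is_autosome(chrom: str) -> bool:
    return chrom not in SEX_CHROMS


@dataclass
class GenomeConfig:
    """Configuration for :func:`build_genome`.

    Parameters
    ----------
    preset:
        ``"miniature"`` (hg19/20) or ``"hg19"``; ignored when ``chromosomes``
        is given explicitly.
    chromosomes:
        Optional explicit ``[(name, length_bp), ...]`` list.
    bin_size:
        Bin width in bp (default 20,000).
    gc_range:
        The simulated GC field is a smooth random field mapped into this
        interval (default [0.3, 0.6], the bulk of the human GC distribution).
    gc_smooth_bins:
        Moving-average window (in bins) of the GC field; larger = smoother.
    gc_seed:
        Seed of the GC field generator; a fixed seed gives a fixed genome.
    gc_track:
        Optional explicit per-chromosome GC arrays (overrides simulation).
    cytobands:
        Optional explicit band table ``[(chrom, start, end, band), ...]``;
        when absent a synthetic banding (p/q arms around a centromere at 40%
        of the chromosome) is generated.
    bands_per_arm:
        Number of synthetic bands per chromosome arm (default 6).
    """

    preset: str = "miniature"
    chromosomes: Sequence[tuple[str, int]] | None = None
    bin_size: int = 20_000
    gc_range: tuple[float, float] = (0.3, 0.6)
    gc_smooth_bins: int = 50
    gc_seed: int = 0
    gc_track: Mapping[str, np.ndarray] | None = None
    cytobands: Sequence[tuple[str, int, int, str]] | None = None
    bands_per_arm: int = 6


@dataclass
class GenomeModel:
    """Binned genome coordinate frame shared by all profiles.

    Bins are stored as flat arrays concatenated in chromosome order;
    ``chrom_slice(name)`` returns the slice of the flat arrays belonging to
    one chromosome.  All coordinates are 0-based half-open.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int
    bin_chrom: np.ndarray  # str array, one entry per bin
    bin_start: np.ndarray  # int64
    bin_end: np.ndarray  # int64
    bin_gc: np.ndarray  # float64 in [0, 1]
    cytobands: pd.DataFrame  # columns: chrom, start, end, band
    _offsets: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._offsets:
            lo = 0
            for name, _ in self.chromosomes:
                n = int(np.sum(self.bin_chrom == name))
                self._offsets[name] = (lo, lo + n)
                lo += n

    # -- basic accessors -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return int(self.bin_start.size)

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise BoundsError(f"unknown chromosome {chrom!r}")

    def chrom_slice(self, chrom: str) -> slice:
        if chrom not in self._offsets:
            raise BoundsError(f"unknown chromosome {chrom!r}")
        lo, hi = self._offsets[chrom]
        return slice(lo, hi)

    @property
    def autosomal_mask(self) -> np.ndarray:
        return np.array([is_autosome(c) for c in self.bin_chrom])

    def chrom_mask(self, chrom: str) -> np.ndarray:
        m = np.zeros(self.n_bins, dtype=bool)
        m[self.chrom_slice(chrom)] = True
        return m

    def bins_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.bin_chrom,
                "start": self.bin_start,
                "end": self.bin_end,
                "gc": self.bin_gc,
            }
        )

    def bin_index(self, chrom: str, pos: int) -> int:
        """Flat index of the bin containing ``pos`` (half-open membership)."""
        length = self.chrom_length(chrom)
        if pos < 0 or pos >= length:
            raise BoundsError(f"position {chrom}:{pos} outside [0, {length})")
        lo, _ = self._offsets[chrom]
        return lo + int(pos) // self.bin_size

    def band_at(self, chrom: str, pos: int) -> str:
        """Cytoband label (e.g. ``q24.3``) containing ``pos``."""
        tab = self.cytobands
        rows = tab[(tab["chrom"] == chrom) & (tab["start"] <= pos) & (pos < tab["end"])]
        if rows.empty:
            raise BoundsError(f"no cytoband covers {chrom}:{pos}")
        return str(rows.iloc[0]["band"])


def _tile(length: int, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, bin_size, dtype=np.int64)
    ends = np.minimum(starts + bin_size, length)
    return starts, ends


def _smooth_gc_field(n: int, rng: np.random.Generator, window: int, lo: float, hi: float) -> np.ndarray:
    """Smooth random field in [lo, hi]: moving-average of white noise, rescaled."""
    window = max(1, min(window, n))
    raw = rng.standard_normal(n + window)
    kernel = np.ones(window) / window
    smooth = np.convolve(raw, kernel, mode="valid")[:n]
    # squash to (-1, 1) then map affinely; tanh keeps the field inside the range
    # without the hard clipping a min-max rescale of a short chromosome would need
    z = np.tanh(smooth * np.sqrt(window) / 2.0)
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    return mid + half * z


def _synthetic_cytobands(
    chromosomes: Sequence[tuple[str, int]], bands_per_arm: int
) -> pd.DataFrame:
    """Plausible ISCN-style banding: centromere at 40%, bands numbered outward.

    p-arm bands run telomere→centromere with numbers descending toward the
    centromere (``p21, p13, p12, p11`` style); q-arm bands ascend away from it.
    Bands are contiguous and cover [0, length).
    """
    rows = []
    for chrom, length in chromosomes:
        cen = int(length * 0.4)
        short = chrom.lstrip("chr")
        for arm, lo, hi in (("p", 0, cen), ("q", cen, length)):
            k = max(1, bands_per_arm)
            edges = np.linspace(lo, hi, k + 1).astype(np.int64)
            labels = [f"{arm}{1 + i // 3}{1 + i % 3}" for i in range(k)]
            if arm == "p":
                # outward numbering: highest label at the telomere (coordinate 0)
                labels = labels[::-1]
            for i in range(k):
                rows.append((chrom, int(edges[i]), int(edges[i + 1]), labels[i]))
        _ = short
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "band"])


def build_genome(config: GenomeConfig | None = None) -> GenomeModel:
    """Build a tiled :class:`GenomeModel` from a :class:`GenomeConfig`.

    Raises :class:`InvalidConfigError` on non-positive bin size or chromosome
    length.  The GC field is deterministic under a fixed ``gc_seed``.
    """
    config = config or GenomeConfig()
    if config.bin_size <= 0:
        raise InvalidConfigError(f"bin_size must be positive, got {config.bin_size}")
    if config.chromosomes is not None:
        chroms = [(str(c), int(n)) for c, n in config.chromosomes]
    elif config.preset == "miniature":
        chroms = [(c, n // MINIATURE_SCALE) for c, n in HG19_LENGTHS.items()]
    elif config.preset == "hg19":
        chroms = list(HG19_LENGTHS.items())
    else:
        raise InvalidConfigError(f"unknown preset {config.preset!r}")
    for name, length in chroms:
        if length <= 0:
            raise InvalidConfigError(f"chromosome {name} has non-positive length {length}")
    lo, hi = config.gc_range
    if not (0.0 <= lo < hi <= 1.0):
        raise InvalidConfigError(f"gc_range must satisfy 0 <= lo < hi <= 1, got {config.gc_range}")

    rng = np.random.default_rng(config.gc_seed)
    chrom_arr, starts, ends, gcs = [], [], [], []
    for name, length in chroms:
        s, e = _tile(length, config.bin_size)
        if config.gc_track is not None:
            gc = np.asarray(config.gc_track[name], dtype=float)
            if gc.size != s.size:
                raise InvalidConfigError(
                    f"gc_track for {name} has {gc.size} values, expected {s.size}"
                )
            if np.any((gc < 0) | (gc > 1)):
                raise InvalidConfigError(f"gc_track for {name} outside [0, 1]")
        else:
            gc = _smooth_gc_field(s.size, rng, config.gc_smooth_bins, lo, hi)
        chrom_arr.append(np.full(s.size, name, dtype=object))
        starts.append(s)
        ends.append(e)
        gcs.append(gc)

    if config.cytobands is not None:
        bands = pd.DataFrame(config.cytobands, columns=["chrom", "start", "end", "band"])
        _validate_cytobands(bands, chroms)
    else:
        bands = _synthetic_cytobands(chroms, config.bands_per_arm)

    return GenomeModel(
        chromosomes=chroms,
        bin_size=config.bin_size,
        bin_chrom=np.concatenate(chrom_arr),
        bin_start=np.concatenate(starts),
        bin_end=np.concatenate(ends),
        bin_gc=np.concatenate(gcs),
        cytobands=bands,
    )


def _validate_cytobands(bands: pd.DataFrame, chroms: Sequence[tuple[str, int]]) -> None:
    lengths = dict(chroms)
    for chrom, grp in bands.groupby("chrom"):
        if chrom not in lengths:
            raise InvalidConfigError(f"cytoband table names unknown chromosome {chrom!r}")
        grp = grp.sort_values("start")
        if int(grp.iloc[0]["start"]) != 0 or int(grp.iloc[-1]["end"]) != lengths[chrom]:
            raise InvalidConfigError(f"cytobands do not cover {chrom}")
        if not np.all(grp["end"].to_numpy()[:-1] == grp["start"].to_numpy()[1:]):
            raise InvalidConfigError(f"cytobands overlap or leave gaps on {chrom}")
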