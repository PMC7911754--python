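"""File formats, packaged fixtures and run configuration.

All interval formats are 0-based half-open.  Column layouts:

* counts TSV:    ``chrom  start  end  count``
* BAF TSV:       ``chrom  pos  baf``
* manifest CSV:  ``specimen_id,group,miscarriage_count,maternal_age,platform``
* segments BED:  ``chrom  start  end  mean_log2  n_bins``
* calls BED:     ``chrom  start  end  type|cytoband|mosaic_fraction  size``
* truth JSON:    serialised :class:`~poccnv.simulate.KaryotypeSpec`
* tables CSV:    :class:`~poccnv.cohort.CohortTables` frames as written

Packaged fixtures under ``poccnv/data`` hold the printed count tables of a
1556-case POC miscarriage series (stratified outcome counts and the CNV
catalogue summary) and a synthetic toy GMT for exercising the enrichment
statistic.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnvseq import BinnedCounts, Segment
from .classify import CnvCall
from .enrichment import GeneSetCollection, read_gmt
from .errors import BoundsError, InvalidConfigError, SchemaError
from .genome import GenomeModel
from .simulate import BafProfile, Event, KaryotypeSpec, SpecimenMeta

COUNTS_COLUMNS = ["chrom", "start", "end", "count"]
BAF_COLUMNS = ["chrom", "pos", "baf"]
MANIFEST_COLUMNS = ["specimen_id", "group", "miscarriage_count", "maternal_age", "platform"]


def _require_columns(df: pd.DataFrame, needed: list[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# -- counts ------------------------------------------------------------------

def write_counts_tsv(counts: BinnedCounts, genome: GenomeModel, path) -> None:
    df = genome.bins_frame()[["chrom", "start", "end"]].copy()
    df["count"] = counts.counts
    df.to_csv(path, sep="\t", index=False)

def read_counts_tsv(path, genome: GenomeModel, specimen_id: str | None = None) -> BinnedCounts:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, COUNTS_COLUMNS, path)
    if len(df) != genome.n_bins:
        raise SchemaError(f"{path}: {len(df)} rows, genome has {genome.n_bins} bins")
    if (df["count"] < 0).any():
        row = int(df.index[df["count"] < 0][0]) + 2  # header is line 1
        raise SchemaError(f"{path}: negative count at line {row}")
    if not (df["chrom"].to_numpy() == genome.bin_chrom).all():
        raise SchemaError(f"{path}: bin chromosomes do not match the genome model")
    if not (df["start"].to_numpy() == genome.bin_start).all():
        raise SchemaError(f"{path}: bin starts do not match the genome model")
    counts = df["count"].to_numpy(dtype=np.int64)
    return BinnedCounts(
        specimen_id=specimen_id or Path(path).stem,
        counts=counts,
        total_reads=int(counts.sum()),
    )


# -- BAF ---------------------------------------------------------------------

def write_baf_tsv(baf: BafProfile, path) -> None:
    pd.DataFrame({"chrom": baf.chrom, "pos": baf.pos, "baf": baf.baf}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )

def read_baf_tsv(path, genome: GenomeModel | None = None, markers_per_mb: float = 0.0) -> BafProfile:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, BAF_COLUMNS, path)
    if ((df["baf"] < 0) | (df["baf"] > 1)).any():
        raise SchemaError(f"{path}: BAF outside [0, 1]")
    if genome is not None:
        for chrom, grp in df.groupby("chrom"):
            length = genome.chrom_length(str(chrom))
            bad = grp[(grp["pos"] < 0) | (grp["pos"] >= length)]
            if len(bad):
                p = int(bad.iloc[0]["pos"])
                raise BoundsError(f"{path}: marker {chrom}:{p} outside [0, {length})")
    return BafProfile(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        baf=df["baf"].to_numpy(dtype=float),
        markers_per_mb=markers_per_mb,
    )


# -- manifest ----------------------------------------------------------------

def write_manifest_csv(metas: list[SpecimenMeta], path) -> None:
    pd.DataFrame([asdict(m) for m in metas])[MANIFEST_COLUMNS].to_csv(path, index=False)

def read_manifest_csv(path) -> list[SpecimenMeta]:
    df = pd.read_csv(path)
    _require_columns(df, MANIFEST_COLUMNS, path)
    return [
        SpecimenMeta(
            specimen_id=str(r["specimen_id"]),
            group=str(r["group"]),
            miscarriage_count=int(r["miscarriage_count"]),
            maternal_age=float(r["maternal_age"]),
            platform=str(r["platform"]),
        )
        for _, r in df.iterrows()
    ]


# -- segments / calls BED ----------------------------------------------------

def write_segments_bed(segments: list[Segment], path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.mean_log2:.6g}\t{s.n_bins}\n")

def read_segments_bed(path) -> list[Segment]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise SchemaError(f"{path}:{ln}: expected 5 BED columns, got {len(parts)}")
            chrom, start, end, mean, nb = parts
            out.append(
                Segment(
                    chrom=chrom, start_bin=0, end_bin=0,
                    mean_log2=float(mean), n_bins=int(nb), start=int(start), end=int(end),
                )
            )
    return out


def write_calls_bed(calls: list[CnvCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            name = f"{c.type}|{c.cytoband}|{c.mosaic_fraction:.4g}"
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{c.size}\n")

def read_calls_bed(path) -> list[CnvCall]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise SchemaError(f"{path}:{ln}: expected 5 BED columns, got {len(parts)}")
            chrom, start, end, name, size = parts
            try:
                ctype, band, mosaic = name.split("|")
            except ValueError as exc:
                raise SchemaError(f"{path}:{ln}: malformed call name {name!r}") from exc
            out.append(
                CnvCall(
                    chrom=chrom, start=int(start), end=int(end), type=ctype,
                    size=int(size), mosaic_fraction=float(mosaic), cytoband=band,
                )
            )
    return out


# -- truth JSON --------------------------------------------------------------

def write_truth_json(truth: KaryotypeSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1)

def read_truth_json(path) -> KaryotypeSpec:
    with open(path) as fh:
        d = json.load(fh)
    return KaryotypeSpec(
        sex=d["sex"],
        events=[Event(**e) for e in d.get("events", [])],
        ploidy=d.get("ploidy", "diploid"),
        mcc_fraction=float(d.get("mcc_fraction", 0.0)),
        loh_regions=[tuple(r) for r in d.get("loh_regions", [])],
    )


# -- packaged fixtures -------------------------------------------------------

def _data_path(name: str):
    return resources.files("poccnv").joinpath("data", name)

def load_table1_counts() -> pd.DataFrame:
    """Stratified cohort counts (n, mean age, normal/abnormal) of the
    packaged 1556-case POC series."""
    with resources.as_file(_data_path("table1_counts.csv")) as p:
        return pd.read_csv(p, dtype={"stratum": str})

def load_table2_counts() -> pd.DataFrame:
    """Stratified abnormal-category counts of the packaged series."""
    with resources.as_file(_data_path("table2_counts.csv")) as p:
        return pd.read_csv(p, dtype={"stratum": str})

def load_cnv_catalogue() -> pd.DataFrame:
    """CNV catalogue summary of the packaged series (duplication/deletion
    totals and the two recurrent chromosome-16 duplications' carrier counts)."""
    with resources.as_file(_data_path("cnv_catalogue.csv")) as p:
        return pd.read_csv(p)

def load_toy_gmt() -> GeneSetCollection:
    """Synthetic toy gene-set collection for exercising the enrichment test."""
    with resources.as_file(_data_path("toy_pathways.gmt")) as p:
        return read_gmt(p)


# -- run configuration -------------------------------------------------------

_KNOWN_SECTIONS = {"genome", "simulate", "cbs", "criteria", "seed", "output_dir"}


def load_run_config(path) -> dict:
    """Load a YAML/JSON run configuration, rejecting unknown top-level keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidConfigError(f"{path}: run config must be a mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise InvalidConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    return cfg
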