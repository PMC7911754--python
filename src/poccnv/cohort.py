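"""Cohort aggregation: summary tables, age stratification, recurrent-CNV
clustering and SA-vs-RPL association tests.

Percentage conventions follow the reporting style of clinical POC series:
whole-cohort percentages (miscarriage-count strata, normal/abnormal rates)
are printed to 2 decimals with the cohort size as denominator; abnormal-
category percentages use the total number of abnormal specimens as
denominator and are printed as integers.  All rounding is half-up.

The association test between carrier frequencies in the sporadic-abortion
(SA) and recurrent-pregnancy-loss (RPL) groups uses Fisher's exact test
(minimum-likelihood two-sided, computed in exact integer arithmetic by
hypergeometric tail summation) whenever any expected cell count is below 5,
and the Pearson chi-square test otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .classify import CnvCall, SpecimenResult
from .errors import InvalidConfigError
from .genome import GenomeModel
from .simulate import SpecimenMeta

log = logging.getLogger("poccnv")

ABNORMAL_CATEGORIES = (
    "autosomal_trisomy",
    "autosomal_monosomy",
    "mosaic_or_triploidy",
    "partial_imbalance",
    "monosomy_x",
    "other",
)

STRATA = ("1", "2", "3", "4+")


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (2.5 -> 3), as printed clinical tables use."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(num: int, den: int, decimals: int) -> float:
    return round_half_up(100.0 * num / den, decimals) if den else float("nan")


@dataclass
class CohortTables:
    """Miscarriage-count-stratified cohort summary.

    ``table1``: per stratum — cohort share, mean maternal age, normal and
    abnormal counts with whole-cohort percentages (2 decimals).
    ``table2``: per stratum — abnormal-category counts with percentages of
    all abnormal specimens (integer).
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    n_cohort: int
    n_abnormal: int
    excluded: int = 0


def _stratum(count: int) -> str:
    return str(count) if count < 4 else "4+"


def build_cohort_tables(
    results: Sequence[SpecimenResult], metas: Sequence[SpecimenMeta]
) -> CohortTables:
    """Aggregate specimen results into the stratified cohort tables.

    Specimens without a category (QC-excluded) are dropped with a warning and
    counted in ``excluded``.
    """
    if len(results) != len(metas):
        raise InvalidConfigError("results and metas must be parallel lists")
    rows = []
    excluded = 0
    for res, meta in zip(results, metas):
        if res.category is None:
            excluded += 1
            continue
        rows.append(
            {
                "stratum": _stratum(meta.miscarriage_count),
                "age": meta.maternal_age,
                "category": res.category,
            }
        )
    if excluded:
        log.warning("%d specimens excluded from cohort tables (no category)", excluded)
    df = pd.DataFrame(rows)
    n_cohort = len(df)
    t1_counts = []
    t2_counts = []
    for s in STRATA:
        sub = df[df["stratum"] == s]
        normal = int((sub["category"] == "normal").sum())
        t1_counts.append(
            {
                "stratum": s,
                "n": len(sub),
                "mean_age": round_half_up(sub["age"].mean(), 2) if len(sub) else float("nan"),
                "normal": normal,
                "abnormal": len(sub) - normal,
            }
        )
        t2_counts.append(
            {"stratum": s, **{c: int((sub["category"] == c).sum()) for c in ABNORMAL_CATEGORIES}}
        )
    return tables_from_counts(pd.DataFrame(t1_counts), pd.DataFrame(t2_counts), excluded=excluded)


def tables_from_counts(
    table1_counts: pd.DataFrame, table2_counts: pd.DataFrame, excluded: int = 0
) -> CohortTables:
    """Recompute all table percentages from raw per-stratum counts.

    ``table1_counts`` needs columns ``stratum, n, mean_age, normal, abnormal``
    (``mean_age`` optional); ``table2_counts`` needs ``stratum`` plus one
    column per abnormal category.  This is also the fixture-driven entry
    point used to reproduce a printed table from its counts.
    """
    t1 = table1_counts.copy()
    t2 = table2_counts.copy()
    n_cohort = int(t1["n"].sum())
    n_abnormal = int(t1["abnormal"].sum())
    if "mean_age" not in t1.columns:
        t1["mean_age"] = float("nan")

    out1 = []
    for _, r in t1.iterrows():
        out1.append(
            {
                "stratum": r["stratum"],
                "n": int(r["n"]),
                "frequency_pct": _pct(int(r["n"]), n_cohort, 2),
                "mean_age": r["mean_age"],
                "normal_n": int(r["normal"]),
                "normal_pct": _pct(int(r["normal"]), n_cohort, 2),
                "abnormal_n": int(r["abnormal"]),
                "abnormal_pct": _pct(int(r["abnormal"]), n_cohort, 2),
            }
        )
    out1.append(
        {
            "stratum": "total",
            "n": n_cohort,
            "frequency_pct": 100.0,
            "mean_age": float("nan"),
            "normal_n": int(t1["normal"].sum()),
            "normal_pct": _pct(int(t1["normal"].sum()), n_cohort, 2),
            "abnormal_n": n_abnormal,
            "abnormal_pct": _pct(n_abnormal, n_cohort, 2),
        }
    )

    cats = [c for c in ABNORMAL_CATEGORIES if c in t2.columns]
    out2 = []
    for _, r in t2.iterrows():
        row_abn = int(sum(r[c] for c in cats))
        row = {
            "stratum": r["stratum"],
            "abnormal_n": row_abn,
            "abnormal_pct": _pct(row_abn, n_abnormal, 0),
        }
        for c in cats:
            row[f"{c}_n"] = int(r[c])
            row[f"{c}_pct"] = _pct(int(r[c]), n_abnormal, 0)
        out2.append(row)
    total_row = {
        "stratum": "total",
        "abnormal_n": n_abnormal,
        "abnormal_pct": _pct(n_abnormal, n_abnormal, 0),
    }
    for c in cats:
        total_row[f"{c}_n"] = int(t2[c].sum())
        total_row[f"{c}_pct"] = _pct(int(t2[c].sum()), n_abnormal, 0)
    out2.append(total_row)

    return CohortTables(
        table1=pd.DataFrame(out1),
        table2=pd.DataFrame(out2),
        n_cohort=n_cohort,
        n_abnormal=n_abnormal,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# age stratification
# ---------------------------------------------------------------------------

AGE_BIN_LABELS = ("<30", "30-34", ">=35")


def age_bin(age: float, edges: tuple[float, float] = (30.0, 35.0)) -> str:
    """Closed-on-left age bins: age 29 -> '<30', 30 and 34 -> '30-34', 35 -> '>=35'."""
    if age < edges[0]:
        return AGE_BIN_LABELS[0]
    if age < edges[1]:
        return AGE_BIN_LABELS[1]
    return AGE_BIN_LABELS[2]


def stratify_by_age(
    results: Sequence[SpecimenResult],
    metas: Sequence[SpecimenMeta],
    edges: tuple[float, float] = (30.0, 35.0),
) -> pd.DataFrame:
    """Abnormality rate per (group, age bin) with counts and denominators.

    Empty cells report ``rate = NaN`` (undefined), never 0.
    """
    rows = []
    for group in ("SA", "RPL"):
        for label in AGE_BIN_LABELS:
            n = abn = 0
            for res, meta in zip(results, metas):
                if res.category is None or meta.group != group:
                    continue
                if age_bin(meta.maternal_age, edges) != label:
                    continue
                n += 1
                abn += res.category != "normal"
            rows.append(
                {
                    "group": group,
                    "age_bin": label,
                    "n": n,
                    "abnormal_n": abn,
                    "rate": abn / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recurrent-CNV clustering
# ---------------------------------------------------------------------------

@dataclass
class RecurrentCluster:
    chrom: str
    start: int
    end: int
    cytoband: str
    type: str  # dup | del
    members: list[CnvCall] = field(default_factory=list)
    count_rpl: int = 0
    count_sa: int = 0

    @property
    def n(self) -> int:
        return self.count_rpl + self.count_sa

    @property
    def recurrent(self) -> bool:
        return self.n >= 2


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_recurrent_cnvs(
    calls: Sequence[CnvCall],
    groups: Sequence[str],
    overlap_frac: float = 0.5,
    by_cytoband: bool = False,
    genome: GenomeModel | None = None,
) -> list[RecurrentCluster]:
    """Single-linkage clustering of CNV calls across the cohort.

    Calls of the same type (dup with dup, del with del) are linked when their
    reciprocal overlap is at least ``overlap_frac`` (or, with
    ``by_cytoband=True``, when they share a cytoband label).  The
    representative region is the intersection of the members (the interval of
    the member nearest the cluster's median midpoint when a single-linkage
    chain leaves the intersection empty).  Output order and membership are
    invariant to the input order of the calls.
    """
    if len(calls) != len(groups):
        raise InvalidConfigError("calls and groups must be parallel lists")
    order = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].type, calls[i].start, calls[i].end))
    uf = _UnionFind(len(calls))
    for oi in range(len(order)):
        i = order[oi]
        for oj in range(oi + 1, len(order)):
            j = order[oj]
            a, b = calls[i], calls[j]
            if (a.chrom, a.type) != (b.chrom, b.type):
                break
            if by_cytoband:
                if a.cytoband == b.cytoband:
                    uf.union(i, j)
            else:
                if b.start >= a.end:
                    break  # later calls start even further right
                if _reciprocal_overlap(a, b) >= overlap_frac:
                    uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(calls)):
        clusters.setdefault(uf.find(i), []).append(i)

    out: list[RecurrentCluster] = []
    for idxs in clusters.values():
        members = [calls[i] for i in idxs]
        start = max(c.start for c in members)
        end = min(c.end for c in members)
        if start >= end:  # chained members with empty intersection
            mids = sorted((c.start + c.end) // 2 for c in members)
            med = mids[len(mids) // 2]
            rep = min(members, key=lambda c: abs((c.start + c.end) // 2 - med))
            start, end = rep.start, rep.end
        chrom = members[0].chrom
        if genome is not None:
            short = chrom.removeprefix("chr")
            band = f"{short}{genome.band_at(chrom, (start + end) // 2)}"
        else:
            bands = sorted(c.cytoband for c in members)
            band = bands[len(bands) // 2]
        out.append(
            RecurrentCluster(
                chrom=chrom,
                start=start,
                end=end,
                cytoband=band,
                type=members[0].type,
                members=sorted(members, key=lambda c: (c.start, c.end)),
                count_rpl=sum(1 for i in idxs if groups[i] == "RPL"),
                count_sa=sum(1 for i in idxs if groups[i] == "SA"),
            )
        )
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.type))
    return out


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    test_name: str  # chi2 | fisher
    statistic: float | None
    p_value: float
    odds_ratio: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by hypergeometric tail summation.

    Exact integer arithmetic: with fixed margins, outcome probabilities are
    proportional to C(r1, k)·C(r2, c1−k); the two-sided p sums the
    probabilities of all outcomes no more likely than the observed one
    (minimum-likelihood method).  A degenerate (zero) margin gives p = 1.
    """
    (a, b), (c, d) = ((int(x) for x in row) for row in table)
    if min(a, b, c, d) < 0:
        raise InvalidConfigError("2x2 table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if lo == hi:
        return 1.0
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return float(Fraction(num, sum(weights)))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def compare_counts(
    carriers_rpl: int, n_rpl: int, carriers_sa: int, n_sa: int
) -> TestResult:
    """SA-vs-RPL carrier-frequency test on the 2x2 table.

    Fisher's exact test when any expected or observed cell count is below 5
    (the chi-square approximation is unreliable in either case), otherwise
    the Pearson chi-square test (two-sided, no continuity correction).
    """
    if carriers_rpl > n_rpl or carriers_sa > n_sa:
        raise InvalidConfigError("carrier count exceeds group size")
    a, b = carriers_rpl, n_rpl - carriers_rpl
    c, d = carriers_sa, n_sa - carriers_sa
    table = ((a, b), (c, d))
    n = a + b + c + d
    orr = _odds_ratio(a, b, c, d)
    row = (a + b, c + d)
    col = (a + c, b + d)
    if 0 in row or 0 in col or n == 0:
        return TestResult("fisher", None, 1.0, orr, table)
    expected = min(r * cc / n for r in row for cc in col)
    if expected < 5 or min(a, b, c, d) < 5:
        return TestResult("fisher", None, fisher_exact_2x2(table), orr, table)
    stat, p, _, _ = chi2_contingency(np.array(table), correction=False)
    return TestResult("chi2", float(stat), float(p), orr, table)


def compare_cnv_frequency(cluster: RecurrentCluster, n_rpl: int, n_sa: int) -> TestResult:
    """Association test for one recurrent-CNV cluster's carrier counts."""
    return compare_counts(cluster.count_rpl, n_rpl, cluster.count_sa, n_sa)
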