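"""Hypergeometric gene-set over-representation with BH adjustment.

Given a query gene list (e.g. the genes inside candidate CNV regions) and a
collection of gene sets in GMT form, each set is scored with the upper-tail
hypergeometric probability P(X >= k) of drawing at least the observed overlap
``k`` when ``n`` query genes are sampled without replacement from a universe
of ``N`` genes containing ``K`` set members.  P-values are adjusted across
all sets with the Benjamini-Hochberg procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InvalidConfigError, SchemaError

log = logging.getLogger("poccnv")


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Gene sets plus the background universe.

    When no universe is given it defaults to the union of all set members.
    Set members outside the universe are dropped; duplicate symbols within a
    set are collapsed.
    """

    sets: list[GeneSet]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset(g for s in self.sets for g in s.members)
        filtered = []
        for s in self.sets:
            members = tuple(sorted(set(s.members) & self.universe))
            filtered.append(GeneSet(s.set_id, s.description, members))
        self.sets = filtered


@dataclass
class EnrichmentRow:
    set_id: str
    description: str
    k: int  # overlap
    K: int  # set size
    n: int  # query size (after universe filtering)
    N: int  # universe size
    p_value: float
    adjusted_p: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not 0 <= k <= min(K, n):
        raise InvalidConfigError(f"overlap k={k} impossible for K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str], collection: GeneSetCollection, adjust: str = "fdr_bh"
) -> list[EnrichmentRow]:
    """Over-representation test of a query gene list against a collection.

    Query symbols outside the universe are dropped with a warning.  Rows are
    sorted by adjusted p, ties broken by set id.  An empty filtered query
    returns an empty list.
    """
    query_set = set(query)
    dropped = query_set - collection.universe
    if dropped:
        log.warning("%d query genes outside the universe were dropped", len(dropped))
    query_set &= collection.universe
    if not query_set:
        log.warning("empty query after universe filtering; no enrichment computed")
        return []
    N = len(collection.universe)
    n = len(query_set)
    rows = []
    for s in collection.sets:
        K = len(s.members)
        k = len(query_set.intersection(s.members))
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append(EnrichmentRow(s.set_id, s.description, k, K, n, N, p, p))
    if rows:
        _, adj, _, _ = multipletests([r.p_value for r in rows], method=adjust)
        for r, a in zip(rows, adj):
            r.adjusted_p = float(a)
    rows.sort(key=lambda r: (r.adjusted_p, r.set_id))
    return rows


# ---------------------------------------------------------------------------
# GMT format
# ---------------------------------------------------------------------------

def read_gmt(path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: id, description, member genes...)."""
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{ln}: GMT line needs id, description and >=1 gene")
            sets.append(GeneSet(parts[0], parts[1], tuple(parts[2:])))
    return GeneSetCollection(sets, frozenset(universe) if universe else frozenset())


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join((s.set_id, s.description, *s.members)) + "\n")
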