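"""Hypergeometric gene-set over-representation analysis.

Given a query gene list and a GMT collection, each set is scored with
the upper-tail hypergeometric probability P(X >= k) of observing at
least the seen overlap k, where X ~ Hypergeometric(N, K, n) with N the
universe size, K the set size and n the query size within the universe.
The tail includes the observed k (the standard over-representation
convention). q-values come from the same BH routine as the
differential-expression stage, and ``top(10)`` mirrors the common
report of the ten most significant categories.

The universe defaults to the union of all annotated genes in the
collection; query genes outside it are dropped and logged, never
silently discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .errors import InputError, ParseError
from .diffexp import fdr_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with descriptions and an annotation universe."""

    sets: dict
    descriptions: dict
    universe: frozenset

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")
            if not members <= self.universe:
                raise InputError(f"gene set {name!r} not within universe")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Parse a standard GMT file (name, description, members...).

    Duplicate members within a set are collapsed. The universe is the
    union of all members unless ``universe`` (an iterable of gene ids)
    overrides it; sets are then intersected with that universe.
    """
    path = Path(path)
    sets, descriptions = {}, {}
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path.name}:{lineno}: GMT line needs at "
                             "least 3 tab-separated fields")
        name, description = fields[0], fields[1]
        if name in sets:
            raise ParseError(f"{path.name}:{lineno}: duplicate set name "
                             f"{name!r}")
        members = frozenset(g for g in fields[2:] if g)
        if not members:
            raise ParseError(f"{path.name}:{lineno}: set {name!r} has no "
                             "members")
        sets[name] = members
        descriptions[name] = description
    if not sets:
        raise ParseError(f"{path.name}: no gene sets found")
    if universe is None:
        univ = frozenset().union(*sets.values())
    else:
        univ = frozenset(universe)
        sets = {n: m & univ for n, m in sets.items()}
        sets = {n: m for n, m in sets.items() if m}
        if not sets:
            raise InputError("no gene set overlaps the supplied universe")
    return GeneSetCollection(sets=sets, descriptions=descriptions,
                             universe=univ)


class EnrichmentResults:
    """Per-set overlap counts and hypergeometric p/q-values, sorted by p."""

    def __init__(self, table: pd.DataFrame, n_query_used: int,
                 n_query_dropped: int):
        self.table = table
        self.n_query_used = n_query_used
        self.n_query_dropped = n_query_dropped

    def top(self, k: int = 10) -> pd.DataFrame:
        """The k most significant sets (p ascending, ties by name)."""
        return self.table.head(k).reset_index(drop=True)

    def summary(self, k: int = 10) -> str:
        lines = [
            "Hypergeometric over-representation",
            "==================================",
            f"gene sets tested: {len(self.table)}",
            f"query genes used: {self.n_query_used} "
            f"({self.n_query_dropped} outside universe dropped)",
            "",
            f"Top {min(k, len(self.table))} sets:",
            self.top(k).to_string(index=False,
                                  float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def hypergeom_enrich(query, collection: GeneSetCollection) -> EnrichmentResults:
    """Score every set in the collection against the query gene list."""
    query = set(query)
    effective = query & collection.universe
    dropped = len(query) - len(effective)
    if dropped:
        logger.info("%d query genes outside the universe were dropped",
                    dropped)
    if not effective:
        raise InputError("no query gene lies in the collection universe")

    N = len(collection.universe)
    n = len(effective)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(effective & members)
        # P(X >= k), upper tail including the observed overlap
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "description":
                     collection.descriptions.get(name, ""),
                     "k": k, "K": K, "n": n, "N": N,
                     "ratio": k / n, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["q"] = fdr_adjust(table["p"].to_numpy())
    table = table.sort_values(["p", "set_name"],
                              kind="stable").reset_index(drop=True)
    return EnrichmentResults(table, n_query_used=n, n_query_dropped=dropped)
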