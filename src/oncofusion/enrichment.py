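"""Hypergeometric over-representation analysis of gene lists.

Given an unranked query gene list (e.g. the target genes of one
oncofusion protein), each named gene set of a GMT collection is tested
for over-representation with the hypergeometric upper tail
P(X >= k), X ~ Hypergeom(N, m, n), where N is the universe size, m the
set size, n the query size and k their overlap.  P-values are
Benjamini-Hochberg adjusted across the collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class GeneSetCollection:
    """Named gene sets restricted to a declared universe."""

    def __init__(self, sets: Mapping[str, Iterable[str]], universe: Iterable[str]):
        self.universe: frozenset[str] = frozenset(universe)
        if not self.universe:
            raise ValueError("empty gene universe")
        self.sets: dict[str, frozenset[str]] = {}
        for name, members in sets.items():
            members = frozenset(members)
            dropped = members - self.universe
            if dropped:
                log.warning(
                    "gene set %r: dropped %d member(s) outside the universe",
                    name, len(dropped),
                )
            self.sets[name] = members & self.universe

    @classmethod
    def read_gmt(cls, path: str | Path, universe: Iterable[str]) -> "GeneSetCollection":
        """Read GMT: one set per line — name, description, then members."""
        sets: dict[str, list[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line with < 3 fields: {line[:60]!r}")
            sets[fields[0]] = fields[2:]
        return cls(sets, universe)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int        # overlap
    m: int        # set size
    n: int        # query size
    N: int        # universe size
    p_value: float
    q_value: float


def hypergeom_enrich(
    query: Iterable[str], collection: GeneSetCollection
) -> list[EnrichmentResult]:
    """Over-representation of the query in every set of the collection.

    Query genes outside the universe are dropped with a warning.  Results
    are BH-adjusted within the collection and sorted by (q, p, name).
    """
    query = set(query)
    outside = query - collection.universe
    if outside:
        log.warning("query: dropped %d gene(s) outside the universe", len(outside))
        query &= collection.universe
    if not query:
        raise ValueError("empty query after universe filtering")
    N = len(collection.universe)
    n = len(query)
    names, pvals, ks, ms = [], [], [], []
    for name, members in collection.sets.items():
        m = len(members)
        k = len(query & members)
        # upper tail P(X >= k) = sf(k - 1)
        p = float(hypergeom.sf(k - 1, N, m, n))
        names.append(name)
        pvals.append(min(1.0, p))
        ks.append(k)
        ms.append(m)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(name, k, m, n, N, p, float(q))
        for name, k, m, p, q in zip(names, ks, ms, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return results


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "set_name": r.set_name, "overlap": r.k, "set_size": r.m,
            "query_size": r.n, "universe_size": r.N,
            "p_value": r.p_value, "q_value": r.q_value,
        }
        for r in results
    ])


def enrichment_heatmap_table(
    results_per_query: Mapping[str, Sequence[EnrichmentResult]],
) -> pd.DataFrame:
    """Pathways x query-sets matrix of -log10 q for heatmap export.

    Rows are the union of pathways over all result lists; entries missing
    from a list are 0.
    """
    if not results_per_query:
        raise ValueError("need >= 1 result list")
    pathways = sorted({
        r.set_name for results in results_per_query.values() for r in results
    })
    out = pd.DataFrame(0.0, index=pathways, columns=list(results_per_query))
    for qname, results in results_per_query.items():
        for r in results:
            out.loc[r.set_name, qname] = -np.log10(max(r.q_value, 1e-300))
    out.index.name = "pathway"
    return out
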