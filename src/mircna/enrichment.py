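"""Gene-set over-representation analysis and miRNA x pathway summaries.

A plain hypergeometric upper-tail test of the overlap between a query gene
list and each named gene set, BH-adjusted across sets. The companion
involvement matrix counts each miRNA's voted targets inside each set and
feeds the hierarchical clustering used for two-cluster panel summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .integrate import normalize_symbol

__all__ = ["GeneSetCollection", "ora_hypergeometric", "mirna_pathway_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit universe.

    Without an explicit universe the union of all set members is used.
    Symbols are uppercase-normalized on construction.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        normalized = {}
        for name, genes in self.sets.items():
            members = frozenset(normalize_symbol(g) for g in genes)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            normalized[name] = members
        self.sets = normalized
        if self.universe is not None:
            self.universe = frozenset(normalize_symbol(g) for g in self.universe)

    def effective_universe(self) -> frozenset[str]:
        if self.universe is not None:
            return self.universe
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


def ora_hypergeometric(
    query: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each set.

    For each set, p = P[X >= overlap] with X ~ Hypergeometric(universe,
    set size, query size); BH q runs across sets. Query genes outside the
    universe are dropped with a warning. Results sorted by p.
    """
    universe = collection.effective_universe()
    query_set = {normalize_symbol(g) for g in query}
    if not query_set:
        raise ValueError("query gene list is empty")
    outside = query_set - universe
    if outside:
        logger.warning(
            "%d query genes outside the universe were dropped", len(outside)
        )
    query_set &= universe
    if not query_set:
        raise ValueError("no query genes remain inside the universe")

    m = len(universe)
    n_query = len(query_set)
    rows = []
    for name, genes in collection.sets.items():
        members = genes & universe
        overlap = len(query_set & members)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(members), n_query))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": n_query,
                "universe_size": m,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"].to_numpy())
    return result.sort_values("p", kind="stable").reset_index(drop=True)


def mirna_pathway_matrix(
    targets: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Count matrix: targets of each miRNA inside each gene set.

    Rows are miRNAs, columns gene sets; entry = number of that miRNA's
    (voted) targets belonging to the set. Two miRNAs with identical target
    sets get identical rows and therefore merge first in clustering.
    """
    set_names = list(collection.sets)
    rows = {}
    for mirna, genes in targets.items():
        gene_set = {normalize_symbol(g) for g in genes}
        rows[mirna] = [len(gene_set & collection.sets[name]) for name in set_names]
    return pd.DataFrame.from_dict(rows, orient="index", columns=set_names)
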