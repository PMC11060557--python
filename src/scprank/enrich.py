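"""Over-representation analysis of DEG lists against gene-set collections.

For each (entity, collection) pair, every term receives a one-sided
hypergeometric p-value for the overlap between the entity's DEG set and the
term's gene set, within a gene universe; BH adjustment is applied across the
terms of the collection.  All terms are retained — downstream mapping needs
positions deep in the list — so the product is a deterministic ranking, not
a filtered set.  Drug repurposing is the same operation against a
drug-signature collection whose term names are drug identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import GeneSetCollection
from .diffexp import DEGTable

__all__ = ["EnrichmentTable", "enrich_entity", "rank_terms"]

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ("term", "overlap", "set_size", "p_value", "adj_p")


@dataclass(frozen=True)
class EnrichmentTable:
    """Ranked enrichment results for one entity against one collection.

    Rows are sorted ascending by p-value, ties broken by descending overlap
    then term name, making the ranking total and deterministic.
    """

    entity: str
    collection: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != list(ENRICH_COLUMNS):
            raise ValueError(f"enrichment columns must be {ENRICH_COLUMNS}")
        if len(t):
            if (t["overlap"] > t["set_size"]).any():
                raise ValueError("overlap exceeds set size")
            if (t["p_value"] < 0).any() or (t["p_value"] > 1).any():
                raise ValueError("p-values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def is_empty(self) -> bool:
        return len(self.table) == 0


def hypergeom_tail(overlap: int, universe: int, set_size: int, n_draws: int) -> float:
    """P[X >= overlap] for X ~ Hypergeom(N=universe, K=set_size, n=n_draws)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, n_draws))


def enrich_entity(
    degs: DEGTable,
    collection: GeneSetCollection,
    universe: frozenset[str] | set[str],
) -> EnrichmentTable:
    """Hypergeometric over-representation of *degs* in each term of *collection*.

    *universe* is the background gene set (all genes tested for this entity);
    it must contain every DEG gene.  Term gene sets are clipped to the
    universe before testing.  An empty DEG list yields an empty table with a
    warning — the entity is then penalized downstream through J = 0.
    """
    universe = frozenset(g.upper() for g in universe)
    deg_set = frozenset(g.upper() for g in degs.genes)
    if not deg_set <= universe:
        missing = sorted(deg_set - universe)[:5]
        raise ValueError(f"universe must contain every DEG gene; missing {missing}")
    if not len(collection):
        raise ValueError(f"collection {collection.name!r} is empty")
    if not deg_set:
        logger.warning("%s/%s: empty DEG list, empty enrichment", degs.entity, collection.name)
        return EnrichmentTable(degs.entity, collection.name, _empty())

    n, n_deg = len(universe), len(deg_set)
    rows = []
    for term, genes in collection.sets.items():
        in_universe = genes & universe
        k = len(in_universe & deg_set)
        rows.append(
            {
                "term": term,
                "overlap": k,
                "set_size": len(in_universe),
                "p_value": hypergeom_tail(k, n, len(in_universe), n_deg),
            }
        )
    tab = pd.DataFrame(rows)
    tab["adj_p"] = multipletests(tab["p_value"], method="fdr_bh")[1]
    tab = (
        tab.sort_values(["p_value", "overlap", "term"], ascending=[True, False, True])
        .reset_index(drop=True)[list(ENRICH_COLUMNS)]
    )
    return EnrichmentTable(degs.entity, collection.name, tab)


def rank_terms(table: EnrichmentTable) -> tuple[str, ...]:
    """Ordered term names — the data-driven ranked list the mapping step consumes."""
    return tuple(table.table["term"])


def _empty() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": pd.Series(dtype=str),
            "overlap": pd.Series(dtype=int),
            "set_size": pd.Series(dtype=int),
            "p_value": pd.Series(dtype=float),
            "adj_p": pd.Series(dtype=float),
        }
    )
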