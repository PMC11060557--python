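"""Final cell-type prioritization: per-collection ranks, mean-rank merge,
and the union with the communication-network ranking.

Within each collection, entities are ranked by ascending RS (rank 1 = best
agreement with prior knowledge; ties get average ranks).  Collections in
which no entity mapped any prior term (J = 0 everywhere) carry no
information and are excluded.  The mean rank across the usable pathway and
drug collections gives the final order; the communication-network ranking
is kept independent and enters only through the union of the two top-k
lists.  A pseudo-bulk entity may take part in the per-collection ranks as a
comparator but never enters the union.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .commnet import CommRanking, top_k_comm
from .diffexp import BULK
from .mapping import MappingResult

__all__ = ["RankReport", "rank_collection", "merge_ranks", "union_prioritization"]


@dataclass(frozen=True)
class RankReport:
    """Assembled prioritization for one run.

    ``rank_table``: entity x collection ranks (NaN for unusable collections)
    plus a ``mean_rank`` column; ``final_order``: entities by ascending mean
    rank, ties alphabetical; ``comm_order``: cell types by |LogFDI|
    descending; ``union_top``: top-k union of the two orders (never
    containing the pseudo-bulk comparator); ``collections_used``: the
    collections that contributed to the mean.
    """

    rank_table: pd.DataFrame
    final_order: tuple[str, ...]
    comm_order: tuple[str, ...]
    union_top: frozenset[str]
    collections_used: tuple[str, ...]
    collections_dropped: tuple[str, ...]
    k: int


def rank_collection(results: list[MappingResult]) -> pd.Series:
    """Entity -> rank within one collection (ascending RS, average-rank ties)."""
    entities = [r.entity for r in results]
    if len(set(entities)) != len(entities):
        raise ValueError("duplicate entity in collection results")
    rs = pd.Series({r.entity: r.RS for r in results}, dtype=float)
    return rs.rank(method="average", ascending=True)


def collection_is_usable(results: list[MappingResult]) -> bool:
    """A collection is informative iff at least one entity mapped a term."""
    return any(r.J > 0 for r in results)


def merge_ranks(
    per_collection: dict[str, list[MappingResult]],
) -> tuple[pd.DataFrame, tuple[str, ...], tuple[str, ...]]:
    """Build the entity x collection rank table and the mean-rank column.

    Collections with no mapped information for any entity are dropped from
    the mean.  Returns (rank_table, used, dropped); raises if nothing is
    usable (the checklist matched no data-driven result at all).
    """
    if not per_collection:
        raise ValueError("no collections supplied")
    used, dropped = [], []
    cols: dict[str, pd.Series] = {}
    for name, results in per_collection.items():
        cols[name] = rank_collection(results)
        (used if collection_is_usable(results) else dropped).append(name)
    if not used:
        raise ValueError(
            "no collection mapped any prior term for any entity; "
            "revise the checklist terms"
        )
    table = pd.DataFrame(cols).sort_index()
    table["mean_rank"] = table[used].mean(axis=1)
    return table, tuple(used), tuple(dropped)


def union_prioritization(
    final_order: tuple[str, ...], comm_order: tuple[str, ...], k: int = 3
) -> frozenset[str]:
    """Union of the two top-k lists (mean-rank order and |LogFDI| order)."""
    if not final_order or not comm_order:
        raise ValueError("both orders must be non-empty")
    return frozenset(final_order[:k]) | frozenset(comm_order[:k])


def build_report(
    per_collection: dict[str, list[MappingResult]],
    comm: CommRanking,
    k: int = 3,
) -> RankReport:
    """Assemble the full prioritization report.

    The pseudo-bulk comparator (entity ``BULK``), if present in the mapping
    results, is ranked inside each collection but removed before the top-k
    union.
    """
    table, used, dropped = merge_ranks(per_collection)
    order = (
        table.reset_index(names="entity")
        .sort_values(["mean_rank", "entity"], ascending=[True, True], kind="stable")
    )
    final_order = tuple(e for e in order["entity"])
    final_cells = tuple(e for e in final_order if e != BULK)
    comm_order = comm.order
    union = union_prioritization(final_cells, top_k_comm(comm, k=min(k, len(comm_order))), k=k)
    return RankReport(
        rank_table=table,
        final_order=final_order,
        comm_order=comm_order,
        union_top=union,
        collections_used=used,
        collections_dropped=dropped,
        k=k,
    )
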