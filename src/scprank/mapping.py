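"""Mapping prior-knowledge term order onto data-driven rankings.

Each prior term is located in the entity's ranked enrichment list by greedy
first-hit substring matching (either string containing the other counts,
after normalization; each result position is consumed at most once).  From
the matched positions the agreement between prior order and data-driven
order is scored:

* ``E`` — Euclidean distance between the prior indices and their matched
  positions, with unmatched (NA) terms contributing a fixed penalty distance
  of ``L + 1`` (one past the end of the data-driven list of length ``L``,
  exceeding every attainable matched distance);
* ``J`` — Jaccard similarity of the asymmetric binary match vectors, which
  reduces to (number matched) / (number of prior terms);
* ``RS = E / J`` — the ranking score, guarded by dividing by 1e-6 when
  ``J = 0``.  Smaller RS means better agreement with the prior knowledge;
  RS is zero exactly when every prior term matches at its own index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .knowledge import normalize_term

__all__ = ["MappingResult", "match_terms", "ranking_score", "map_entity", "J_GUARD"]

#: divisor used in place of J when no prior term matched
J_GUARD = 1e-6


@dataclass(frozen=True)
class MappingResult:
    """Match positions and agreement scores for one (entity, collection)."""

    entity: str
    collection: str
    prior_terms: tuple[str, ...]
    matched_position: tuple[int | None, ...]
    L: int
    E: float
    J: float
    RS: float

    def __post_init__(self) -> None:
        hit = [p for p in self.matched_position if p is not None]
        if len(set(hit)) != len(hit):
            raise ValueError("matched positions must be unique")
        if any(not (1 <= p <= self.L) for p in hit):
            raise ValueError(f"matched positions must lie in [1, {self.L}]")

    @property
    def n_matched(self) -> int:
        return sum(p is not None for p in self.matched_position)


def match_terms(
    prior: Sequence[str], result: Sequence[str]
) -> list[int | None]:
    """Greedy positional matching of prior terms into a ranked result list.

    For prior term *i* (in order), the match is the smallest 1-based index
    *j* of a not-yet-consumed result term such that, after normalization,
    either string contains the other as a substring.  Consumption guarantees
    the returned positions are unique, so a Euclidean distance over them is
    meaningful.  Unmatched terms yield ``None``.
    """
    res_norm = [normalize_term(t) for t in result]
    consumed = [False] * len(res_norm)
    positions: list[int | None] = []
    for term in prior:
        t = normalize_term(term)
        hit = None
        for j, r in enumerate(res_norm):
            if consumed[j]:
                continue
            if t in r or r in t:
                hit = j
                break
        if hit is None:
            positions.append(None)
        else:
            consumed[hit] = True
            positions.append(hit + 1)
    return positions


def ranking_score(
    matched_position: Sequence[int | None], n: int, L: int
) -> tuple[float, float, float]:
    """Compute (E, J, RS) from matched positions.

    Parameters
    ----------
    matched_position:
        Per prior term, the 1-based position in the data-driven list, or
        ``None`` for no match.
    n:
        Number of prior terms (must equal ``len(matched_position)``).
    L:
        Length of the data-driven list; sets the NA penalty distance
        ``L + 1``.
    """
    if n < 1:
        raise ValueError("empty prior term list (checklist defect)")
    if len(matched_position) != n:
        raise ValueError("matched_position length must equal n")
    sq = 0.0
    matched = 0
    for i, p in enumerate(matched_position, start=1):
        if p is None:
            d = L + 1
        else:
            d = abs(i - p)
            matched += 1
        sq += float(d) * float(d)
    e = math.sqrt(sq)
    j = matched / n
    rs = e / j if j > 0 else e / J_GUARD
    return e, j, rs


def map_entity(
    entity: str,
    collection: str,
    prior: Sequence[str],
    result: Sequence[str],
) -> MappingResult:
    """Match *prior* into *result* and score the agreement for one entity."""
    positions = match_terms(prior, result)
    n, L = len(prior), len(result)
    e, j, rs = ranking_score(positions, n, L)
    return MappingResult(
        entity=entity,
        collection=collection,
        prior_terms=tuple(prior),
        matched_position=tuple(positions),
        L=L,
        E=e,
        J=j,
        RS=rs,
    )
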