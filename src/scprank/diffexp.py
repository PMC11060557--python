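"""Differential expression between disease and control cells.

The disease signature of each cell type is obtained with the standard
single-cell recipe: library-size normalization to the median depth followed
by ``log1p``, a two-sided Wilcoxon rank-sum test per gene between the two
condition groups, and Benjamini–Hochberg adjustment across the genes tested
within that cell type.  Genes detected in fewer than ``min_pct`` of the
cells of both groups are excluded before testing.  A pseudo-bulk comparator
pools all cells per condition regardless of type, mimicking a bulk RNA-seq
contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionDataset

__all__ = [
    "DEGTable",
    "normalize_counts",
    "deg_per_celltype",
    "pseudo_bulk_deg",
    "baseline_rankings",
    "BULK",
]

logger = logging.getLogger(__name__)

BULK = "BULK"

DEG_COLUMNS = ("gene", "effect", "p_value", "adj_p")


@dataclass(frozen=True)
class DEGTable:
    """Differential genes for one entity (a cell type, or ``BULK``).

    ``table`` has columns ``gene, effect, p_value, adj_p`` sorted by
    ``adj_p`` ascending then ``|effect|`` descending; ``effect`` is the
    log2 ratio of (mean normalized expression + 1), disease over control.
    """

    entity: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.entity:
            raise ValueError("entity must be non-empty")
        t = self.table
        if list(t.columns) != list(DEG_COLUMNS):
            raise ValueError(f"DEG table columns must be {DEG_COLUMNS}")
        if len(t):
            if (t["p_value"] < 0).any() or (t["p_value"] > 1).any():
                raise ValueError("p-values outside [0, 1]")
            if (t["adj_p"] + 1e-12 < t["p_value"]).any():
                raise ValueError("adjusted p smaller than raw p")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


def normalize_counts(data: ExpressionDataset) -> ExpressionDataset:
    """Median-library-size scaling followed by log1p.

    Each cell's counts are scaled by (median library size / its library
    size), correcting depth imbalances between conditions, then log1p
    transformed.  Raw counts are retained; the result is stored in
    ``data.normalized``.
    """
    libsize = data.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(f"cell(s) with zero total count: {[data.cell_ids[i] for i in zero[:5]]}")
    scale = np.median(libsize) / libsize
    data.normalized = np.log1p(data.counts * scale[np.newaxis, :])
    return data


def _require_normalized(data: ExpressionDataset) -> np.ndarray:
    if data.normalized is None:
        normalize_counts(data)
    return data.normalized


def _wilcoxon_table(
    entity: str,
    x_dis: np.ndarray,
    x_ctl: np.ndarray,
    genes: np.ndarray,
    alpha: float,
    min_pct: float,
) -> DEGTable:
    """Vectorized rank-sum test per gene; rows with adj_p < alpha retained."""
    detected = np.maximum(
        (x_dis > 0).mean(axis=1), (x_ctl > 0).mean(axis=1)
    ) >= min_pct
    if not detected.any():
        logger.warning("%s: no gene passes the %.0f%% detection filter", entity, 100 * min_pct)
        return DEGTable(entity, _empty_table())
    xd, xc, g = x_dis[detected], x_ctl[detected], genes[detected]
    # exact null when both groups are small and tie-free, asymptotic with
    # tie correction otherwise (scipy picks per scRNA-seq convention)
    res = stats.mannwhitneyu(xd, xc, axis=1, alternative="two-sided", method="auto")
    pvals = np.atleast_1d(res.pvalue)
    adj = multipletests(pvals, method="fdr_bh")[1]
    effect = np.log2(xd.mean(axis=1) + 1.0) - np.log2(xc.mean(axis=1) + 1.0)
    tab = pd.DataFrame(
        {"gene": g, "effect": effect, "p_value": pvals, "adj_p": adj}
    )
    tab = tab[tab["adj_p"] < alpha].copy()
    tab["_absfx"] = tab["effect"].abs()
    tab = (
        tab.sort_values(["adj_p", "_absfx", "gene"], ascending=[True, False, True])
        .drop(columns="_absfx")
        .reset_index(drop=True)
    )
    return DEGTable(entity, tab)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {"gene": pd.Series(dtype=str), "effect": pd.Series(dtype=float),
         "p_value": pd.Series(dtype=float), "adj_p": pd.Series(dtype=float)}
    )


def deg_per_celltype(
    data: ExpressionDataset,
    cell_type: str,
    alpha: float = 0.05,
    min_pct: float = 0.1,
    min_cells: int = 3,
) -> DEGTable:
    """Disease-vs-control DEGs within one cell type at adjusted p < *alpha*.

    If either condition has fewer than *min_cells* cells of this type the
    entity is skipped with a warning and an empty table is returned.
    """
    norm = _require_normalized(data)
    m_dis = data.cells_of(cell_type, "disease")
    m_ctl = data.cells_of(cell_type, "control")
    if m_dis.sum() < min_cells or m_ctl.sum() < min_cells:
        logger.warning(
            "%s: insufficient cells (disease %d, control %d < %d); skipped",
            cell_type, m_dis.sum(), m_ctl.sum(), min_cells,
        )
        return DEGTable(cell_type, _empty_table())
    return _wilcoxon_table(
        cell_type, norm[:, m_dis], norm[:, m_ctl],
        np.asarray(data.gene_ids), alpha, min_pct,
    )


def pseudo_bulk_deg(
    data: ExpressionDataset,
    alpha: float = 0.05,
    min_pct: float = 0.1,
) -> DEGTable:
    """DEGs from pooling all cells per condition (bulk RNA-seq surrogate)."""
    norm = _require_normalized(data)
    m_dis = data.cells_of(None, "disease")
    m_ctl = data.cells_of(None, "control")
    if not m_dis.any() or not m_ctl.any():
        raise ValueError("both conditions must be non-empty for pseudo-bulk DE")
    return _wilcoxon_table(
        BULK, norm[:, m_dis], norm[:, m_ctl], np.asarray(data.gene_ids), alpha, min_pct
    )


def baseline_rankings(
    data: ExpressionDataset, deg_tables: dict[str, DEGTable]
) -> pd.DataFrame:
    """Conventional comparator orderings of cell types.

    Returns a table with one row per cell type, columns ``n_degs``,
    ``prop_disease``, ``prop_control``, ``prop_diff`` and the two rank
    columns ``rank_by_degs`` (descending DEG count) and ``rank_by_prop``
    (descending absolute proportion difference); ties break alphabetically.
    """
    meta = data.cell_meta
    types = data.cell_types
    rows = []
    for ct in types:
        p_dis = ((meta["cell_type"] == ct) & (meta["condition"] == "disease")).sum() / max(
            (meta["condition"] == "disease").sum(), 1
        )
        p_ctl = ((meta["cell_type"] == ct) & (meta["condition"] == "control")).sum() / max(
            (meta["condition"] == "control").sum(), 1
        )
        rows.append(
            {
                "cell_type": ct,
                "n_degs": len(deg_tables[ct]) if ct in deg_tables else 0,
                "prop_disease": p_dis,
                "prop_control": p_ctl,
                "prop_diff": abs(p_dis - p_ctl),
            }
        )
    df = pd.DataFrame(rows).set_index("cell_type")
    order_deg = df.sort_values(["n_degs"], ascending=False, kind="stable").index
    # alphabetical index is the stable-sort tie-break for both orderings
    order_prop = df.sort_values(["prop_diff"], ascending=False, kind="stable").index
    df["rank_by_degs"] = pd.Series(range(1, len(df) + 1), index=order_deg)
    df["rank_by_prop"] = pd.Series(range(1, len(df) + 1), index=order_prop)
    return df.reset_index()
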