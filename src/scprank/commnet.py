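"""Cell-type ranking from cell-cell communication network perturbation.

Given two directed interaction-count networks over the same cell types —
one inferred from control cells, one from disease cells — each cell type is
scored by the log2 fold difference of its normalized interaction totals:

    TNCI_i = (NSC_i + NTC_i) / TIC        (control)
    TNDI_i = (NSD_i + NTD_i) / TID        (disease)
    LogFDI_i = log2(TNDI_i / TNCI_i)

where NS*/NT* are the cell type's outgoing (source) and incoming (target)
interaction counts and TIC/TID the network totals.  Because every
interaction contributes one source and one target, the normalized totals
each sum to 2 over cell types.  A positive LogFDI means the cell type
gained communication share in disease; the ranking uses |LogFDI|, as the
magnitude of perturbation is what prioritizes a cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import InteractionNetwork

__all__ = ["CommRanking", "node_totals", "logfdi", "top_k_comm"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CommRanking:
    """Per-cell-type communication perturbation scores and their ordering.

    ``table`` columns: ``cell_type, NSC, NTC, NSD, NTD, TNCI, TNDI, fold,
    LogFDI, abs_rank`` (``fold`` = TNDI/TNCI).  ``order`` lists cell types
    by |LogFDI| descending, ties alphabetical.
    """

    table: pd.DataFrame
    order: tuple[str, ...]
    TIC: float
    TID: float


def node_totals(net: InteractionNetwork) -> pd.DataFrame:
    """Outgoing/incoming interaction counts per cell type.

    Self-loops count once in ``n_source`` and once in ``n_target``.
    Returns a frame indexed by cell type with columns ``n_source``,
    ``n_target``, ``total`` (``total`` = network-wide interaction count,
    identical on every row).
    """
    c = net.counts.astype(float)
    return pd.DataFrame(
        {
            "n_source": c.sum(axis=1),
            "n_target": c.sum(axis=0),
            "total": c.sum(),
        },
        index=list(net.cell_types),
    )


def logfdi(
    control: InteractionNetwork,
    disease: InteractionNetwork,
    eps: float = 0.5,
) -> CommRanking:
    """Log2 fold difference in normalized interaction totals per cell type.

    Both networks are aligned to the sorted union of their cell types
    (zero-filling absent types).  The ratio is undefined when a cell type
    has zero interactions on either side; for those cell types only, a
    pseudocount *eps* is added to both raw totals (NSC+NTC and NSD+NTD)
    before normalization, keeping the score finite while leaving all other
    cell types on the exact path.
    """
    if control.condition != "control" or disease.condition != "disease":
        raise ValueError("pass (control, disease) networks in that order")
    union = tuple(sorted(set(control.cell_types) | set(disease.cell_types)))
    ctl = control.reindex(union)
    dis = disease.reindex(union)
    tic, tid = ctl.total, dis.total
    if tic <= 0 or tid <= 0:
        raise ValueError("both networks must contain at least one interaction")

    nt_c = node_totals(ctl)
    nt_d = node_totals(dis)
    raw_c = (nt_c["n_source"] + nt_c["n_target"]).to_numpy()
    raw_d = (nt_d["n_source"] + nt_d["n_target"]).to_numpy()
    tnci = raw_c / tic
    tndi = raw_d / tid
    needs_eps = (raw_c == 0) | (raw_d == 0)
    if needs_eps.any():
        logger.warning(
            "pseudocount %g applied to %d zero-degree cell type(s)", eps, needs_eps.sum()
        )
        tnci = np.where(needs_eps, (raw_c + eps) / tic, tnci)
        tndi = np.where(needs_eps, (raw_d + eps) / tid, tndi)
    log_fdi = np.log2(tndi / tnci)
    fold = tndi / tnci

    tab = pd.DataFrame(
        {
            "cell_type": union,
            "NSC": nt_c["n_source"].to_numpy(),
            "NTC": nt_c["n_target"].to_numpy(),
            "NSD": nt_d["n_source"].to_numpy(),
            "NTD": nt_d["n_target"].to_numpy(),
            "TNCI": tnci,
            "TNDI": tndi,
            "fold": fold,
            "LogFDI": log_fdi,
        }
    )
    tab["_abs"] = tab["LogFDI"].abs()
    tab = tab.sort_values(["_abs", "cell_type"], ascending=[False, True], kind="stable")
    tab["abs_rank"] = range(1, len(tab) + 1)
    order = tuple(tab["cell_type"])
    tab = tab.drop(columns="_abs").sort_values("cell_type").reset_index(drop=True)
    return CommRanking(table=tab, order=order, TIC=tic, TID=tid)


def top_k_comm(ranking: CommRanking, k: int = 3) -> tuple[str, ...]:
    """First *k* cell types by |LogFDI| descending (all of them if k exceeds the count)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking.order):
        logger.warning("k=%d exceeds %d cell types; returning all", k, len(ranking.order))
    return ranking.order[:k]
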