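"""Self-contained synthetic fixtures with planted ground truth.

The generator emulates everything a real run needs — an annotated
case/control count matrix, pathway gene-set collections, a CMAP-style drug
signature collection, an ordered prior-knowledge checklist with drugs and
MOAs, a drug->MOA lookup table, and a pair of cell-cell interaction
networks — while planting a known signal in one target cell type:

* expression: counts follow a gamma-Poisson (negative binomial) baseline
  with log-normal per-gene means; in the target cell type's disease cells,
  the genes of ``prior_depth`` designated sets per pathway collection are
  up-shifted, with a graded fraction of each set shifted so that the
  enrichment strength decreases along the checklist order;
* every non-target cell type receives the same magnitude of shift in sets
  that are *not* on the checklist, so all cell types have DEGs and
  non-empty enrichments and the ranking has to discriminate by agreement
  with the prior order rather than by mere signal presence;
* drug signatures of the checklist drugs are built to overlap the planted
  genes with graded strength; remaining drugs get random signatures;
* interaction networks: disease equals control up to mild multiplicative
  jitter, except the target cell type whose outgoing and incoming counts
  are scaled by ``comm_fold``.  The target's baseline communication share
  is kept modest so that, in small networks, the planted fold dominates
  the compensatory share shift of the other cell types.

Setting ``planted_effect = 0`` and ``comm_fold = 1`` yields a null dataset
(no signal anywhere; the truth record flags this).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    ExpressionDataset,
    GeneSetCollection,
    InteractionNetwork,
    write_expression,
    write_gmt,
    write_network,
)
from .knowledge import Checklist, MOATable, save_checklist

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "write_bundle", "DRUG_COLLECTION"]

DRUG_COLLECTION = "DRUG"

_CELL_TYPE_ROSTER = (
    "Astrocyte", "Bcell", "Microglia", "Neuron", "Tcell",
    "Endothelial", "Fibroblast", "Macrophage", "NKcell", "Oligodendrocyte",
)
_COLLECTION_ROSTER = ("KEGG", "GOBP", "WIKI", "MSIG", "REACT")
_DRUG_ROSTER = (
    "sirolimus", "selumetinib", "palbociclib", "everolimus", "trametinib",
    "dexamethasone", "metformin", "imatinib", "lovastatin", "aspirin",
    "ruxolitinib", "bortezomib", "erlotinib", "vorinostat", "celecoxib",
    "haloperidol", "tamoxifen", "verapamil", "ibuprofen", "omeprazole",
)
_PLANTED_MOAS = ("MTOR inhibitor", "MEK inhibitor", "CDK inhibitor")
_FILLER_MOAS = (
    "glucocorticoid receptor agonist", "HMGCR inhibitor", "JAK inhibitor",
    "proteasome inhibitor", "EGFR inhibitor", "HDAC inhibitor",
    "cyclooxygenase inhibitor", "estrogen receptor antagonist",
    "calcium channel blocker", "proton pump inhibitor", "dopamine receptor antagonist",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults describe the standard benchmark condition: 2,000 genes, five
    cell types with 40 cells per type per condition, a log-scale planted
    shift of 1.5 in the target cell type, five prior terms per collection,
    and a two-fold communication perturbation.
    """

    seed: int = 0
    n_genes: int = 2000
    n_cell_types: int = 5
    cells_per_type_per_condition: int = 40
    target_cell_type: str = "Microglia"
    n_collections: int = 3
    sets_per_collection: int = 20
    genes_per_set: int = 30
    planted_effect: float = 1.5
    prior_depth: int = 5
    comm_fold: float = 2.0
    n_drugs: int = 15
    n_planted_drugs: int = 3
    nb_dispersion: float = 2.0
    disease_name: str = "synthetic disease"

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_cell_types", "cells_per_type_per_condition",
            "n_collections", "sets_per_collection", "genes_per_set",
            "prior_depth", "n_drugs", "n_planted_drugs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.planted_effect < 0:
            raise ValueError("planted_effect must be >= 0")
        if self.comm_fold <= 0:
            raise ValueError("comm_fold must be > 0")
        if self.n_cell_types > len(_CELL_TYPE_ROSTER):
            raise ValueError(f"at most {len(_CELL_TYPE_ROSTER)} cell types supported")
        if self.n_collections > len(_COLLECTION_ROSTER):
            raise ValueError(f"at most {len(_COLLECTION_ROSTER)} pathway collections supported")
        if self.n_drugs > len(_DRUG_ROSTER):
            raise ValueError(f"at most {len(_DRUG_ROSTER)} drugs supported")
        if self.genes_per_set > self.n_genes:
            raise ValueError("genes_per_set exceeds the gene pool")
        if self.prior_depth > self.sets_per_collection // 2:
            raise ValueError(
                "prior_depth must leave at least as many non-prior sets per "
                "collection (needed for off-target background signal)"
            )
        if self.n_planted_drugs > min(self.n_drugs, len(_PLANTED_MOAS)):
            raise ValueError("too many planted drugs")
        if self.target_cell_type not in _CELL_TYPE_ROSTER[: self.n_cell_types]:
            raise ValueError(
                f"target_cell_type must be one of "
                f"{_CELL_TYPE_ROSTER[: self.n_cell_types]}"
            )

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(sorted(_CELL_TYPE_ROSTER[: self.n_cell_types]))

    @property
    def no_signal(self) -> bool:
        return self.planted_effect == 0 and self.comm_fold == 1


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the answer key for recovery tests."""

    target_cell_type: str
    planted_sets: dict[str, tuple[str, ...]]
    planted_genes: tuple[str, ...]
    planted_drugs: tuple[str, ...]
    background_sets: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)
    no_signal: bool = False


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, r: float) -> np.ndarray:
    """Gamma-Poisson draw: NB with mean mu and dispersion r (var = mu + mu^2/r)."""
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def generate(
    spec: SyntheticSpec,
) -> tuple[
    ExpressionDataset,
    list[GeneSetCollection],
    Checklist,
    MOATable,
    tuple[InteractionNetwork, InteractionNetwork],
    GroundTruth,
]:
    """Generate one complete synthetic study (deterministic in ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    gene_arr = np.array(genes)
    cell_types = spec.cell_types
    target = spec.target_cell_type

    # ----- gene-set collections -------------------------------------------
    collections: list[GeneSetCollection] = []
    planted_sets: dict[str, tuple[str, ...]] = {}
    background_sets: dict[str, dict[str, tuple[str, ...]]] = {}
    planted_gene_idx: set[int] = set()
    shift_fraction = np.linspace(1.0, 0.6, spec.prior_depth)
    # per-gene shift factor for the target's disease cells
    target_factor = np.ones(spec.n_genes)
    offtarget_factor = {ct: np.ones(spec.n_genes) for ct in cell_types if ct != target}

    others = [ct for ct in cell_types if ct != target]
    for ci in range(spec.n_collections):
        cname = _COLLECTION_ROSTER[ci]
        sets: dict[str, frozenset[str]] = {}
        members: list[np.ndarray] = []
        for si in range(spec.sets_per_collection):
            idx = rng.choice(spec.n_genes, size=spec.genes_per_set, replace=False)
            members.append(idx)
            sets[f"{cname} pathway {si + 1:03d}"] = frozenset(gene_arr[idx])
        names = list(sets)
        # checklist sets are drawn at random (not name-adjacent) so that
        # p-value-tie ordering by term name cannot mimic the prior order
        prior_pick = rng.choice(spec.sets_per_collection, size=spec.prior_depth, replace=False)
        planted_sets[cname] = tuple(names[i] for i in prior_pick)
        if spec.planted_effect > 0:
            for k, si in enumerate(prior_pick):
                idx = members[si]
                n_shift = int(round(shift_fraction[k] * len(idx)))
                chosen = idx[:n_shift]
                target_factor[chosen] = np.exp(spec.planted_effect)
                planted_gene_idx.update(chosen.tolist())
            # off-target background: each other cell type gets its own
            # non-checklist sets shifted by the same magnitude
            pool = [names[i] for i in range(spec.sets_per_collection) if i not in set(prior_pick)]
            per_ct = max(1, len(pool) // max(len(others), 1))
            background_sets[cname] = {}
            for oi, ct in enumerate(others):
                picked = pool[oi * per_ct: oi * per_ct + min(per_ct, spec.prior_depth)]
                background_sets[cname][ct] = tuple(picked)
                for nm in picked:
                    idx = members[names.index(nm)]
                    offtarget_factor[ct][idx] = np.exp(spec.planted_effect)
        collections.append(GeneSetCollection(cname, sets))

    planted_genes = tuple(sorted(gene_arr[sorted(planted_gene_idx)]))

    # ----- drug signature collection --------------------------------------
    drug_names = list(_DRUG_ROSTER[: spec.n_drugs])
    planted_drugs = tuple(drug_names[: spec.n_planted_drugs]) if spec.planted_effect > 0 else ()
    planted_pool = np.array(sorted(planted_gene_idx), dtype=int)
    drug_sets: dict[str, frozenset[str]] = {}
    for di, drug in enumerate(drug_names):
        term = f"{drug}_HL60_10UM"
        if drug in planted_drugs and planted_pool.size:
            frac = 0.8 - 0.15 * di
            n_hit = min(int(round(frac * spec.genes_per_set)), planted_pool.size)
            hit = rng.choice(planted_pool, size=n_hit, replace=False)
            rest = rng.choice(
                np.setdiff1d(np.arange(spec.n_genes), planted_pool),
                size=spec.genes_per_set - n_hit,
                replace=False,
            )
            idx = np.concatenate([hit, rest])
        else:
            idx = rng.choice(spec.n_genes, size=spec.genes_per_set, replace=False)
        drug_sets[term] = frozenset(gene_arr[idx])
    collections.append(GeneSetCollection(DRUG_COLLECTION, drug_sets))

    # ----- MOA table and checklist ----------------------------------------
    moa_rows: list[tuple[str, str]] = []
    filler = list(_FILLER_MOAS)
    for di, drug in enumerate(drug_names):
        if drug in planted_drugs:
            moa_rows.append((drug, _PLANTED_MOAS[list(planted_drugs).index(drug)]))
        else:
            moa_rows.append((drug, filler[di % len(filler)]))
    moa_table = MOATable(tuple(moa_rows))

    checklist = Checklist(
        disease_name=spec.disease_name,
        mode="discovery",
        pathway_terms={c: planted_sets[c] for c in planted_sets},
        drug_terms=planted_drugs,
        moa_terms=tuple(_PLANTED_MOAS[: len(planted_drugs)]),
    )

    # ----- expression counts ----------------------------------------------
    base_mu = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    if planted_gene_idx:
        # keep planted genes detectably expressed
        idx = np.array(sorted(planted_gene_idx))
        base_mu[idx] = np.maximum(base_mu[idx], 0.5)
    n_per = spec.cells_per_type_per_condition
    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    meta_rows: list[tuple[str, str, str]] = []
    for ct in cell_types:
        for cond in ("control", "disease"):
            mu = base_mu.copy()
            if cond == "disease":
                if ct == target:
                    mu = mu * target_factor
                elif ct in offtarget_factor:
                    mu = mu * offtarget_factor[ct]
            block = _nb_counts(
                rng, np.repeat(mu[:, None], n_per, axis=1), spec.nb_dispersion
            )
            blocks.append(block)
            for j in range(n_per):
                cid = f"{ct}_{cond}_{j + 1:03d}"
                cell_ids.append(cid)
                meta_rows.append((cid, ct, cond))
    counts = np.concatenate(blocks, axis=1)
    meta = pd.DataFrame(meta_rows, columns=["cell_id", "cell_type", "condition"]).set_index(
        "cell_id"
    )
    data = ExpressionDataset(counts, tuple(genes), tuple(cell_ids), meta)

    # ----- interaction networks -------------------------------------------
    n_ct = len(cell_types)
    t_idx = cell_types.index(target)
    lam = np.full((n_ct, n_ct), 12.0)
    lam[t_idx, :] = 6.0
    lam[:, t_idx] = 6.0
    ctl_counts = rng.poisson(lam) + 1  # +1 avoids zero-degree types
    jitter = rng.uniform(0.92, 1.08, size=(n_ct, n_ct))
    dis_counts = np.rint(ctl_counts * jitter).astype(np.int64)
    if spec.comm_fold != 1:
        loop = dis_counts[t_idx, t_idx]
        dis_counts[t_idx, :] = np.rint(dis_counts[t_idx, :] * spec.comm_fold)
        dis_counts[:, t_idx] = np.rint(dis_counts[:, t_idx] * spec.comm_fold)
        dis_counts[t_idx, t_idx] = int(round(loop * spec.comm_fold))
    control_net = InteractionNetwork("control", cell_types, ctl_counts)
    disease_net = InteractionNetwork("disease", cell_types, dis_counts)

    truth = GroundTruth(
        target_cell_type=target,
        planted_sets=planted_sets,
        planted_genes=planted_genes,
        planted_drugs=planted_drugs,
        background_sets=background_sets,
        no_signal=spec.no_signal,
    )
    return data, collections, checklist, moa_table, (control_net, disease_net), truth


def write_bundle(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Generate and write a complete input bundle in the pipeline's file formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data, colls, checklist, moa, (ctl, dis), truth = generate(spec)
    write_expression(data, out / "expression")
    for coll in colls:
        write_gmt(coll, out / f"{coll.name}.gmt")
    save_checklist(checklist, out / "checklist.yaml")
    with open(out / "moa_table.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug_name\tmoa\n")
        for drug, m in moa.rows:
            fh.write(f"{drug}\t{m}\n")
    write_network(ctl, out / "network_control.csv")
    write_network(dis, out / "network_disease.csv")
    with open(out / "truth.yaml", "w", encoding="utf-8") as fh:
        import yaml

        yaml.safe_dump(
            {
                "target_cell_type": truth.target_cell_type,
                "planted_sets": {c: list(v) for c, v in truth.planted_sets.items()},
                "planted_drugs": list(truth.planted_drugs),
                "no_signal": truth.no_signal,
            },
            fh,
            sort_keys=False,
        )
    return out
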