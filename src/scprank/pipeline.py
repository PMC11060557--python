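"""End-to-end orchestration: DE -> enrichment -> mapping -> ranks -> union.

The pipeline is a thin composition of the library stages; every
intermediate product is a plain table so any stage can be re-entered from
disk.  :func:`run` works on in-memory objects (the natural entry point from
Python); :func:`run_from_files` loads the file bundle first and writes all
outputs, which is what the command-line interface calls.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .commnet import CommRanking, logfdi
from .dataio import (
    ExpressionDataset,
    GeneSetCollection,
    InteractionNetwork,
    read_expression,
    read_gmt,
    read_network,
)
from .diffexp import (
    BULK,
    DEGTable,
    baseline_rankings,
    deg_per_celltype,
    normalize_counts,
    pseudo_bulk_deg,
)
from .enrich import EnrichmentTable, enrich_entity, rank_terms
from .knowledge import Checklist, MOATable, expand_moas, load_checklist, load_moa_table
from .mapping import MappingResult, map_entity
from .ranking import RankReport, build_report
from .synthetic import DRUG_COLLECTION

__all__ = ["RunConfig", "PipelineResult", "run", "run_from_files"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of one pipeline run.

    ``alpha`` is the adjusted-p DEG threshold (0.05); ``min_pct`` and
    ``min_cells`` gate the per-cell-type test; ``comm_eps`` is the
    zero-degree pseudocount of the communication ranking; ``k`` the union
    depth (top-3 by default); ``include_bulk`` adds the pseudo-bulk
    comparator to the per-collection ranks.
    """

    alpha: float = 0.05
    min_pct: float = 0.1
    min_cells: int = 3
    comm_eps: float = 0.5
    k: int = 3
    include_bulk: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class PipelineResult:
    """Everything one run produced."""

    report: RankReport
    deg_tables: dict[str, DEGTable]
    enrichments: dict[tuple[str, str], EnrichmentTable]
    mappings: dict[str, list[MappingResult]]
    comm: CommRanking
    baselines: pd.DataFrame


def _prior_lists(checklist: Checklist) -> dict[str, tuple[str, ...]]:
    """Collection -> ordered prior terms; the drug list enters as DRUG."""
    priors = {c: tuple(ts) for c, ts in checklist.pathway_terms.items() if ts}
    if checklist.drug_terms:
        priors[DRUG_COLLECTION] = tuple(checklist.drug_terms)
    return priors


def run(
    data: ExpressionDataset,
    collections: list[GeneSetCollection],
    checklist: Checklist,
    control_net: InteractionNetwork,
    disease_net: InteractionNetwork,
    config: RunConfig = RunConfig(),
    moa_table: MOATable | None = None,
) -> PipelineResult:
    """Execute every stage on in-memory inputs and assemble the report."""
    if checklist.mode == "hypothesis" and checklist.moa_terms and moa_table is not None:
        checklist = expand_moas(checklist, moa_table)
    by_name = {c.name: c for c in collections}
    priors = _prior_lists(checklist)
    missing = sorted(set(priors) - set(by_name))
    if missing:
        raise ValueError(
            f"checklist names collection(s) with no gene-set file: {missing}"
        )

    normalize_counts(data)
    entities = list(data.cell_types)
    deg_tables: dict[str, DEGTable] = {
        ct: deg_per_celltype(data, ct, alpha=config.alpha, min_pct=config.min_pct,
                             min_cells=config.min_cells)
        for ct in entities
    }
    if config.include_bulk:
        deg_tables[BULK] = pseudo_bulk_deg(data, alpha=config.alpha, min_pct=config.min_pct)
        entities = entities + [BULK]
    for name, t in deg_tables.items():
        logger.info("stage=de entity=%s degs=%d", name, len(t))

    # universe per entity: genes surviving the detection filter is the tested
    # family; the observed gene list is its stable superset carrier
    universe = frozenset(g.upper() for g in data.gene_ids)

    enrichments: dict[tuple[str, str], EnrichmentTable] = {}
    mappings: dict[str, list[MappingResult]] = {c: [] for c in priors}
    for cname, prior in priors.items():
        coll = by_name[cname]
        for ent in entities:
            table = enrich_entity(deg_tables[ent], coll, universe)
            enrichments[(ent, cname)] = table
            result = map_entity(ent, cname, prior, rank_terms(table))
            mappings[cname].append(result)
            logger.info(
                "stage=map entity=%s collection=%s matched=%d/%d RS=%.4g",
                ent, cname, result.n_matched, len(prior), result.RS,
            )

    comm = logfdi(control_net, disease_net, eps=config.comm_eps)
    report = build_report(mappings, comm, k=config.k)
    baselines = baseline_rankings(data, deg_tables)
    return PipelineResult(
        report=report,
        deg_tables=deg_tables,
        enrichments=enrichments,
        mappings=mappings,
        comm=comm,
        baselines=baselines,
    )


# ---------------------------------------------------------------------------
# file-level entry point


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_from_files(
    expression: str | Path,
    meta: str | Path,
    checklist_path: str | Path,
    gmt_paths: list[str | Path],
    control_network: str | Path,
    disease_network: str | Path,
    out_dir: str | Path,
    moa_path: str | Path | None = None,
    mode: str | None = None,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Load a file bundle, run the pipeline, and write all output tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = read_expression(expression, meta)
    checklist = load_checklist(checklist_path, mode=mode)
    collections = [read_gmt(p) for p in gmt_paths]
    moa_table = load_moa_table(moa_path) if moa_path else None
    cell_types = tuple(sorted(data.cell_meta["cell_type"].unique()))
    ctl = read_network(control_network, "control", cell_types=cell_types)
    dis = read_network(disease_network, "disease", cell_types=cell_types)

    result = run(data, collections, checklist, ctl, dis, config=config, moa_table=moa_table)

    for ent, tab in result.deg_tables.items():
        tab.table.to_csv(out / f"degs_{ent}.tsv", sep="\t", index=False)
    for (ent, cname), tab in result.enrichments.items():
        tab.table.to_csv(out / f"enrichment_{ent}_{cname}.tsv", sep="\t", index=False)
    rows = []
    for cname, results in result.mappings.items():
        for r in results:
            rows.append(
                {
                    "entity": r.entity, "collection": cname, "n": len(r.prior_terms),
                    "L": r.L, "matched": r.n_matched, "E": r.E, "J": r.J, "RS": r.RS,
                }
            )
    pd.DataFrame(rows).to_csv(out / "mapping_scores.tsv", sep="\t", index=False)
    result.report.rank_table.reset_index(names="entity").to_csv(
        out / "rank_report.tsv", sep="\t", index=False
    )
    pd.DataFrame({"entity": list(result.report.final_order)}).to_csv(
        out / "final_ranking.tsv", sep="\t", index=False
    )
    result.comm.table.to_csv(out / "comm_ranking.tsv", sep="\t", index=False)
    (out / "union_top.txt").write_text(
        "\n".join(sorted(result.report.union_top)) + "\n", encoding="utf-8"
    )
    result.baselines.to_csv(out / "baselines.tsv", sep="\t", index=False)

    inputs = [Path(p) for p in [meta, checklist_path, control_network, disease_network,
                                *(gmt_paths or [])] if p]
    manifest = {
        "version": __version__,
        "config": {
            "alpha": config.alpha, "min_pct": config.min_pct,
            "min_cells": config.min_cells, "comm_eps": config.comm_eps,
            "k": config.k, "include_bulk": config.include_bulk, "seed": config.seed,
        },
        "collections_used": list(result.report.collections_used),
        "collections_dropped": list(result.report.collections_dropped),
        "input_sha256": {str(p): _sha256(p) for p in inputs if p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return result
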