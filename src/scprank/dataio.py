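"""Readers and writers for every on-disk format the pipeline touches.

Expression data travels as a matrix-market sparse matrix (genes x cells)
plus plain-TSV gene/cell id lists and a cell metadata table — the
Cell Ranger-compatible, language-neutral carrier.  Gene sets are standard
GMT.  Cell-cell interaction networks are either square CSV matrices with
matching row/column headers or three-column edge lists.

All readers validate and reject malformed input rather than coercing it;
every write -> read round-trip is an identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .knowledge import normalize_term

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "InteractionNetwork",
    "CONDITIONS",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("disease", "control")


@dataclass
class ExpressionDataset:
    """Annotated count matrix (genes x cells) with per-cell metadata.

    ``counts`` holds raw non-negative integers; ``normalized`` is filled in
    by :func:`scprank.diffexp.normalize_counts` and is ``None`` until then.
    ``cell_meta`` is indexed by cell id with columns ``cell_type`` and
    ``condition`` (levels exactly ``disease``/``control``).
    """

    counts: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    cell_meta: pd.DataFrame
    normalized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.cell_ids = tuple(str(c) for c in self.cell_ids)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene id list length {len(self.gene_ids)} != matrix rows {n_genes}"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell id list length {len(self.cell_ids)} != matrix columns {n_cells}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids are not unique")
        meta = self.cell_meta
        if not {"cell_type", "condition"} <= set(meta.columns):
            raise ValueError("cell_meta needs columns 'cell_type' and 'condition'")
        missing = [c for c in self.cell_ids if c not in meta.index]
        if missing:
            raise ValueError(f"cells without metadata: {missing[:5]}")
        meta = meta.loc[list(self.cell_ids)]
        levels = set(meta["condition"])
        bad = sorted(levels - set(CONDITIONS))
        if bad:
            raise ValueError(
                f"unknown condition label(s) {bad}; allowed: {list(CONDITIONS)}"
            )
        if levels != set(CONDITIONS):
            missing = sorted(set(CONDITIONS) - levels)
            raise ValueError(f"condition level(s) with no cells: {missing}")
        self.cell_meta = meta
        # cell types present in only one condition cannot be tested; flag them
        tab = meta.groupby(["cell_type", "condition"], observed=True).size().unstack(fill_value=0)
        for ct, row in tab.iterrows():
            for cond in CONDITIONS:
                if cond not in row or row.get(cond, 0) == 0:
                    logger.warning("cell type %r has no %s cells", ct, cond)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(sorted(self.cell_meta["cell_type"].unique()))

    def cells_of(self, cell_type: str | None, condition: str) -> np.ndarray:
        """Boolean mask over columns selecting a (cell type, condition) group."""
        m = (self.cell_meta["condition"] == condition).to_numpy()
        if cell_type is not None:
            m &= (self.cell_meta["cell_type"] == cell_type).to_numpy()
        return m


@dataclass(frozen=True)
class GeneSetCollection:
    """A named gene-set collection: term name -> set of (upper-cased) symbols."""

    name: str
    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        norm_seen: set[str] = set()
        clean: dict[str, frozenset[str]] = {}
        for term, genes in self.sets.items():
            key = normalize_term(term)
            if key in norm_seen:
                raise ValueError(f"collection {self.name!r}: duplicate term {term!r}")
            norm_seen.add(key)
            genes = frozenset(str(g).upper() for g in genes)
            if not genes:
                raise ValueError(f"collection {self.name!r}: empty gene set {term!r}")
            clean[str(term)] = genes
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class InteractionNetwork:
    """Directed interaction counts between cell types for one condition.

    ``counts[s, t]`` is the number of inferred source->target interactions
    from cell type ``cell_types[s]`` to ``cell_types[t]`` (the shape of a
    cell-cell communication tool's aggregated output).
    """

    condition: str
    cell_types: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        object.__setattr__(self, "cell_types", tuple(str(c) for c in self.cell_types))
        counts = np.asarray(self.counts)
        n = len(self.cell_types)
        if counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("interaction counts must be non-negative")
        if len(set(self.cell_types)) != n:
            raise ValueError("cell types are not unique")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def reindex(self, cell_types: tuple[str, ...]) -> "InteractionNetwork":
        """Re-order/extend to *cell_types*, zero-filling absent types."""
        n = len(cell_types)
        out = np.zeros((n, n), dtype=self.counts.dtype)
        pos = {c: i for i, c in enumerate(cell_types)}
        for i, ci in enumerate(self.cell_types):
            if ci not in pos:
                raise ValueError(f"cell type {ci!r} absent from target ordering")
            for j, cj in enumerate(self.cell_types):
                out[pos[ci], pos[cj]] = self.counts[i, j]
        return InteractionNetwork(self.condition, tuple(cell_types), out)


# ---------------------------------------------------------------------------
# expression


def _resolve_triplet(matrix_path: Path) -> tuple[Path, Path, Path]:
    if matrix_path.is_dir():
        return (
            matrix_path / "matrix.mtx",
            matrix_path / "genes.tsv",
            matrix_path / "cells.tsv",
        )
    return matrix_path, matrix_path.with_name("genes.tsv"), matrix_path.with_name("cells.tsv")


def read_expression(matrix_path: str | Path, meta_path: str | Path) -> ExpressionDataset:
    """Load an expression dataset.

    *matrix_path* is either a directory containing ``matrix.mtx``,
    ``genes.tsv`` and ``cells.tsv``, or the ``.mtx`` file itself with the two
    TSVs as siblings.  *meta_path* is a TSV with header
    ``cell_id  cell_type  condition``.
    """
    mtx, genes_p, cells_p = _resolve_triplet(Path(matrix_path))
    for p in (mtx, genes_p, cells_p, Path(meta_path)):
        if not p.exists():
            raise FileNotFoundError(f"expression input not found: {p}")
    counts = spio.mmread(str(mtx))
    if sparse.issparse(counts):
        counts = counts.toarray()
    counts = np.asarray(counts)
    gene_ids = genes_p.read_text(encoding="utf-8").split()
    cell_ids = cells_p.read_text(encoding="utf-8").split()
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if list(meta.columns[:3]) != ["cell_id", "cell_type", "condition"]:
        raise ValueError(
            "metadata TSV must have header 'cell_id\\tcell_type\\tcondition', "
            f"got {list(meta.columns)}"
        )
    meta = meta.set_index("cell_id")
    return ExpressionDataset(counts, tuple(gene_ids), tuple(cell_ids), meta)


def write_expression(data: ExpressionDataset, out_dir: str | Path) -> None:
    """Write the matrix-market + TSV carrier read back by :func:`read_expression`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), sparse.coo_matrix(data.counts))
    (out / "genes.tsv").write_text("\n".join(data.gene_ids) + "\n", encoding="utf-8")
    (out / "cells.tsv").write_text("\n".join(data.cell_ids) + "\n", encoding="utf-8")
    meta = data.cell_meta.reset_index()
    meta.columns = ["cell_id", *data.cell_meta.columns]
    meta.to_csv(out / "meta.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a standard GMT file (term, description, genes...); genes upper-cased."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    sets: dict[str, frozenset[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term = fields[0]
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = frozenset(g.upper() for g in fields[2:] if g.strip())
    return GeneSetCollection(name or path.stem, sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in collection.sets.items():
            fh.write("\t".join([term, collection.name, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# networks


def read_network(
    path: str | Path,
    condition: str,
    cell_types: tuple[str, ...] | None = None,
) -> InteractionNetwork:
    """Read an interaction network from square-matrix CSV or edge-list TSV.

    CSV: first column holds row labels, header holds column labels; row and
    column label sets must be identical.  TSV: header ``source target count``.
    *cell_types* optionally declares types absent from the file (zero-filled);
    the final ordering is always lexicographic for determinism.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network file not found: {path}")
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, index_col=0)
        rows, cols = set(map(str, df.index)), set(map(str, df.columns))
        if rows != cols:
            raise ValueError(
                f"{path}: row and column header sets differ: "
                f"{sorted(rows ^ cols)} not shared"
            )
        order = sorted(rows)
        mat = df.loc[order, order].to_numpy()
    elif path.suffix.lower() in (".tsv", ".txt"):
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        if list(df.columns[:3]) != ["source", "target", "count"]:
            raise ValueError(f"{path}: edge list needs header 'source\\ttarget\\tcount'")
        order = sorted(set(df["source"]) | set(df["target"]))
        idx = {c: i for i, c in enumerate(order)}
        mat = np.zeros((len(order), len(order)), dtype=np.int64)
        for _, row in df.iterrows():
            mat[idx[row["source"]], idx[row["target"]]] += int(row["count"])
    else:
        raise ValueError(f"unknown network format: {path.suffix!r} (use .csv or .tsv)")
    if np.any(mat < 0):
        raise ValueError(f"{path}: negative interaction counts")
    net = InteractionNetwork(condition, tuple(order), mat)
    if cell_types is not None:
        union = tuple(sorted(set(cell_types) | set(order)))
        net = net.reindex(union)
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write as square CSV (the canonical carrier for :func:`read_network`)."""
    pd.DataFrame(net.counts, index=net.cell_types, columns=net.cell_types).to_csv(path)
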