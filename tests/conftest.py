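import numpy as np
import pandas as pd
import pytest

from scprank import ExpressionDataset, SyntheticSpec, generate


def make_dataset(counts, cell_types, conditions, gene_ids=None, cell_ids=None):
    """Small in-memory dataset builder for unit tests."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(1, n_genes + 1)]
    cell_ids = cell_ids or [f"c{i}" for i in range(1, n_cells + 1)]
    meta = pd.DataFrame(
        {"cell_type": cell_types, "condition": conditions}, index=cell_ids
    )
    return ExpressionDataset(counts, tuple(gene_ids), tuple(cell_ids), meta)


@pytest.fixture(scope="session")
def small_bundle():
    """One small synthetic study shared across tests (fast to generate)."""
    spec = SyntheticSpec(
        seed=7, n_genes=400, n_cell_types=4, cells_per_type_per_condition=25,
        target_cell_type="Microglia", n_collections=2, sets_per_collection=12,
        genes_per_set=15, prior_depth=4, n_drugs=8, n_planted_drugs=2,
    )
    data, colls, checklist, moa, nets, truth = generate(spec)
    return {
        "spec": spec, "data": data, "collections": colls, "checklist": checklist,
        "moa": moa, "control": nets[0], "disease": nets[1], "truth": truth,
    }
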