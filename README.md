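# scprank

Prior-knowledge-driven prioritization of cell types in case/control
single-cell RNA-seq experiments.

## The problem

A clustered, annotated scRNA-seq dataset with disease and control cells
yields per-cell-type differential expression, pathway enrichment, and
drug-repurposing results — but rarely an answer to the question a disease
researcher actually asks: *which cell types are worth following up?*
Common proxies (number of DEGs, shifts in cell-type proportions) are noisy
and correlate poorly with disease relevance.

`scprank` ranks cell types by how well their data-driven results agree with
*ordered* prior knowledge about the disease — pathway terms, drugs, and
drug mechanisms of action (MOAs) listed most-relevant-first, as exported
from a disease database (discovery mode) or stated by the expert user
(hypothesis mode, with MOA keywords expanded into concrete drugs through a
repurposing-hub lookup table).

## The method

For each cell type and each gene-set collection (pathway databases and a
CMAP-style drug-signature collection):

1. **Differential expression** — per-cell-type Wilcoxon rank-sum test on
   median-library-size-normalized, log1p counts, Benjamini–Hochberg
   adjusted, DEGs at adjusted p < 0.05.
2. **Over-representation** — one-sided hypergeometric test of the DEG set
   against every term; all terms are kept, producing a ranked term list.
3. **Mapping** — each prior term is located in the ranked list by substring
   matching (greedy first hit, each position consumed once). With prior
   terms indexed 1..n and matched positions p_i (NA if unfound, penalty
   distance L+1 where L is the result-list length):

   - E = sqrt( Σ d_i² ), d_i = |i − p_i| (or L+1 for NA)
   - J = (#matched) / n, the Jaccard similarity of asymmetric binary
     presence vectors
   - **RS = E / J** (E / 1e-6 when J = 0); smaller = better agreement

4. **Rank merge** — within each collection, cell types are ranked by
   ascending RS; the mean rank across informative collections gives the
   final order. A pseudo-bulk entity (all cells pooled per condition) can
   be ranked alongside as a bulk RNA-seq comparator.
5. **Communication ranking** — independently, cell types are ranked by the
   perturbation of their cell-cell communication networks:
   LogFDI_i = log2(TNDI_i / TNCI_i), where TNCI_i = (NSC_i + NTC_i)/TIC
   and TNDI_i = (NSD_i + NTD_i)/TID are the cell type's normalized
   source+target interaction totals in the control and disease networks.
6. **Union** — the final prioritization is the union of the top-3 cell
   types by mean rank and the top-3 by |LogFDI|.

A seeded synthetic-data generator produces complete input bundles
(expression, gene sets, checklist, MOA table, networks) with a planted
target cell type, so the whole pipeline is testable end to end without any
external download.

## Worked example

```python
import numpy as np
from scprank import InteractionNetwork, logfdi, top_k_comm

control = InteractionNetwork("control", ("A", "B", "C"),
    np.array([[0, 3, 0], [2, 0, 5], [0, 0, 0]]))
disease = InteractionNetwork("disease", ("A", "B", "C"),
    np.array([[0, 1, 0], [1, 0, 0], [0, 6, 0]]))
print(logfdi(control, disease).table.round(4).to_string(index=False))
```

```
cell_type  NSC  NTC  NSD  NTD  TNCI  TNDI  fold  LogFDI  abs_rank
        A  3.0  2.0  1.0  1.0   0.5  0.25   0.5  -1.000         1
        B  7.0  3.0  1.0  7.0   1.0  1.00   1.0   0.000         3
        C  0.0  5.0  6.0  0.0   0.5  0.75   1.5   0.585         2
```

Cell type A holds half of the 10 control interactions (TNCI = 0.5) but only
a quarter of the 8 disease interactions (TNDI = 0.25): LogFDI = −1, a
two-fold loss of communication share, making A the most perturbed cell
type. See `examples/` for one short script per capability, including the
complete end-to-end prioritization (`examples/01_end_to_end_prioritization.py`,
which recovers the planted Microglia target at mean rank 1.00).

## Command line

```sh
scprank simulate --seed 1 --out bundle/     # synthetic input bundle
scprank run --bundle bundle/ --out results/ # all stages end to end
scprank de / enrich / map / comm / rank     # stage-at-a-time, re-entrant
```

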