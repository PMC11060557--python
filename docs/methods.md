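# Methods

## Model and procedure

`scprank` treats cell-type prioritization as an agreement problem between
two orderings: an ordered prior-knowledge checklist (most disease-relevant
term first) and the data-driven ranking of the same vocabulary produced by
over-representation analysis of each cell type's differential genes.

**Differential expression.** Counts are scaled per cell to the median
library size and log1p-transformed; depth differences between conditions
are thereby removed before testing. Each gene is tested disease vs control
with a two-sided Wilcoxon rank-sum test (exact null when both groups have
at most 8 tie-free observations, normal approximation with tie and
continuity correction otherwise — the scipy policy). p-values are BH
adjusted across the genes tested within one entity (a cell type, or the
pooled pseudo-bulk), matching the per-entity testing family of standard
single-cell marker workflows. DEGs are rows with adjusted p below `alpha`
(default 0.05). Genes detected in fewer than `min_pct` (default 10%) of
cells in both groups are excluded before testing; cell types with fewer
than `min_cells` (default 3) cells in either condition are skipped with an
empty table. Up- and down-regulated genes enter enrichment as one list;
the effect column (log2 ratio of mean normalized expression + 1, disease
over control) is reported but not used downstream.

**Enrichment.** One-sided hypergeometric p per term, with the universe
being the entity's observed gene list (a stable superset of the tested
family) and term gene sets clipped to the universe. BH adjustment runs
across the terms of one collection. Every term is retained: the product of
this stage is a total, deterministic ranking (ascending p, ties broken by
descending overlap then term name), because the mapping stage needs
positions arbitrarily deep in the list. Terms are ranked by raw p-value;
BH adjustment is monotone within a collection, so the adjusted column
would give the same order. Drug repurposing is the same operation against
a collection whose term names are drug identifiers (CMAP-style
`drug_cellline_dose` names match the drug prior by substring).

**Mapping and the ranking score.** Prior term i (1-based) is matched to
the smallest-index unconsumed result term where either normalized string
contains the other; consumption makes matched positions unique, which a
Euclidean distance requires. With matched positions p_i and result length
L:

    E  = sqrt( Σ_i d_i² ),  d_i = |i − p_i|  (matched),  d_i = L + 1  (NA)
    J  = #matched / n
    RS = E / J   (E / 1e-6 when J = 0)

The NA distance L+1 exceeds every attainable matched distance, so
converting any match to NA strictly increases RS — unmatched terms are
penalized through both E and J. RS is zero exactly when every prior term
matches at its own index. The guard constant 1e-6 keeps fully unmatched
entities finite but orders them after every partially matched one.

**Rank merge.** Within each collection, entities are ranked by ascending
RS with average ranks on ties. A collection in which no entity matched any
prior term (J = 0 everywhere) carries no information and is excluded from
the mean; if no collection is informative the run aborts with a request to
revise the checklist rather than emit an arbitrary ranking. The final
order is ascending mean rank, ties alphabetical. The pseudo-bulk
comparator participates in collection ranks (to show what a bulk contrast
would have seen) but never in the top-k union — it is a comparator, not a
cell type.

**Communication ranking.** From directed interaction-count networks
(control, disease) aligned to the sorted union of cell types:
TNCI_i = (NSC_i + NTC_i)/TIC, TNDI_i = (NSD_i + NTD_i)/TID,
LogFDI_i = log2(TNDI_i/TNCI_i). Self-loops count once as source and once
as target; consequently Σ TNCI = Σ TNDI = 2. The ratio is undefined for a
cell type with zero interactions on either side; for those cell types only,
a pseudocount `comm_eps` (default 0.5) is added to both raw totals before
normalization, keeping scores finite while leaving all other cell types on
the exact path. Cell types are ordered by |LogFDI| descending (the
magnitude of perturbation prioritizes; the sign only says gain vs loss),
ties alphabetical. This ranking is kept out of the mean rank — it reflects
a different data modality — and enters through the union of the two top-k
lists (k = 3 by default, giving a union of size 3–6).

## Synthetic data: what it emulates, what it does not

The generator plants a known answer so recovery is measurable:

- counts are gamma-Poisson (negative binomial, dispersion 2.0) with
  log-normal per-gene means (median ≈ 1 count), a standard over-dispersed
  scRNA-seq surrogate at aggregate resolution;
- in the target cell type's disease cells, genes of the checklist's sets
  are shifted multiplicatively by exp(planted_effect) — an additive shift
  of ≈ planted_effect on the log1p scale for well-expressed genes — with
  the shifted fraction of each set decreasing along the checklist order
  (1.0 down to 0.6), so enrichment strength follows the prior order;
- every *other* cell type receives the same magnitude of shift in sets
  *not* on the checklist. All cell types therefore show DEGs and non-empty
  enrichments, and the ranking must discriminate by agreement with the
  prior order, not by the mere presence of signal;
- checklist sets are drawn at random from each collection so that
  p-value-tie ordering by term name cannot mimic the prior order;
- drug signatures of the checklist drugs overlap the planted genes with
  graded strength; the MOA table maps each checklist drug to a distinct
  MOA keyword, exercising the hypothesis-mode expansion chain;
- the disease network equals the control network up to ±8% multiplicative
  jitter, except the target cell type whose outgoing and incoming counts
  are scaled by comm_fold. The target's baseline communication rate is set
  lower than the others' (Poisson 6 vs 12): in a small network a planted
  fold-change necessarily shifts every other type's share in compensation,
  and a modest baseline share keeps the planted |LogFDI| dominant over
  that compensatory shift.

Not emulated: batch effects, doublets, ambient RNA, per-sample
pseudoreplication, annotation uncertainty, and the vocabulary mismatch of
real prior-knowledge sources (synthetic term names match exactly, so
matching robustness beyond case/whitespace differences is exercised only
by unit tests). Passing recovery tests therefore demonstrates that the
scoring chain orders a clean planted signal correctly — not that the
pipeline is robust to the full noise structure of real atlases.

The benchmark condition used by the test suite and the acceptance script
is 2,000 genes, five cell types, 40 cells per type per condition, planted
effect 1.5, prior depth 5, comm_fold 2, with 20 independent seeds and 20
matched null seeds (planted effect 0, comm_fold 1). Under the null most
runs produce no DEGs, hence no mapped collection, and the pipeline
declines to rank; such runs count as "target not recovered" in the null
rate.

## Numerical choices and degenerate inputs

- All tie-breaks are deterministic (average ranks within collections,
  alphabetical elsewhere), so identical inputs reproduce byte-identical
  outputs on any platform.
- Empty DEG list → empty enrichment → all-NA mapping with J = 0; the
  entity lands at the bottom through the 1e-6 guard.
- Empty prior list for a collection is a checklist defect and raises.
- A cell with zero total counts makes library-size scaling undefined and
  raises with the cell named.
- Zero-interaction networks raise; zero-degree cell types take the
  pseudocount path only.
- Matching normalizes case and whitespace only; no fuzzy or synonym
  matching (a deliberate scope boundary — false-positive matches would
  silently improve RS).

## Known limitations

- The DE test treats cells as replicates (no per-sample pseudo-bulk
  aggregation); with few biological samples per condition the DEG lists
  are anti-conservative, which shifts enrichment input but not the scoring
  algebra.
- Greedy first-hit matching is order-dependent by design; a prior term
  phrased very generically can consume a position a later, more specific
  term needed.
- The mean rank weights all informative collections equally; collections
  with very different sizes L are comparable only through rank, not
  through RS magnitude.
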