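"""Hypothesis-driven checklists: expanding MOA keywords into drug names.

In hypothesis mode the user states mechanisms of action rather than drug
names; the lookup table (a drug-repurposing-hub style export) supplies the
concrete drugs, in keyword order, for mapping against drug-signature
enrichment results.
"""

from scprank import Checklist, MOATable, expand_moas

checklist = Checklist(
    disease_name="LAM",
    mode="hypothesis",
    pathway_terms={"KEGG": ("MTOR signaling pathway", "PI3K-Akt signaling pathway")},
    moa_terms=("CDK inhibitor", "MTOR inhibitor", "MEK inhibitor"),
)
table = MOATable((
    ("palbociclib", "CDK inhibitor"),
    ("sirolimus", "MTOR inhibitor"),
    ("everolimus", "MTOR inhibitor"),
    ("selumetinib", "MEK inhibitor"),
    ("aspirin", "cyclooxygenase inhibitor"),
))

expanded = expand_moas(checklist, table)
print("MOA keywords (in relevance order):", ", ".join(checklist.moa_terms))
print("expanded drug list:", ", ".join(expanded.drug_terms))
# drugs appear grouped by keyword, keeping the user's relevance order;
# aspirin is absent because no keyword matches its mechanism
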