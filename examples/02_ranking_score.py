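"""The ranking score RS = E / J on a hand-sized example.

Prior knowledge lists two terms in relevance order; the data-driven
enrichment ranked them in the opposite order.  Each prior term is located
in the result list by substring matching, E is the Euclidean distance
between prior indices and matched positions (unmatched terms contribute a
fixed penalty distance L+1), J is the fraction of prior terms matched, and
RS = E / J — smaller means better agreement.
"""

from scprank import map_entity

prior = ["TNF signaling", "apoptosis", "autophagy"]
result_terms = [
    "Apoptosis Modulation and Signaling",
    "TNF signaling pathway",
    "Cell cycle",
    "Oxidative phosphorylation",
]

r = map_entity("Microglia", "WIKI", prior, result_terms)
for term, pos in zip(r.prior_terms, r.matched_position):
    print(f"  prior {term!r:40} -> position {pos}")
print(f"E = {r.E:.5f}   (distance between prior order and matched positions)")
print(f"J = {r.J:.3f}     (2 of 3 prior terms found; 'autophagy' got the L+1 penalty)")
print(f"RS = {r.RS:.4f}  (E / J; 0 would mean a perfect in-order mapping)")
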