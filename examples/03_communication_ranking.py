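"""Cell-type ranking from communication-network perturbation (LogFDI).

Cell type A has 5 of the 10 control interactions (TNCI = 0.5) but only
2 of the 8 disease interactions (TNDI = 0.25): LogFDI = log2(0.25/0.5) = -1,
a two-fold loss of communication share in disease.
"""

import numpy as np

from scprank import InteractionNetwork, logfdi, top_k_comm

control = InteractionNetwork(
    "control", ("A", "B", "C"),
    np.array([[0, 3, 0],
              [2, 0, 5],
              [0, 0, 0]]),
)
disease = InteractionNetwork(
    "disease", ("A", "B", "C"),
    np.array([[0, 1, 0],
              [1, 0, 0],
              [0, 6, 0]]),
)

ranking = logfdi(control, disease)
print(ranking.table[["cell_type", "NSC", "NTC", "NSD", "NTD",
                     "TNCI", "TNDI", "fold", "LogFDI"]].round(4).to_string(index=False))
print("\nranked by |LogFDI| (largest perturbation first):",
      " > ".join(top_k_comm(ranking, 3)))
# A's LogFDI of -1 reads: its share of network communication halved in disease
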