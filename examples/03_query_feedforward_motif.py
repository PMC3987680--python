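"""Build a miniature feed-forward motif and query one gene's context.

Mirrors the canonical worked case: a repressor (ZNF24-like) targeted by
ten upregulated miRNAs, and its experimentally validated target (VEGFA-
like) targeted by eleven miRNAs — five shared with the repressor — whose
expression nevertheless rises because derepression overrides the miRNAs.
"""

import pandas as pd

from tomnet import EdgeSet, TargetClassification, build_tom_network, query_gene
from tomnet.io_formats import REL_MIRNA, REL_REPRESSES

mirna_edges = EdgeSet()
shared = [f"miR-S{i}" for i in range(5)]
for m in shared + [f"miR-R{i}" for i in range(5)]:
    mirna_edges.add(m, REL_MIRNA, "ZNF24")
for m in shared + [f"miR-V{i}" for i in range(6)]:
    mirna_edges.add(m, REL_MIRNA, "VEGFA")

repressor_edges = EdgeSet()
repressor_edges.add("ZNF24", REL_REPRESSES, "VEGFA")

classification = TargetClassification(
    pd.DataFrame(
        {"n_mirnas": [11, 10], "target_class": ["PC", "IC"]},
        index=["VEGFA", "ZNF24"],
    )
)

network = build_tom_network(mirna_edges, repressor_edges, classification)
record, narrative = query_gene(network, "VEGFA")
print(narrative)
print()
print(f"shared miRNAs closing the loop: {sorted(record.shared_mirnas)}")
print("  -> despite 11 targeting miRNAs, VEGFA is upregulated (PC): "
      "loss of its repressor outweighs direct miRNA repression")
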