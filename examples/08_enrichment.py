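"""Over-representation of a gene list in named gene sets (GMT-style).

A plain hypergeometric upper-tail test against each set, BH-adjusted; the
miRNA x pathway matrix summarizes which miRNAs hit which sets and feeds
the hierarchical clustering used for panel subgrouping.
"""

from mircna.enrichment import (
    GeneSetCollection,
    mirna_pathway_matrix,
    ora_hypergeometric,
)
from mircna.expression import hierarchical_cluster

universe = [f"GENE{i}" for i in range(200)]
collection = GeneSetCollection(
    {
        "hippo_signaling": frozenset(universe[0:25]),
        "cell_cycle": frozenset(universe[20:60]),
        "axon_guidance": frozenset(universe[100:140]),
    },
    universe=frozenset(universe),
)

query = universe[0:15] + universe[150:155]  # enriched for hippo_signaling
result = ora_hypergeometric(query, collection)
print(result[["set", "overlap", "set_size", "p", "q"]].round(6)
      .to_string(index=False))

targets = {
    "miR-A": universe[0:10],
    "miR-B": universe[2:12],
    "miR-C": universe[100:115],
}
matrix = mirna_pathway_matrix(targets, collection)
print("\nmiRNA x pathway target counts:")
print(matrix.to_string())
clusters = hierarchical_cluster(matrix.astype(float), axis="rows")
print("clustering leaf order:", clusters.leaf_order)
# miR-A and miR-B share most targets and cluster together, apart from the
# axon-guidance-directed miR-C.
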