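"""Vote predicted targets across databases and intersect with CNA genes.

A (miRNA, gene) prediction survives when at least 2 of 3 databases agree;
the surviving union is then intersected with the genes inside the
recurrent CNA regions, shrinking the candidate list to genes potentially
hit by both mechanisms.
"""

from mircna.integrate import (
    TargetPredictionSet,
    intersect_targets_with_cna_genes,
    vote_targets,
)

db1 = TargetPredictionSet.from_pairs("micro-t", [
    ("miR-A", "MYC"), ("miR-A", "CCND2"), ("miR-A", "DICER1"),
    ("miR-B", "IGF1R"), ("miR-B", "ETV6"),
])
db2 = TargetPredictionSet.from_pairs("mirdb", [
    ("miR-A", "MYC"), ("miR-A", "CCND2"),
    ("miR-B", "IGF1R"), ("miR-B", "PIK3CA"),
])
db3 = TargetPredictionSet.from_pairs("targetscan", [
    ("miR-A", "MYC"),
    ("miR-B", "ETV6"), ("miR-B", "CDKN1A"),
])

voted = vote_targets([db1, db2, db3], min_databases=2)
for mirna, genes in sorted(voted.items()):
    print(f"{mirna}: >= 2-of-3 targets = {sorted(genes)}")

region_genes = [["MYC", "IGF1R", "TP53"], ["GATA3", "ETV6"]]
common, summary = intersect_targets_with_cna_genes(voted, region_genes)
print(f"\nvoted-target union: {summary['n_targets_union']}")
print(f"also inside CNA regions: {summary['n_intersected']} -> {sorted(common)}")
print(f"reduction: {summary['pct_reduction']}%")
# Genes predicted by only one database (DICER1, PIK3CA, CDKN1A) are gone;
# the intersection keeps only voted targets lying in altered regions.
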