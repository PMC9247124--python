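"""Mine disease→gene association rules from chemical transactions.

Four chemicals with gene/disease links; mining finds every itemset present
in at least half of them, then scores {disease} → {gene} rules.
"""

from dili_netminer import (
    InteractionRecord,
    PathwayHierarchy,
    build_association_db,
    mine_frequent_itemsets,
    query_disease_genes,
    score_gene_disease_rules,
)

records = [
    InteractionRecord(c, t, "disease" if t == "cholestasis" else "gene")
    for c, targets in {
        "chem1": ("ABCC2", "NQO1", "cholestasis"),
        "chem2": ("ABCC2", "cholestasis"),
        "chem3": ("NQO1",),
        "chem4": ("ABCC2", "NQO1", "cholestasis"),
    }.items()
    for t in targets
]

db = build_association_db(records, PathwayHierarchy())
itemsets = mine_frequent_itemsets(db, min_support=0.5)
print(f"{len(itemsets)} frequent itemsets at support >= 0.5 over {db.n_transactions} chemicals")

scores = score_gene_disease_rules(db, itemsets, "cholestasis")
for s in scores:
    print(f"  {s.disease_id} -> {s.gene}: confidence={s.confidence:.2f} "
          f"support={s.support:.2f} ({s.n_cooccurring_chemicals} chemicals)")
print("candidates:", query_disease_genes(scores, top_k=250))
# Confidence is the fraction of disease-linked chemicals also linked to the
# gene: ABCC2 co-occurs with cholestasis in all 3 of its chemicals (1.00),
# NQO1 in 2 of 3 (0.67) — the genes most probably connected to the disease.
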