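"""Hypergeometric over-representation of a small gene list.

A query list that exactly covers one 5-gene pathway in a 10-gene universe
has upper-tail probability C(5,5)C(5,0)/C(10,5) = 1/252: the chance of
drawing all five annotated genes in five draws without replacement.
"""

from degnet import PathwayDB, enrich, hypergeom_pvalue

print("P[X >= 5] for k=5, n=5, K=5, N=10:", hypergeom_pvalue(5, 5, 5, 10))

db = PathwayDB(
    pathways={
        "PW_TARGET": ("target pathway", frozenset({"A", "B", "C", "D", "E"})),
        "PW_OTHER": ("unrelated pathway", frozenset({"F", "G", "H", "I", "J"})),
    }
)
table = enrich({"A", "B", "C", "D", "E"}, db)
print(table[["pathway_id", "overlap_k", "pathway_size_K", "p_value", "fdr",
             "bonferroni"]].to_string(index=False))
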