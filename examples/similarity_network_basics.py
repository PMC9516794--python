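"""Build a Kruskal-Wallis similarity network for a handful of genes.

Two co-regulated genes have statistically indistinguishable expression
across the case samples, so their pairwise KW p value is high and they
are joined by an edge; a gene with a shifted distribution gets p below
the 0.005 threshold and stays disconnected.  Closeness centrality then
picks the essential (peripheral, CC <= average) genes.
"""

import pandas as pd

from degnet import (
    ExpressionMatrix,
    closeness_centrality,
    select_essential,
    similarity_matrix,
    to_network,
)

samples = [f"s{i}" for i in range(8)]
values = pd.DataFrame(
    {
        "GENEA": [8.1, 8.0, 7.9, 8.2, 8.0, 8.1, 7.8, 8.0],
        "GENEB": [8.0, 8.2, 8.1, 7.9, 8.1, 8.0, 8.0, 8.1],
        "GENEC": [12.0, 12.1, 11.9, 12.2, 12.0, 12.1, 11.8, 12.0],
    },
    index=samples,
).T
groups = pd.Series(["case"] * 8, index=samples)
expr = ExpressionMatrix(values=values, groups=groups)

sm = similarity_matrix(expr, ["GENEA", "GENEB", "GENEC"], sample_scope="cases")
print("similarity cells (0 = dissimilar):")
print(pd.DataFrame(sm.values, index=sm.genes, columns=sm.genes).round(3))

net = to_network(sm)
scores = closeness_centrality(net)
essential = select_essential(net, scores)
print("closeness:", {g: round(c, 3) for g, c in scores.scores.items()},
      "average:", round(scores.average, 3))
print("essential genes (CC <= average):", sorted(essential.genes))
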