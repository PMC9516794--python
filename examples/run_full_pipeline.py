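"""Run the complete DEG pre-processing pipeline on synthetic data.

Generates the four inputs (expression, DEG table, PPI, pathways) with a
planted up- and down-regulated module, runs filtering -> similarity
networks -> closeness -> PPI expansion -> Bottleneck selection ->
enrichment, and prints the per-stage counts and the top pathway of each
branch.  The planted pathway (PW_PLANTED) should rank first in both.
"""

from degnet import make_truth, run
from degnet.simulate import (
    simulate_deg_table,
    simulate_expression,
    simulate_pathways,
    simulate_ppi,
)

truth = make_truth(n_genes=300, module_size=25, seed=0)
expr = simulate_expression(300, 10, 10, truth)
deg = simulate_deg_table(expr, truth)
ppi = simulate_ppi(300, 2, truth)
pathways = simulate_pathways(50, truth=truth)

result = run(deg, expr, ppi, pathways)

print("stage counts:", result.report["counts"])
for branch in (result.up, result.down):
    top = branch.enrichment.iloc[0]
    print(
        f"{branch.regulation:>4} branch: {len(branch.essential)} essential -> "
        f"{len(branch.community_members)} community -> {len(branch.relevant)} relevant; "
        f"top pathway {top.pathway_id} (p={top.p_value:.3g}, fdr={top.fdr:.3g})"
    )
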