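"""Determinism and statistical calibration of the synthetic generators."""

import networkx as nx
import numpy as np
import pytest

from degnet.io import read_gmt, write_gmt
from degnet.similarity import kruskal_wallis
from degnet.simulate import (
    PlantedTruth,
    make_truth,
    simulate_deg_table,
    simulate_expression,
    simulate_pathways,
    simulate_ppi,
)


class TestDeterminism:
    def test_expression_is_pure_in_seed(self):
        truth = make_truth(seed=42)
        a = simulate_expression(300, 10, 10, truth)
        b = simulate_expression(300, 10, 10, truth)
        assert a.values.equals(b.values)
        assert not a.values.equals(simulate_expression(300, 10, 10, make_truth(seed=43)).values)

    def test_ppi_is_pure_in_seed(self):
        truth = make_truth(seed=5)
        g1 = simulate_ppi(300, 2, truth)
        g2 = simulate_ppi(300, 2, truth)
        assert set(g1.edges()) == set(g2.edges())

    def test_pathways_are_pure_in_seed(self):
        truth = make_truth(seed=5)
        assert (
            simulate_pathways(50, truth=truth).pathways
            == simulate_pathways(50, truth=truth).pathways
        )


class TestExpression:
    def test_zero_effect_means_equal_in_expectation(self):
        truth = make_truth(seed=1, effect_size=0.0)
        expr = simulate_expression(300, 10, 10, truth)
        cases = expr.values[expr.samples_in("cases")].mean(axis=1)
        controls = expr.values[expr.samples_in("controls")].mean(axis=1)
        diff = (cases - controls).loc[list(truth.module_genes)]
        assert abs(diff.mean()) < 0.15

    def test_module_pair_similarity_survives_threshold(self):
        """Two co-regulated module genes should read as similar (KW p above
        the 0.005 threshold) in nearly every realization at noise 0.1."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            truth = make_truth(n_genes=10, module_size=2, seed=seed, noise_sd=0.1)
            expr = simulate_expression(10, 10, 10, truth)
            g1, g2 = truth.up_module
            cases = expr.samples_in("cases")
            p = kruskal_wallis(
                [expr.values.loc[g1, cases], expr.values.loc[g2, cases]]
            ).p_value
            hits += p > 0.005
        assert hits / n_seeds >= 0.95

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_truth(n_genes=10, module_size=8)
        with pytest.raises(ValueError):
            simulate_expression(300, 1, 10, make_truth(seed=0))


@pytest.fixture(scope="module")
def monte_carlo():
    """200 replicates of the reference conditions, summarized per gene."""
    planted_pass = 0
    sign_ok = 0
    background_pass = 0
    n_background = 0
    n_seeds = 200
    for seed in range(n_seeds):
        truth = make_truth(n_genes=60, module_size=5, seed=seed)
        expr = simulate_expression(60, 10, 10, truth)
        deg = simulate_deg_table(expr, truth).set_index("gene_symbol")
        up_gene = truth.up_module[0]
        row = deg.loc[up_gene]
        planted_pass += (row["adj_p_value"] <= 0.005) and (abs(row["log_fc"]) >= 1.5)
        sign_ok += row["log_fc"] > 0
        bg = deg.loc[[g for g in deg.index if g not in truth.module_genes]]
        background_pass += int(
            ((bg["adj_p_value"] <= 0.005) & (bg["log_fc"].abs() >= 1.5)).sum()
        )
        n_background += len(bg)
    return {
        "planted_rate": planted_pass / n_seeds,
        "sign_rate": sign_ok / n_seeds,
        "background_rate": background_pass / n_background,
    }


class TestDegTable:
    def test_planted_gene_passes_thresholds(self, monte_carlo):
        assert monte_carlo["planted_rate"] >= 0.95

    def test_logfc_sign_matches_planted_direction(self, monte_carlo):
        assert monte_carlo["sign_rate"] >= 0.99

    def test_background_pass_rate_below_nominal(self, monte_carlo):
        assert monte_carlo["background_rate"] <= 0.005

    def test_schema_matches_reader_contract(self, default_inputs):
        deg = default_inputs["deg"]
        assert list(deg.columns) == [
            "probe_id",
            "gene_symbol",
            "p_value",
            "adj_p_value",
            "log_fc",
        ]
        assert deg["p_value"].between(0, 1, inclusive="right").all()
        assert deg["adj_p_value"].between(0, 1, inclusive="right").all()


class TestPpiAndPathways:
    def test_graph_connected_and_contains_modules(self, default_truth):
        g = simulate_ppi(300, 2, default_truth)
        assert nx.is_connected(g)
        assert default_truth.module_genes <= set(g.nodes())

    def test_planted_pathway_covers_modules(self, default_truth):
        db = simulate_pathways(50, truth=default_truth)
        _, members = db.pathways[default_truth.planted_pathway_id]
        assert default_truth.module_genes <= members

    def test_decoys_avoid_module_genes(self, default_truth):
        db = simulate_pathways(50, truth=default_truth)
        for pid, (_, members) in db.pathways.items():
            if pid != default_truth.planted_pathway_id:
                assert not members & default_truth.module_genes

    def test_gmt_round_trip(self, tmp_path, default_truth):
        db = simulate_pathways(20, truth=default_truth)
        write_gmt(db, tmp_path / "sim.gmt")
        assert read_gmt(tmp_path / "sim.gmt").pathways == db.pathways

    def test_overlapping_modules_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            PlantedTruth(up_module=("G0001",), down_module=("G0001",))
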