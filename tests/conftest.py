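import pytest

from degnet.simulate import (
    make_truth,
    simulate_deg_table,
    simulate_expression,
    simulate_inputs,
    simulate_pathways,
    simulate_ppi,
)


@pytest.fixture(scope="session")
def default_truth():
    return make_truth(seed=0)


@pytest.fixture(scope="session")
def default_inputs(default_truth):
    """In-memory synthetic inputs at the reference study conditions."""
    expr = simulate_expression(300, 10, 10, default_truth)
    deg = simulate_deg_table(expr, default_truth)
    ppi = simulate_ppi(300, 2, default_truth)
    db = simulate_pathways(50, truth=default_truth)
    return {"truth": default_truth, "expr": expr, "deg": deg, "ppi": ppi, "db": db}


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The same conditions written to disk as the five input files."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_inputs(outdir, seed=0)
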