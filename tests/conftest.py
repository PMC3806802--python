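import numpy as np
import pytest

import bruwave as bw


@pytest.fixture(scope="session")
def mixed_fix():
    """Mixed-length fixture (2 kb-500 kb, both size classes), control + drug."""
    return bw.make_fixture(
        300, seed=7, config=bw.SimConfig(depth=300_000),
        conditions=("control", "cpt0"))


@pytest.fixture(scope="session")
def long_fix():
    """Long-gene fixture for metagene/mechanism checks at high depth."""
    return bw.make_fixture(
        400, {"kind": "log_uniform", "low": 100_000, "high": 300_000},
        seed=7, config=bw.SimConfig(depth=1_000_000),
        conditions=("control", "cpt0"))


@pytest.fixture(scope="session")
def long_profiles(long_fix):
    params = bw.AnalysisParams()
    genes = long_fix["genes"]
    expr_c = bw.quantify_condition(genes, long_fix["reads"]["control"],
                                   "control")
    cohort = bw.select_cohort(expr_c, genes, params)
    prof = {}
    for cond in ("control", "cpt0"):
        reads = long_fix["reads"][cond]
        prof[cond] = bw.build_profile(cohort, reads, len(reads), params,
                                      condition=cond)
    return params, cohort, prof


@pytest.fixture(scope="session")
def recovery_results_default():
    """Wave-rate recovery study at the default post-washout rate."""
    return bw.rate_recovery_study(v_recovery=1200.0, seed=1, n_genes=100,
                                  depth=1_000_000, n_bootstrap=100)


def toy_genes():
    return [
        bw.GeneModel("gA", "chr1", 1000, 6000, "+"),
        bw.GeneModel("gB", "chr1", 20_000, 30_000, "-"),
    ]


@pytest.fixture
def genes_pair():
    return toy_genes()
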