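import numpy as np
import pytest

import trophoshift as ts


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — ultrametric, root age 2."""
    return ts.read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def bd_tree():
    """A 40-tip birth-death tree of height 100 (seeded)."""
    scenario = ts.SimScenario(n_tips=40, J=6, K_true=3, seed=11)
    rng = np.random.default_rng(11)
    from trophoshift.synth import simulate_tree
    return simulate_tree(scenario, rng)


@pytest.fixture(scope="session")
def small_truth_and_chain():
    """A 30-tip, 3-state simulation and a short fitted chain (reused widely)."""
    scenario = ts.SimScenario(n_tips=30, J=5, K_true=3, seed=7,
                              sample_size=("fixed", 200))
    truth = ts.simulate(scenario)
    config = ts.ModelConfig(K=8, iterations=600, thin=5, burnin=40, seed=8)
    chain = ts.gibbs_sample(truth.tree, truth.counts, config)
    return truth, chain
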