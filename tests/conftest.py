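import numpy as np
import pytest

import vaftree as vt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest error-free simulated dataset with its generating tree."""
    rng = np.random.default_rng(99)
    params = vt.BDParams(0.5, 200)
    tree = vt.sample_tree(params, rng)
    mu = 2e-3 / tree.total_length  # mu*L = 2e-3, comfortably single-hit
    asn = vt.assign_mutations(tree, mu, 20000, rng)
    table = vt.simulate_reads(
        asn, tree, vt.DepthModel("fixed", 100), 0.0, rng
    ).to_two_state()
    return {"params": params, "tree": tree, "mu": mu, "table": table}
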