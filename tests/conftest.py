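import numpy as np
import pytest

from seminalseq import normalization as nz
from seminalseq.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """A 300-gene default-condition experiment with promoters and truth."""
    return simulate_experiment(SimConfig(n_genes=300, seed=101))


@pytest.fixture(scope="session")
def small_norm(small_sim):
    return nz.tmm_factors(small_sim.counts)


@pytest.fixture(scope="session")
def small_logexpr(small_sim, small_norm):
    from seminalseq.de import log_expression

    filt = nz.expression_filter(small_sim.counts)
    fp = nz.fpkm(small_sim.counts, small_sim.annotation["length_bp"], small_norm)
    return log_expression(fp.loc[filt])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
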