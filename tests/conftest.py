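import numpy as np
import pytest

from endcall import SimConfig, call_ends, scan_genome, simulate


@pytest.fixture(scope="session")
def sim():
    """The default desk-scale scenario (100 kb, 20 genes, 30 planted
    ends of which 8 rho-type, seed 42)."""
    return simulate(SimConfig())


@pytest.fixture(scope="session")
def consensus(sim):
    """Consensus 3' ends called from the two Term-seq replicates."""
    ends, infos = call_ends(sim.termseq)
    return ends, infos


@pytest.fixture(scope="session")
def rho_scores(sim):
    """Genome-wide Rho scan of the +/-BCM DirectRNA tracks."""
    return scan_genome(sim.direct_bcm, sim.direct_untreated)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
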