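import numpy as np
import pytest

from transcurate import (
    SimConfig,
    generate_proteome,
    generate_transcriptome,
)
from transcurate.synthetic import emit_hits


@pytest.fixture(scope="session")
def proteome():
    return generate_proteome(60, (120, 200), "Cgig", seed=11)


@pytest.fixture(scope="session")
def sim(proteome):
    """A small mixed contig set with planted chimeras/duplicates/noncoding."""
    cfg = SimConfig(
        n_normal=12, n_chimera=6, n_contained=4, n_noncoding=8, seed=7
    )
    contigs, truth = generate_transcriptome(proteome, cfg)
    return cfg, contigs, truth


@pytest.fixture(scope="session")
def sim_hits(proteome, sim):
    _, contigs, truth = sim
    return emit_hits(contigs, proteome, truth, noise=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
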