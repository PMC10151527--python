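import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heterosim.genome import GenomeMap, build_genome
from heterosim.trait_model import GeneEffect, TraitModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """Two chromosomes of 100 cM with 10 genes each."""
    return build_genome(2, 100.0, 10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def genome_with_r(r: float) -> GenomeMap:
    """Two genes on one chromosome at the map distance giving recombination ``r``."""
    if not 0.0 < r < 0.5:
        raise ValueError("need 0 < r < 0.5")
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return GenomeMap((max(d, 1.0),), np.array([0, 0]), np.array([0.0, d]))


def two_gene_trait(I=None, m=(5.0, 5.0), a=(1.0, 1.0), d=(0.4, 0.8), pair_type="custom"):
    """A two-gene trait, optionally with one epistatic pair with table ``I``."""
    from heterosim.trait_model import EpistaticPair

    genes = [GeneEffect(0, m[0], a[0], d[0]), GeneEffect(1, m[1], a[1], d[1])]
    pairs = []
    if I is not None:
        pairs = [EpistaticPair(0, 1, pair_type, np.asarray(I, float), 0.0, 0.0)]
    return TraitModel(genes, pairs)
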