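import numpy as np
import pytest

from wlassoqtl import GeneticMap, GenotypeMatrix, arabidopsis_like_map


@pytest.fixture(scope="session")
def ara_map() -> GeneticMap:
    return arabidopsis_like_map()


@pytest.fixture
def tiny_map() -> GeneticMap:
    """One chromosome, three markers at 0 / 2 / 5 cM."""
    return GeneticMap(("m1", "m2", "m3"), ("1", "1", "1"), np.array([0.0, 2.0, 5.0]))


@pytest.fixture
def tiny_geno(tiny_map) -> GenotypeMatrix:
    vals = np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    return GenotypeMatrix(vals, ("r1", "r2"), tiny_map)


def qtl_design(rng: np.random.Generator, n=165, p=69, sigma2=1.0):
    """Independent binary design with six alternating +-0.5 effects."""
    X = rng.integers(0, 2, (n, p)).astype(float)
    k = min(6, p)
    truth = np.unique(((np.arange(k) + 0.5) * p / k).astype(int))
    theta = np.zeros(p)
    theta[truth] = 0.5 * (-1.0) ** np.arange(len(truth))
    y = X @ theta + rng.normal(0.0, np.sqrt(sigma2), n)
    return X, y, truth
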