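import numpy as np
import pytest

from pollenscreen.popgen_stats import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def example_matrix():
    """Four haplotypes {000, 001, 011, 111} with a known outgroup."""
    alleles = np.array([list("000"), list("001"), list("011"), list("111")])
    return HaplotypeMatrix(
        "example", alleles, [1, 2, 3], outgroups={"og": np.array(list("000"))}
    )


def random_binary_matrix(rng, n_max=10, s_max=20):
    """A random small haplotype matrix with a random ancestral vector; every
    column is guaranteed polymorphic."""
    n = int(rng.integers(4, n_max + 1))
    s = int(rng.integers(1, s_max + 1))
    alleles = np.full((n, s), "0", dtype="U1")
    for j in range(s):
        k = int(rng.integers(1, n))
        rows = rng.choice(n, size=k, replace=False)
        alleles[rows, j] = "1"
    anc = rng.choice(["0", "1"], size=s, p=[0.8, 0.2]).astype("U1")
    return HaplotypeMatrix(
        f"rand_{n}_{s}", alleles, np.arange(1, s + 1), outgroups={"og": anc}
    )
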