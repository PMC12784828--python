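import numpy as np
import pytest

from sswas.io import GenotypePanel, Pedigree
from sswas.simulate import SimConfig, simulate_dataset


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree.from_records([("A", "0", "0"), ("B", "0", "0"), ("C", "A", "B")])


@pytest.fixture(scope="session")
def small_dataset():
    """Shared small simulated data set (600 animals, 1000 SNPs)."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def random_pedigree(n: int, rng: np.random.Generator, p_founder: float = 0.2) -> Pedigree:
    """Random valid pedigree: each animal's parents drawn from earlier animals."""
    ids = [f"a{i}" for i in range(n)]
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(1, n):
        if rng.random() > p_founder:
            sire[i] = rng.integers(0, i)
            dam[i] = rng.integers(0, i)
            if dam[i] == sire[i] and i > 1:
                dam[i] = (sire[i] + 1) % i
    return Pedigree(ids, sire, dam)


def binomial_panel(
    n: int, m: int, rng: np.random.Generator, maf_low: float = 0.1
) -> GenotypePanel:
    """Unrelated individuals, independent SNPs (drift-free equilibrium)."""
    p = rng.uniform(maf_low, 0.5, m)
    g = rng.binomial(2, p, size=(n, m)).astype(float)
    chrom = np.sort(rng.integers(1, 6, m))
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chrom):
        k = int(np.sum(chrom == c))
        pos[chrom == c] = np.sort(rng.choice(10**8, k, replace=False))
    return GenotypePanel([f"i{i}" for i in range(n)], [f"s{j}" for j in range(m)], g, chrom, pos)
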