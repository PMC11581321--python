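import numpy as np
import pytest

from canineqg import relmat, simpop, varcomp
from canineqg.formats import GenotypeMatrix
from canineqg.pedigree import Pedigree


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study-shaped configuration used by several suites."""
    return simpop.SimConfig(
        seed=42,
        n_founders=12,
        n_generations=3,
        matings_per_generation=8,
        offspring_per_mating=2,
        n_chromosomes=4,
        snps_per_chromosome=30,
        genotyped_fraction=0.6,
        missing_rate=0.05,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return simpop.simulate_population(small_config)


@pytest.fixture(scope="session")
def default_population():
    """One study-sized population (378 animals, 234 genotyped)."""
    cfg = simpop.SimConfig(seed=7, snps_per_chromosome=20)
    return cfg, simpop.simulate_population(cfg)


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random valid pedigree: each animal's parents drawn from earlier
    animals (or unknown), respecting sexes."""
    rows = []
    sexes = []
    for i in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        sire = dam = None
        males = [f"X{j}" for j in range(i) if sexes[j] == "M"]
        females = [f"X{j}" for j in range(i) if sexes[j] == "F"]
        if males and rng.random() < 0.7:
            sire = males[rng.integers(len(males))]
        if females and rng.random() < 0.7:
            dam = females[rng.integers(len(females))]
        rows.append((f"X{i}", sire, dam, sex))
        sexes.append(sex)
    return Pedigree.from_tuples(rows, sort=False)


def random_genotypes(rng: np.random.Generator, n: int, m: int,
                     missing_rate: float = 0.0) -> GenotypeMatrix:
    freqs = rng.uniform(0.1, 0.5, size=m)
    dosage = rng.binomial(2, freqs, size=(n, m)).astype(float)
    if missing_rate:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan
    return GenotypeMatrix(
        [f"a{i}" for i in range(n)],
        [f"s{j}" for j in range(m)],
        np.array([str(1 + j % 5) for j in range(m)], dtype=object),
        np.arange(1, m + 1) * 1000,
        np.array(["A"] * m, dtype=object),
        np.array(["G"] * m, dtype=object),
        dosage,
    )
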