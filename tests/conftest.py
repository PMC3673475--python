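import numpy as np
import pytest

from spawnrs.genotypes import AlleleFrequencyTable, GenotypeTable, LocusDef


@pytest.fixture
def two_loci():
    return [LocusDef("LocA", 4), LocusDef("LocB", 2)]


@pytest.fixture
def small_table(two_loci):
    alleles = np.array(
        [
            [[100, 104], [50, 52]],
            [[100, 100], [52, 54]],
            [[104, 108], [50, 50]],
        ]
    )
    return GenotypeTable(two_loci, ["ind1", "ind2", "ind3"], alleles)


def random_table(rng, n=100, n_loci=8, n_alleles=25, motif=4) -> GenotypeTable:
    loci = [LocusDef(f"L{j}", motif) for j in range(n_loci)]
    sizes = 100 + motif * np.arange(n_alleles)
    alleles = rng.choice(sizes, size=(n, n_loci, 2))
    return GenotypeTable(loci, [f"I{k:04d}" for k in range(n)], alleles)


def uniform_freqs(n_loci=8, n_alleles=25, motif=4) -> AlleleFrequencyTable:
    loci = [LocusDef(f"L{j}", motif) for j in range(n_loci)]
    sizes = 100 + motif * np.arange(n_alleles)
    freqs = {
        l.name: {int(s): 1.0 / n_alleles for s in sizes} for l in loci
    }
    return AlleleFrequencyTable(loci, freqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
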