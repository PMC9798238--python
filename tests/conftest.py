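import numpy as np
import pytest

from binqtl.genome import build_genome_template
from binqtl.simulate import corrupt_genotypes, simulate_ril_population


@pytest.fixture(scope="session")
def small_template():
    """Two 50-Mb/50-cM chromosomes with 800 SNPs each."""
    return build_genome_template(
        2, [50_000_000, 50_000_000], [50.0, 50.0], 800, seed=101
    )


@pytest.fixture(scope="session")
def small_population(small_template):
    """60 F7 lines with clean calls plus their true genome mosaics."""
    truth, clean = simulate_ril_population(small_template, 60, 6, seed=102)
    return truth, clean


@pytest.fixture(scope="session")
def small_noisy(small_population):
    _, clean = small_population
    return corrupt_genotypes(clean, 0.01, 0.05, seed=103)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
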