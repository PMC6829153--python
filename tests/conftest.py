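import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from sexantag.genome_sim import GenomeSimConfig, run_genome_sim
from sexantag.model import FitnessScheme, GenotypeFrequencies, MateChoiceMatrix


@pytest.fixture
def additive_scheme() -> FitnessScheme:
    return FitnessScheme(s=0.1, alpha=1.0, hf=0.5, hm=0.5)


@pytest.fixture
def random_mating() -> MateChoiceMatrix:
    return MateChoiceMatrix.random_mating()


@pytest.fixture
def hw_half() -> GenotypeFrequencies:
    return GenotypeFrequencies.hardy_weinberg(0.5)


def _mini_cfg(neutral: bool, seed: int) -> GenomeSimConfig:
    # small population with scaled-up mutation rate so tens of loci segregate
    return GenomeSimConfig(
        carrying_capacity=300,
        genome_length=1e6,
        recombination_rate=1e-7,
        mutation_rate=1e-7,
        steps=80,
        replicates=1,
        neutral=neutral,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mini_antagonistic_population():
    res = run_genome_sim(_mini_cfg(neutral=False, seed=101))
    return res.replicates[0]


@pytest.fixture(scope="session")
def mini_neutral_population():
    res = run_genome_sim(_mini_cfg(neutral=True, seed=102))
    return res.replicates[0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
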