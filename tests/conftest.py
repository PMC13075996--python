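import pytest

from asvnet.preprocess import css_normalize, prevalence_filter
from asvnet.synthetic import SimulationConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (56 samples x 350 ASVs, planted
    effects) shared by read-only tests."""
    counts, taxonomy, phenotypes, truth = generate(SimulationConfig(seed=0))
    return counts, taxonomy, phenotypes, truth


@pytest.fixture(scope="session")
def default_abundances(default_dataset):
    counts, _, _, _ = default_dataset
    return css_normalize(prevalence_filter(counts, 20))
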