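import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from herbnet.corpus import HerbRecord, Prescription, normalize_corpus
from herbnet.synthetic import GeneratorConfig, generate_dataset

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_lexicon():
    return [
        HerbRecord("Ji Xue Teng", frozenset({"JiXueTeng-alt"}), property="Warm"),
        HerbRecord("Huang Qi", frozenset({"HQ"}), property="Warm"),
        HerbRecord("Ku Shen", frozenset(), property="Cold"),
        HerbRecord("A", frozenset({"A-syn"})),
        HerbRecord("B", frozenset()),
    ]


def make_corpus(formulae):
    """Build a normalized corpus from plain herb-name lists."""
    return [
        Prescription(id=f"p{i}", herbs=tuple(herbs))
        for i, herbs in enumerate(formulae)
    ]


def random_corpus(rng, n_formulae, n_herbs, min_size=2, max_size=None):
    """A random normalized corpus over a small vocabulary."""
    names = [f"h{i}" for i in range(n_herbs)]
    max_size = max_size or n_herbs
    out = []
    for i in range(n_formulae):
        size = int(rng.integers(min_size, max_size + 1))
        herbs = rng.choice(names, size=size, replace=False)
        out.append(Prescription(id=f"p{i}", herbs=tuple(herbs)))
    return out


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale synthetic dataset shared across tests."""
    return generate_dataset(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def default_corpus(default_dataset):
    return normalize_corpus(
        default_dataset.raw_corpus, default_dataset.lexicon
    )


SMALL_GENERATOR = dict(
    n_prescriptions=120,
    n_herbs=60,
    n_chem_herbs=26,
    compounds_per_herb=6,
    ppi_nodes=300,
    n_disease_genes=40,
    n_terms=40,
    term_size_range=(10, 60),
    n_planted_terms=4,
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(GeneratorConfig(seed=7, **SMALL_GENERATOR))
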