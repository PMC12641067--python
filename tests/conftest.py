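import numpy as np
import pytest

from gcdcas_pk.population import default_population
from gcdcas_pk.trial_sim import builtin_designs


@pytest.fixture(scope="session")
def pop():
    return default_population()


@pytest.fixture(scope="session")
def designs():
    return builtin_designs()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def study3_dataset(tmp_path_factory):
    """One synthetic probenecid cross-over dataset (study #3 design)."""
    from gcdcas_pk.synthetic import GenerationSpec, generate_study

    out = tmp_path_factory.mktemp("study3")
    paths = generate_study(GenerationSpec(design="study3", seed=7), out)
    return paths


@pytest.fixture(scope="session")
def three_study_datasets(tmp_path_factory):
    """Synthetic replicates of all three designs under the final model."""
    from gcdcas_pk.datasets import read_dataset
    from gcdcas_pk.synthetic import GenerationSpec, generate_study

    out = tmp_path_factory.mktemp("ensemble")
    dfs = {}
    for design in ("study1", "study2", "study3"):
        paths = generate_study(GenerationSpec(design=design, seed=42), out / design)
        dfs[design] = read_dataset(paths["dataset"])
    return dfs
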