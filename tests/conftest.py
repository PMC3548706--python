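import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cuprofile import PlantModel, generate_dataset
from cuprofile.orthology import call_orthologs
from cuprofile.profiles import Taxonomy, aggregate_by_genus

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic study shared by integration-level tests."""
    model = PlantModel(
        n_genera=6, genomes_per_genus=(2, 3), decoys_per_genome=8, seed=7
    )
    return generate_dataset(model)


@pytest.fixture(scope="session")
def small_calls(small_dataset):
    return call_orthologs(small_dataset.seeds, small_dataset.proteomes)


@pytest.fixture()
def toy_profile():
    """Tiny genus profile with two crisp column blocks and two row groups."""
    fractions = pd.DataFrame(
        {
            "P1": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
            "P2": [1.0, 0.75, 1.0, 0.0, 0.25, 0.0],
            "P3": [0.0, 0.0, 0.25, 1.0, 1.0, 1.0],
            "P4": [0.0, 0.25, 0.0, 1.0, 0.75, 1.0],
        },
        index=[f"G{i}" for i in range(1, 7)],
    )
    intervals = fractions.map(
        lambda f: 0 if f == 0 else 10 if f == 1 else int(min(9, max(1, round(f * 10))))
    ).astype(int)
    sizes = pd.Series([4] * 6, index=fractions.index)
    from cuprofile.profiles import GenusProfile

    return GenusProfile(fractions=fractions, intervals=intervals, genus_sizes=sizes)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
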