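"""Shared fixtures: synthetic datasets and small model configurations.

Everything is generated programmatically and seeded; session scope keeps the
RDKit standardization work (the slow part) to one pass.
"""

import numpy as np
import pytest

from ggapcpi.curation import resolve_conflicts
from ggapcpi.model import GGAPModel, ModelConfig
from ggapcpi.synthgen import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def synth():
    """The default synthetic study: planted cliffs, conflicts, mixed types."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def curated(synth):
    """Conflict-resolved records of the default synthetic study."""
    records, report = resolve_conflicts(synth.records)
    return records, report


@pytest.fixture(scope="session")
def train_fixture():
    """A small, smooth (cliff/conflict-free) dataset for optimisation tests."""
    spec = SyntheticSpec(
        n_series=4,
        series_size=4,
        n_proteins=2,
        cliff_rate=0.0,
        conflict_rate=0.0,
        protein_length_range=(50, 60),
        seed=5,
    )
    return generate_dataset(spec)


@pytest.fixture()
def tiny_config():
    """A narrow architecture for fast forward/backward tests."""
    return ModelConfig(hidden_dim=20, no_esm=True, dropout=0.0, seed=0)


@pytest.fixture()
def tiny_model(tiny_config):
    return GGAPModel(tiny_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
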