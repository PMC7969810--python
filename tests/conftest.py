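import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from pharmscreen import PharmacophoreModel, SphereConstraint
from pharmscreen.synthetic import (SimSpec, default_planted_model,
                                   generate_activities,
                                   generate_feature_molecules)


def load_table(name: str) -> pd.DataFrame:
    from importlib.resources import files
    import io
    return pd.read_csv(io.StringIO(
        files("pharmscreen.data").joinpath(name).read_text()))


@pytest.fixture(scope="session")
def training_table() -> pd.DataFrame:
    """The 21-compound training activity table (printed inputs)."""
    return load_table("training_set.csv")


@pytest.fixture(scope="session")
def test_table() -> pd.DataFrame:
    """The 38-compound test activity table (printed inputs)."""
    return load_table("test_set.csv")


@pytest.fixture(scope="session")
def planted_model() -> PharmacophoreModel:
    return default_planted_model()


@pytest.fixture(scope="session")
def mixed_model() -> PharmacophoreModel:
    """A 4-constraint mixed-kind model used for recovery tests."""
    return PharmacophoreModel("mixed", [
        SphereConstraint("HBA", (0.0, 0.0, 0.0)),
        SphereConstraint("HY", (5.0, 0.0, 0.0)),
        SphereConstraint("HY", (2.5, 4.3, 0.0)),
        SphereConstraint("AR", (2.5, 1.4, 3.5)),
    ])


@pytest.fixture(scope="session")
def planted_training(mixed_model):
    """12 synthetic actives with activities from the planted law (seed 7)."""
    spec = SimSpec(model=mixed_model, n_actives=12, n_decoys=0, seed=7,
                   noise_sigma_log10=0.1)
    actives, _ = generate_feature_molecules(spec)
    generate_activities(actives, mixed_model, true_C=8.33,
                        noise_sigma_log10=0.1, seed=7)
    return actives
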