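import numpy as np
import pandas as pd
import pytest

from akoselect import SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_table(tmp_path):
    """3 samples x 2 metabolites CSV with one blank cell."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "sample_id,class,met_A,met_B\n"
        "s1,CD,1.5,2.0\n"
        "s2,UC,,3.0\n"
        "s3,nonIBD,2.5,4.0\n"
    )
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 2-class dataset with strong signals, shared across tests."""
    config = SimulationConfig(
        n_samples=80,
        n_metabolites=20,
        n_classes=2,
        n_signal=5,
        effect_size=2.0,
        correlation="independent",
        missing_rate=0.02,
        missing_mechanism="mcar",
        intensity_scale="gaussian",
        seed=11,
    )
    return generate_dataset(config)
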