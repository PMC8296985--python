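import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from covscreen.fp_binding import FPAssayConfig
from covscreen.synthetic import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fp_config() -> FPAssayConfig:
    """Standard assay totals: 100 nM protein, 10 nM probe, probe KD 6 nM."""
    return FPAssayConfig(protein_total=100e-9, probe_total=10e-9, kd_probe=6e-9)


@pytest.fixture
def noiseless() -> SimulationConfig:
    return SimulationConfig(seed=0, cv=0.0, additive_frac=0.0, replicates=1)


@pytest.fixture
def viability_plate() -> pd.DataFrame:
    """Tiny hand-built plate: vehicle mean 10000, kill mean 2000."""
    rows = [
        ("A1", "DMSO", 0.0, "vehicle", 10_100.0, 1),
        ("A2", "DMSO", 0.0, "vehicle", 9_900.0, 1),
        ("A3", "benzethonium", 0.0, "kill_control", 2_000.0, 1),
        ("A4", "cmpd", 1e-6, "treatment", 6_000.0, 1),
        ("A5", "cmpd", 1e-5, "treatment", 4_000.0, 1),
    ]
    return pd.DataFrame(rows, columns=["well", "compound", "conc", "role", "signal", "replicate"])


def rel_err(a, b):
    return np.abs(np.asarray(a) - np.asarray(b)) / np.abs(np.asarray(b))
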