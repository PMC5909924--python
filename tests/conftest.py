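import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from survnn import SimulationConfig, SurvivalDataset, simulate_dataset


@pytest.fixture
def toy_ds() -> SurvivalDataset:
    """Eight patients, three genes, mixed events/censoring, one tie."""
    rng = np.random.default_rng(42)
    return SurvivalDataset(
        X=rng.normal(0, 1, size=(8, 3)),
        time=np.array([2.0, 5.0, 5.0, 1.0, 8.0, 3.0, 6.0, 4.0]),
        event=np.array([1, 1, 0, 1, 0, 1, 1, 0]),
        feature_names=["gA", "gB", "gC"],
        patient_ids=[f"p{i}" for i in range(8)],
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated cohort with known truth (2 groups x 60, 40 genes)."""
    cfg = SimulationConfig(
        n_groups=2, patients_per_group=60, n_genes=40, n_signal_genes=15, seed=123
    )
    ds, truth = simulate_dataset(cfg)
    return ds, truth


def random_survival(rng, n, censor_scale=10.0, event_scale=5.0):
    """Generic censored survival draw for metric tests (tie-free)."""
    T = rng.exponential(event_scale, n)
    C = rng.exponential(censor_scale, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return time, event
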