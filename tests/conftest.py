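import numpy as np
import pytest

from survfuse import ModalityMatrix, SimConfig, simulate_cohort


def tiny_sim_config(seed: int = 7, **overrides) -> SimConfig:
    """Small, fast cohort used across unit tests."""
    kwargs = dict(
        n_patients=120,
        n_features={"cln": 8, "cnv": 40, "dna": 40, "mir": 20, "mrna": 40},
        wsi_patches=6,
        wsi_dim=16,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_sim_config())


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, modality="mrna", domain="continuous", patient_ids=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if patient_ids is None:
        patient_ids = [f"P{i:03d}" for i in range(n)]
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    return ModalityMatrix(modality, patient_ids, feature_ids, values, domain)
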