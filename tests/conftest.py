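import numpy as np
import pytest

from sectorvit.network import ModelConfig
from sectorvit.simulate import SimConfig, generate_cohort
from sectorvit.cohort import SECTOR_ORDER


def flat_effects(**overrides) -> dict:
    eff = {s: 0.0 for s in SECTOR_ORDER}
    eff.update(overrides)
    return eff


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six patients, ~2 slices each, full 105-feature radiomics."""
    cfg = SimConfig(n_patients=6, images_per_patient_mean=2.0,
                    images_per_patient_sd=0.5, class_prevalence=0.5, seed=7)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(embed_dim=16, depth=1, n_heads=2, patch_size=32,
                       dropout=0.0, radiomic_length=105, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
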