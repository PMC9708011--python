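import numpy as np
import pytest

from cinempca.synthetic import SyntheticConfig, generate_cohort
from cinempca.preprocess import fit_reference, preprocess_study, landmark_matrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Single-view planted-signal cohort shared across test modules."""
    cfg = SyntheticConfig(n_subjects=80, image_size=32, views=("SA",), seed=42)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def preprocessed_cohort(small_cohort):
    cfg, studies = small_cohort
    ref = fit_reference([landmark_matrix(s.landmarks, "SA") for s in studies], "SA")
    tensors = np.stack([preprocess_study(s, ref, 32).tensor for s in studies])
    labels = np.array([s.event and s.survival_time <= 1.0 for s in studies])
    return cfg, studies, ref, tensors, labels
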