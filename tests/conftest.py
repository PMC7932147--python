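import pytest

from posthypoxia.preprocess import average_duplicates, chex_normalize
from posthypoxia.simulate import SimConfig, synthetic_reference_tables


@pytest.fixture(scope="session")
def reference_tables():
    """Deterministic synthetic stand-in plates (plasma + retina)."""
    return synthetic_reference_tables()


@pytest.fixture(scope="session")
def reference_matrices(reference_tables):
    return {
        tissue: chex_normalize(average_duplicates(plate))
        for tissue, plate in reference_tables.items()
    }


@pytest.fixture
def noisefree_config():
    """All noise sources off: downstream estimators must be exact."""
    return SimConfig(
        noise_cv=0.0,
        well_scale_sd=0.0,
        duplicate_cv=0.0,
        oct_noise_sd=0.0,
        hist_cv=0.0,
        seed=7,
    )
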