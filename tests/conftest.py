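import numpy as np
import pytest

from ndwti.io import SampleRecord
from ndwti.pipeline import build_feature_table
from ndwti.synth import SceneConfig, paired_stage_dataset


def records_from_samples(samples):
    """Adapt synthetic samples to the extraction-layer record type."""
    return [
        SampleRecord(
            plot_id=s.plot_id,
            stage=s.stage,
            agb=s.agb,
            reflectance_means={b: float(p.mean()) for b, p in s.patches.items()},
            patches=s.patches,
        )
        for s in samples
    ]


@pytest.fixture(scope="session")
def small_samples():
    """A compact two-stage draw used by several integration tests."""
    return paired_stage_dataset(n_pre=60, n_post=40, seed=7, patch_size=16)


@pytest.fixture(scope="session")
def small_feature_table(small_samples):
    return build_feature_table(records_from_samples(small_samples))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def deterministic_config():
    """Noise-free, jitter-free pre-heading generator for exact expectations."""
    return SceneConfig(
        stage="pre_heading",
        patch_size=16,
        noise_sd=0.0,
        illumination_sd=0.0,
        cover_jitter_sd=0.0,
        seed=0,
    )
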