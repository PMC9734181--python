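import numpy as np
import pytest

from pipshift import sim_xray as sx
from pipshift.io_cli import PipelineConfig, _preprocess_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2 hospitals x 2 classes x 50 images at 64x64 — shared across tests."""
    cfg = sx.GenerationConfig(hospitals=sx.default_hospitals(), n_per_class=50,
                              grid=(64, 64), seed=42,
                              noise=sx.NoiseModel(gaussian_sd=1.5))
    return sx.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_processed(small_dataset):
    """Preprocessed stack + kept indices + stats for the small dataset."""
    cfg = PipelineConfig(seed=42)
    kept, images, stats = _preprocess_dataset(small_dataset, cfg)
    return kept, images, stats


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
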