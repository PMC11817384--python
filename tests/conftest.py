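import numpy as np
import pytest

from laverspec.synthetic import GeneratorConfig, QualityRecord, wavelength_axis


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def axis():
    return wavelength_axis()


@pytest.fixture
def record():
    return QualityRecord(sample_id="S000", moisture=9.0, protein=38.0, cutting_stress=0.5)


@pytest.fixture
def small_config():
    """A cube just big enough for the ROI; keeps per-test runtime low."""
    return GeneratorConfig(n_samples=6, lines=52, samples_px=304, seed=7)
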