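import numpy as np
import pytest

from ramansen import prep, synthgen
from ramansen.dataset import Spectrum


@pytest.fixture(scope="session")
def sim_dataset():
    """Small default-template dataset shared across tests (30 per class)."""
    cfg = synthgen.SimulationConfig(n_per_class=30, seed=11)
    return synthgen.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def pre_dataset(sim_dataset):
    """Preprocessed (cosmic-removed, baseline-subtracted) version."""
    return sim_dataset.map_transform(lambda s: prep.preprocess(s))


@pytest.fixture(scope="session")
def templates():
    return synthgen.default_templates()


@pytest.fixture()
def flat_spectrum():
    w = np.arange(690.0, 1656.0)
    return Spectrum(w, np.full(w.size, 5.0), {"sample_id": "flat", "map_id": "", "class_label": ""})


def make_noiseless_template(label="HOL", peaks=None, baseline=(0.0,)):
    """Single-template deterministic config helper for closed-form tests."""
    peaks = peaks or [(1003.0, 1.0, 12.0, 1.0), (1525.0, 0.5, 12.0, 1.0)]
    return synthgen.ClassTemplate(
        class_label=label,
        peaks=peaks,
        fluorescence_scale=(1000.0, 0.0),
        baseline_coeffs=baseline,
        noise_sd=0.0,
        spike_rate=0.0,
    )
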