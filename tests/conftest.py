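import numpy as np
import pytest

from hemowave import detect_r_peaks, ensemble_average
from hemowave.synthetic_data import SyntheticConfig, generate_recording

#: noise/jitter-free single-tube settings whose half-sine ejection (0.12 s)
#: keeps all 1-10 Hz flow harmonics away from spectral nulls — the standard
#: configuration for ground-truth recovery checks
CLEAN_TUBE = dict(
    rr_jitter_sd_s=0.0,
    noise_sd_pressure_mmhg=0.0,
    noise_sd_flow_ml_s=0.0,
    ejection_fraction_of_cycle=0.24,
    round_trip_delay_s=0.05,
)


def clean_config(**overrides) -> SyntheticConfig:
    params = dict(CLEAN_TUBE)
    params.update(overrides)
    return SyntheticConfig(**params)


def analyze_tube(config: SyntheticConfig):
    """(record, truth, segmentation, ensemble beat) for a generated tube."""
    record, truth = generate_recording(config)
    segmentation = detect_r_peaks(record.channels["ecg"], record.fs_hz)
    beat = ensemble_average(record, segmentation)
    return record, truth, segmentation, beat


@pytest.fixture(scope="session")
def reflecting_tube():
    """Noise-free tube with gamma=0.4 plus its analysis products."""
    return analyze_tube(clean_config(gamma=0.4))


@pytest.fixture(scope="session")
def no_reflection_tube():
    """Noise-free tube with gamma=0 plus its analysis products."""
    return analyze_tube(clean_config(gamma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
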