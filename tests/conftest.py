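import numpy as np
import pytest

from szdetect.cli_io import PipelineConfig, run_detection
from szdetect.synthetic_data import SimConfig, generate_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_free_run():
    """Noise-free 20-cell recording plus its full detection result."""
    cfg = SimConfig(n_cells=20, duration=300.0, noise_sd=0.0, pis_rate=2.0, rng_seed=1)
    rec, eeg, truth = generate_recording(cfg)
    result = run_detection(rec, eeg, PipelineConfig())
    return cfg, rec, eeg, truth, result


@pytest.fixture(scope="session")
def noisy_run():
    """Moderate-noise 30-cell recording plus its detection result."""
    cfg = SimConfig(
        n_cells=30,
        duration=400.0,
        seizure_onset=300.0,
        terminal_onset=355.0,
        noise_sd=0.15,
        rng_seed=7,
    )
    rec, eeg, truth = generate_recording(cfg)
    result = run_detection(rec, eeg, PipelineConfig())
    return cfg, rec, eeg, truth, result
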