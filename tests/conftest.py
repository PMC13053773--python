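import numpy as np
import pytest

from runcna.synthetic import gen_emg, gen_vgrf, run_spec_for_speed

BODY_MASS = 72.0


@pytest.fixture(scope="session")
def clean_run():
    """Noise-free 12 km/h run: (spec, force trace, ground truth)."""
    spec = run_spec_for_speed(12.0, n_strides=15, noise_sd=0.0, seed=7)
    trace, gt = gen_vgrf(spec, BODY_MASS)
    return spec, trace, gt


@pytest.fixture(scope="session")
def clean_run_with_emg(clean_run):
    """Noise-free run plus its eight-muscle EMG and filled-in iEMG truth."""
    spec, trace, gt = clean_run
    traces, gt = gen_emg(spec, gt)
    return spec, trace, traces, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
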