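"""Shared fixtures: small synthetic trains and recordings built at test time."""
import numpy as np
import pytest

import fpwatch as fw


@pytest.fixture(scope="session")
def grid_geometry():
    return fw.ArrayGeometry.grid()


@pytest.fixture(scope="session")
def linear_geometry():
    return fw.ArrayGeometry.linear()


@pytest.fixture(scope="session")
def gamma_truth():
    """A moderately busy gamma-renewal train (30/min, 120 s, shape 3.5)."""
    spec = fw.RenewalSpec("gamma", 30.0, shape=3.5, seed=11)
    return fw.generate_event_train(spec, 120.0)


@pytest.fixture(scope="session")
def snr10_recording(gamma_truth, grid_geometry):
    """Standard benchmark recording: SNR 10 (peak 100 uV / noise 10 uV) on the grid."""
    return fw.synthesize_recording(gamma_truth, grid_geometry,
                                   noise_rms_uv=10.0, seed=12, name="bench")


@pytest.fixture(scope="session")
def clean_recording(grid_geometry):
    """Noise-free, jitter-free 50-event recording for exact detection checks."""
    spec = fw.RenewalSpec("gamma", 30.0, shape=3.5, seed=21)
    truth = fw.generate_event_train(spec, 110.0)
    assert truth.n_events >= 50
    truth = fw.GroundTruth(event_times=truth.event_times[:50],
                           source_ids=truth.source_ids[:50],
                           duration_s=110.0)
    wf = fw.FPWaveformModel(jitter_sd_ms=0.0)
    rec = fw.synthesize_recording(truth, grid_geometry, wf, noise_rms_uv=0.0,
                                  seed=22, name="clean50")
    return truth, rec


def random_train(rng: np.random.Generator, max_n: int = 40,
                 duration_s: float = 100.0) -> fw.EventTrain:
    """Helper used by oracle tests: a random strictly-increasing train."""
    n = int(rng.integers(0, max_n + 1))
    times = np.sort(rng.uniform(0, duration_s, n))
    times = np.unique(times)
    return fw.EventTrain(muscle_id="rand", times=times,
                         recording_duration_s=duration_s)
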