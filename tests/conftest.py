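import numpy as np
import pytest

from optomap import OpsinModel, SceneConfig, simulate_mapping_experiment


@pytest.fixture(scope="session")
def targeted_model():
    return OpsinModel.targeted()


@pytest.fixture(scope="session")
def nontargeted_model():
    return OpsinModel.nontargeted()


@pytest.fixture(scope="session")
def small_bundle():
    """One fully simulated targeted-mode experiment (40 cells, fixed seed)."""
    return simulate_mapping_experiment(SceneConfig(n_cells=40, seed=3))


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free experiment: no spontaneous events, no recording or imaging
    noise, full indicator coverage — every event is traceable to truth."""
    cfg = SceneConfig(n_cells=30, seed=11, noise_sd_imaging=0.0,
                      noise_sd_ephys=0.0, spontaneous_epsc_rate=0.0,
                      p_indicator=1.0, p_high_baseline=0.0)
    return simulate_mapping_experiment(cfg)


def epsc_template(n=5000, t_event_ms=150.0, amp=50.0, sample_rate=10_000.0,
                  rise_tau=1.0, decay_tau=5.0):
    """Analytic EPSC sweep used as a detection ground truth."""
    t = np.arange(n) / sample_rate * 1000.0
    dt = t - t_event_ms
    k = np.where(dt >= 0, np.exp(-np.maximum(dt, 0) / decay_tau)
                 - np.exp(-np.maximum(dt, 0) / rise_tau), 0.0)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return -amp * k / peak
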