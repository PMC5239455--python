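import numpy as np
import pytest

from herfret.synthetic import DecaySimConfig


@pytest.fixture
def small_decay_config():
    """Small, fast acquisition used across FLIM tests."""
    return DecaySimConfig(image_shape=(32, 32), photons_per_pixel=5000.0, seed=0)


def truncated_exp_binned_mean(tau: float, n_bins: int, time_window: float) -> float:
    """Independent oracle: mean arrival time (bin-center weighted) of the
    window-truncated exponential, computed directly from the density."""
    dt = time_window / n_bins
    edges = np.linspace(0.0, time_window, n_bins + 1)
    probs = (np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)) / (1.0 - np.exp(-time_window / tau))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(np.sum(probs * centers))
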