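import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from erppipe.core_io import EventMarker, Recording
from erppipe.sim_vep import SimSettings, hemisphere_montage, pink_noise


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim250():
    """Simulated-train settings on the benchmark grid."""
    return SimSettings(rate=250.0)


@pytest.fixture
def montage32():
    return hemisphere_montage(32)


@pytest.fixture
def make_recording(rng):
    """Factory for small synthetic recordings."""

    def _make(n_channels=4, n_samples=1000, rate=250.0, events=(),
              montage=None, data=None, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        if data is None:
            data = pink_noise(n_samples, local, (n_channels,))
        labels = (list(montage.keys())[:n_channels] if montage
                  else [f"ch{i}" for i in range(n_channels)])
        return Recording(
            data=np.asarray(data, dtype=float),
            rate=rate,
            labels=labels,
            montage=montage or {},
            events=[EventMarker(*e) for e in events],
        )

    return _make
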