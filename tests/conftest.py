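import numpy as np
import pytest

from synchnet.config import CouplingSpec, SimulationConfig
from synchnet.epochs import EpochSet
from synchnet.network import WeightedGraph, threshold_graph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_epochs(
    data: np.ndarray,
    sfreq: float = 1000.0,
    t0_ms: float = -200.0,
    conditions=None,
    channels=None,
    subject: str = "S01",
    group=None,
) -> EpochSet:
    """Wrap a raw (epochs, channels, samples) array in an EpochSet."""
    n_e, n_c, n_s = data.shape
    times = t0_ms + 1000.0 / sfreq * np.arange(n_s)
    if conditions is None:
        conditions = np.array(["Go"] * n_e, dtype=object)
    if channels is None:
        channels = [f"CH{i + 1}" for i in range(n_c)]
    return EpochSet(
        data=data,
        times=times,
        sfreq=sfreq,
        channels=channels,
        conditions=np.asarray(conditions, dtype=object),
        subject=subject,
        group=group,
    )


def random_weighted_graph(rng: np.random.Generator, n: int, k: int) -> WeightedGraph:
    """Random symmetric matrix thresholded to exactly k edges."""
    m = rng.uniform(0.05, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return threshold_graph(m, k)


@pytest.fixture
def coupled_pair_config():
    """Two channels, one band, full coupling, no noise."""
    return SimulationConfig(
        n_channels=2,
        channel_labels=("A", "B"),
        n_epochs_per_condition=3,
        conditions=("Go",),
        bands=(("theta", 4.0, 8.0),),
        band_amplitudes={"theta": 10.0},
        coupling_specs=(CouplingSpec("Go", "theta", ("A", "B"), 1.0),),
        noise_sd=0.0,
        phase_jitter_sd=0.05,
        seed=7,
    )
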