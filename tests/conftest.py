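import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from ionvox import synth
from ionvox.io import ChannelStack, MultiplexVolume


@pytest.fixture(scope="session")
def small_phantom():
    """Five-structure 10x80x80 phantom shared across tests (read-only)."""
    config = synth.nuclear_phantom_config(dims=(10, 80, 80), seed=1)
    volume, truth = synth.generate_nuclear_phantom(config)
    return config, volume, truth


@pytest.fixture()
def tiny_volume():
    """Deterministic 2-channel 4x6x5 volume with small integer counts."""
    rng = np.random.default_rng(7)
    return MultiplexVolume(
        [
            ChannelStack("19F", "nucleolin", rng.integers(0, 9, (4, 6, 5))),
            ChannelStack("31P", "DNA", rng.integers(0, 9, (4, 6, 5))),
        ],
        fov_id="tiny",
    )
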