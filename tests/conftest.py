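import numpy as np
import pytest

from mzclust.data_model import IonImageStack


@pytest.fixture
def small_stack():
    """Deterministic 6-image 8x8 stack with hand-set intensities."""
    rng = np.random.default_rng(42)
    images = rng.random((6, 8, 8)).astype(np.float32)
    mz = np.array([100.0, 101.003, 150.0, 151.004, 200.0, 203.0])
    return IonImageStack(mz=mz, images=images)


@pytest.fixture
def tiny_labeled_sim():
    """Small simulated dataset (7 clusters x 8 images) at mild noise."""
    from mzclust.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(
        images_per_cluster=8, noise_sd=0.3, amplitude_jitter=0.3,
        hotspot_fraction=0.0, seed=7))
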