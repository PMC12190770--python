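import numpy as np
import pytest

from optoquant import ChannelVolume, EmbryoTruth


@pytest.fixture
def small_truth():
    """Desk-scale noiseless embryo with uniform reporter expression."""
    return EmbryoTruth(
        seed=7,
        shape=(16, 48, 48),
        n_nuclei=40,
        noise_sd=0.0,
        gfp_field=1000.0,
        effector_gain=2.0,
        baseline_effector=0.0,
    )


@pytest.fixture
def mosaic_truth():
    """Noiseless embryo with mosaic reporter patches (default field)."""
    return EmbryoTruth(seed=11, shape=(16, 48, 48), n_nuclei=40, noise_sd=0.0)


def random_volume(rng, shape=(5, 5, 5), channels=("DAPI", "GFP", "EFFECTOR"), high=1000):
    vox = rng.integers(0, high, size=(len(channels),) + shape).astype(np.uint16)
    return ChannelVolume(voxels=vox, channel_names=channels)
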