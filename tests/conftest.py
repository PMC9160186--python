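import numpy as np
import pytest

from earssvep.synth import ChannelProfile, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """Three subjects, two blocks: enough structure for harness plumbing."""
    return SimConfig(n_subjects=3, n_blocks=2, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Noise-free channels: spectrograms reduce to exact harmonic peaks."""
    profiles = {
        name: ChannelProfile(
            name=name, harmonic_amplitudes=(1.0, 0.5, 1 / 3), noise_sd=0.0
        )
        for name in ("Oz", "P7", "P8", "PO7", "PO8", "TP7", "TP8", "T7", "T8")
    }
    return SimConfig(n_subjects=4, n_blocks=2, seed=3, channel_profiles=profiles)


def make_peak_images(
    n: int, width: int, rng: np.random.Generator, noise: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic spectrogram-like images with one peak row per class.

    Class k peaks at row (8, 11, 14)[k] - 1; optionally adds uniform noise.
    Linearly separable by construction, with a trivial peak-row oracle.
    """
    images = np.zeros((n, 125, width), dtype=np.float32)
    labels = rng.integers(0, 3, size=n)
    rows = np.array([7, 10, 13])
    for i, lab in enumerate(labels):
        if noise:
            images[i] = noise * rng.random((125, width))
        images[i, rows[lab], :] = 1.0
    return images, labels
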