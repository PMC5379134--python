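import numpy as np
import pytest

import madetect as md


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Config sized for fast unit tests (working resolution kept small)."""
    return md.PipelineConfig(working_resolution=256,
                             atoms_per_subdictionary=32,
                             ksvd_iterations=5, rng_seed=7)


@pytest.fixture(scope="session")
def small_scene():
    """A compact synthetic scene reused across read-only tests."""
    params = md.SimulationParams(image_size=256, n_ma=5,
                                 n_bright_distractors=1,
                                 n_large_distractors=1, seed=21)
    return md.generate_scene(params)


def make_disk_image(size=128, radius=40, fg=0.6, bg=0.02):
    """Bright disk on a dark surround: a minimal field-of-view phantom."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = size / 2
    disk = np.hypot(yy - c, xx - c) <= radius
    vals = np.where(disk, fg, bg)
    return md.GrayImage(values=vals), disk


def implant_gaussian(values, center, sigma, contrast):
    """Subtract a dark Gaussian blob in place; returns the modified array."""
    size = values.shape[0]
    r, c = center
    half = int(np.ceil(4 * sigma))
    r0, r1 = max(0, r - half), min(size, r + half + 1)
    c0, c1 = max(0, c - half), min(size, c + half + 1)
    yy, xx = np.mgrid[r0 - r:r1 - r, c0 - c:c1 - c].astype(float)
    values[r0:r1, c0:c1] -= contrast * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    return values
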