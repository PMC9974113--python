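import numpy as np
import pytest

from lungrepair import carve_notches, make_lung_truth


def disk_mask(shape: tuple[int, int], center: tuple[int, int], radius: float) -> np.ndarray:
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return (((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius**2).astype(np.uint8)


def notched_disk(shape=(101, 101), center=(50, 50), radius=30, notch=(20, 50), notch_r=8):
    """A disk with a disk-shaped bite taken out of its boundary."""
    m = disk_mask(shape, center, radius)
    m[disk_mask(shape, notch, notch_r) == 1] = 0
    return m


@pytest.fixture(scope="session")
def lung_case():
    """One deterministic 2-notch lung fixture shared across tests."""
    truth = make_lung_truth(512, 512, seed=11)
    return carve_notches(truth, 2, (8.0, 15.0), seed=12)


@pytest.fixture(scope="session")
def small_lung_case():
    """A 256x256 single-notch case for fast end-to-end tests."""
    truth = make_lung_truth(256, 256, seed=5)
    return carve_notches(truth, 1, (9.0, 11.0), seed=6)
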