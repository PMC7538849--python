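import numpy as np
import pytest

from lucency import SimConfig, TumorVolume, generate_cohort


def block_volume(size=7, hole=None, spacing=1.0):
    """A square solid slice with an optional centered square hole."""
    a = np.ones((size, size), dtype=bool)
    if hole:
        lo = (size - hole) // 2
        a[lo : lo + hole, lo : lo + hole] = False
    return TumorVolume.from_arrays([a], spacing=spacing)


def random_blob_mask(rng, size=32):
    """Random multi-ellipse solid image, possibly with carved lucencies."""
    yy, xx = np.mgrid[0:size, 0:size]
    a = np.zeros((size, size), dtype=bool)
    for _ in range(rng.integers(2, 5)):
        cy, cx = rng.uniform(6, size - 6, 2)
        ry, rx = rng.uniform(3, 8, 2)
        a |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1
    for _ in range(rng.integers(0, 4)):
        cy, cx = rng.uniform(8, size - 8, 2)
        ry, rx = rng.uniform(1, 3, 2)
        a &= ~(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1)
    if not a.any():
        a[size // 2, size // 2] = True
    return a


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject synthetic study shared by pipeline-level tests."""
    return generate_cohort(SimConfig(n_subjects=40), seed=20260930)
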