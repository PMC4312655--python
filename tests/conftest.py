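import numpy as np
import pytest
from scipy import ndimage

from glandring.core_maps import ProbabilityMapStack, normalize_stack


def random_blob(rng: np.random.Generator, size: int = 48, p: float = 0.55) -> np.ndarray:
    """A random smooth hole-free blob: thresholded noise, opened and closed,
    largest connected component, holes filled."""
    noise = ndimage.gaussian_filter(rng.random((size, size)), 4)
    mask = noise > np.quantile(noise, p)
    mask = ndimage.binary_opening(mask, np.ones((3, 3)))
    mask = ndimage.binary_closing(mask, np.ones((3, 3)))
    labels, n = ndimage.label(mask)
    if n == 0:
        mask = np.zeros((size, size), bool)
        mask[size // 2 - 2 : size // 2 + 2, size // 2 - 2 : size // 2 + 2] = True
        return mask
    areas = np.bincount(labels.ravel())[1:]
    mask = labels == (1 + int(np.argmax(areas)))
    return ndimage.binary_fill_holes(mask)


def random_stack(
    rng: np.random.Generator, shape: tuple[int, int] = (24, 24), k: int = 4
) -> ProbabilityMapStack:
    """A normalized random probability stack."""
    vals = rng.random((*shape, k))
    return normalize_stack(ProbabilityMapStack(vals))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
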