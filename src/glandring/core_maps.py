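"""Probability-map stacks and lumen region labeling.

A tissue image enters the pipeline already softly classified into K
per-pixel class posterior maps (e.g. lumen, epithelium, nuclei, stroma).
This module validates and normalizes such stacks, orders channels so the
lumen map comes first, binarizes the lumen channel, and labels lumen
regions by 4-connectivity (diagonal neighbors are NOT connected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

# 4-connectivity: diagonal pixels are not neighbors
_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ProbabilityMapStack:
    """Per-pixel class posteriors as an (H, W, K) float array.

    Parameters
    ----------
    values : ndarray, shape (H, W, K)
        Per-pixel per-class posterior probabilities in [0, 1].
    class_names : list of str, optional
        Ordered channel labels; defaults to ``class_0 .. class_{K-1}``.
    """

    values: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"stack must be (H, W, K), got shape {self.values.shape}"
            )
        if self.n_classes < 2:
            raise ValueError("stack needs at least 2 class channels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stack contains non-finite values")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-9:
            raise ValueError("posterior values must lie in [0, 1]")
        if not self.class_names:
            self.class_names = [f"class_{k}" for k in range(self.n_classes)]
        elif len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal number of channels")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return self.values.shape[2]

    def is_normalized(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.values.sum(axis=2), 1.0, atol=tol))


@dataclass
class LumenRegionSet:
    """Labeled 4-connected lumen components.

    ``label_image`` uses 0 for background and 1..M for regions.
    """

    label_image: np.ndarray
    n_regions: int
    region_areas: np.ndarray

    def region_mask(self, region_id: int) -> np.ndarray:
        if not 1 <= region_id <= self.n_regions:
            raise ValueError(f"region_id {region_id} out of range 1..{self.n_regions}")
        return self.label_image == region_id


def normalize_stack(
    stack: ProbabilityMapStack, zero_policy: str = "uniform"
) -> ProbabilityMapStack:
    """Rescale per-pixel posteriors so each pixel's class sum is 1.

    Relative class proportions are preserved. Pixels whose posteriors are
    all zero get a uniform 1/K distribution (``zero_policy="uniform"``,
    logged) or raise (``zero_policy="error"``).
    """
    vals = stack.values
    sums = vals.sum(axis=2)
    zero = sums <= 0
    if zero.any():
        if zero_policy == "error":
            raise ValueError(f"{int(zero.sum())} pixels have all-zero posteriors")
        logger.warning(
            "%d all-zero pixels assigned uniform 1/%d posterior",
            int(zero.sum()),
            stack.n_classes,
        )
    out = np.empty_like(vals)
    safe = np.where(zero, 1.0, sums)
    out[:] = vals / safe[..., None]
    out[zero] = 1.0 / stack.n_classes
    return ProbabilityMapStack(out, list(stack.class_names))


def order_maps_by_mean_intensity(
    stack: ProbabilityMapStack,
) -> tuple[ProbabilityMapStack, np.ndarray]:
    """Sort channels by decreasing mean intensity; lumen becomes channel 0.

    In glandular tissue the lumen posterior map has the highest mean
    intensity, so descending order selects lumen automatically. Ties keep
    the original channel order (stable sort). Returns the reordered stack
    and the permutation applied (new position i holds old channel perm[i]).
    """
    means = stack.values.mean(axis=(0, 1))
    perm = np.argsort(-means, kind="stable")
    out = ProbabilityMapStack(
        stack.values[:, :, perm], [stack.class_names[i] for i in perm]
    )
    return out, perm


def binarize_lumen(
    stack: ProbabilityMapStack,
    mode: str = "argmax",
    threshold: float = 0.1,
    lumen_channel: int = 0,
) -> np.ndarray:
    """Binary lumen mask from the lumen posterior channel.

    ``argmax`` mode (default): a pixel is lumen iff the lumen posterior is
    maximal among classes (ties resolved in favor of lumen). ``threshold``
    mode: lumen posterior >= threshold.
    """
    lum = stack.values[:, :, lumen_channel]
    if mode == "argmax":
        return lum >= stack.values.max(axis=2)
    if mode == "threshold":
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {threshold}")
        return lum >= threshold
    raise ValueError(f"unknown mode {mode!r}; use 'argmax' or 'threshold'")


def label_lumen_regions(mask: np.ndarray, min_area: int = 1) -> LumenRegionSet:
    """Label 4-connected components of a binary lumen mask.

    Components smaller than ``min_area`` pixels are dropped and the
    remaining labels compacted to 1..M. An empty mask yields M = 0.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT_4)
    if n == 0:
        return LumenRegionSet(labels, 0, np.zeros(0, dtype=np.int64))
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    labels = remap[labels]
    return LumenRegionSet(labels, int(keep.size), areas[keep - 1].astype(np.int64))
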