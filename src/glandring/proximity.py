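"""Shape-preserving ring sampling around lumen regions.

Each lumen region is dilated by a 3x3 square structuring element in
sequential unit steps; the set difference of successive dilations yields
concentric annuli that follow the lumen's shape. Per-annulus class
proportions (posterior mass over ring area) are stacked class-major into
a single R*K profile vector — the proximity feature of one lumen region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from glandring.core_maps import (
    ProbabilityMapStack,
    binarize_lumen,
    label_lumen_regions,
    normalize_stack,
    order_maps_by_mean_intensity,
)

logger = logging.getLogger(__name__)


@dataclass
class RingSet:
    """Ordered disjoint annuli grown from one lumen region.

    ``rings[r]`` is the binary mask of the (r+1)-th annulus; outward rings
    are (r+1)-fold dilation minus r-fold dilation of the region, clipped to
    the image. Inward rings are successive erosion shells of the region.
    """

    region_id: int
    rings: list[np.ndarray]
    se_size: int
    direction: str

    @property
    def R(self) -> int:
        return len(self.rings)

    @property
    def ring_areas(self) -> np.ndarray:
        return np.array([int(r.sum()) for r in self.rings], dtype=np.int64)


@dataclass
class ProximityFeature:
    """Stacked R*K class-proportion profile of one lumen region.

    Layout is class-major: the first R entries are the lumen fractions in
    rings 1..R, the next R the second class's fractions, and so on.
    """

    region_id: int
    vector: np.ndarray
    n_rings: int
    n_classes: int
    empty_rings: list[int] = field(default_factory=list)

    def profile(self) -> np.ndarray:
        """Return the (R, K) ring-by-class proportion matrix."""
        return self.vector.reshape(self.n_classes, self.n_rings).T


@dataclass
class ExtractConfig:
    """Parameters of the feature extraction pipeline for one image."""

    n_rings: int = 10
    se_size: int = 3
    direction: str = "outward"
    binarize_mode: str = "argmax"
    threshold: float = 0.1
    min_area: int = 1
    order_channels: bool = True
    lumen_channel: int = 0


def _square(se_size: int) -> np.ndarray:
    if se_size < 1 or se_size % 2 == 0:
        raise ValueError(f"se_size must be odd and >= 1, got {se_size}")
    return np.ones((se_size, se_size), dtype=bool)


def make_rings(
    region: np.ndarray,
    R: int,
    se_size: int = 3,
    direction: str = "outward",
) -> RingSet:
    """Grow R disjoint annuli around (or inside) a lumen region.

    Outward rings are successive dilation differences; inward rings are
    successive erosion differences (the first inward ring is the region's
    own outermost shell). ``direction="both"`` returns inward rings first,
    innermost-to-outermost order preserved within each block. Rings are
    clipped to the image; a ring may be empty once erosion exhausts the
    region (the all-empty tail is kept so dimensionality stays R).
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region mask is empty")
    if R < 0:
        raise ValueError("R must be >= 0")
    se = _square(se_size)

    def outward(n: int) -> list[np.ndarray]:
        rings, prev = [], region
        for _ in range(n):
            cur = ndimage.binary_dilation(prev, structure=se)
            rings.append(cur & ~prev)
            prev = cur
        return rings

    def inward(n: int) -> list[np.ndarray]:
        rings, prev = [], region
        for _ in range(n):
            cur = ndimage.binary_erosion(prev, structure=se)
            rings.append(prev & ~cur)
            prev = cur
        return rings

    if direction == "outward":
        rings = outward(R)
    elif direction == "inward":
        rings = inward(R)
    elif direction == "both":
        rings = inward(R) + outward(R)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return RingSet(region_id=0, rings=rings, se_size=se_size, direction=direction)


def ring_proportions(ring: np.ndarray, stack: ProbabilityMapStack) -> np.ndarray:
    """Per-class posterior mass fractions over one ring.

    Entry k is the sum of channel-k posteriors over ring pixels divided by
    the ring pixel count. On a normalized stack the K entries of a nonempty
    ring sum to 1. An empty ring returns the all-zero vector.
    """
    ring = np.asarray(ring, dtype=bool)
    area = int(ring.sum())
    if area == 0:
        return np.zeros(stack.n_classes)
    return stack.values[ring].sum(axis=0) / area


def proximity_feature(
    region_id: int, rings: RingSet, stack: ProbabilityMapStack
) -> ProximityFeature:
    """Stack per-ring class proportions into the R*K feature vector."""
    props = np.array([ring_proportions(r, stack) for r in rings.rings])
    if props.size == 0:
        props = props.reshape(0, stack.n_classes)
    empty = [i for i, r in enumerate(rings.rings) if not r.any()]
    # class-major: all rings of class 0, then class 1, ...
    vector = props.T.reshape(-1)
    return ProximityFeature(
        region_id=region_id,
        vector=vector,
        n_rings=rings.R,
        n_classes=stack.n_classes,
        empty_rings=empty,
    )


def extract_image_features(
    stack: ProbabilityMapStack, config: ExtractConfig | None = None
) -> list[ProximityFeature]:
    """Full per-image pipeline: normalize, order, binarize, label, sample.

    Returns one proximity feature per labeled lumen region, in label
    order. Deterministic given the stack and config.
    """
    config = config or ExtractConfig()
    if not stack.is_normalized():
        stack = normalize_stack(stack)
    if config.order_channels:
        stack, _ = order_maps_by_mean_intensity(stack)
    mask = binarize_lumen(
        stack,
        mode=config.binarize_mode,
        threshold=config.threshold,
        lumen_channel=config.lumen_channel,
    )
    regions = label_lumen_regions(mask, min_area=config.min_area)
    if regions.n_regions == 0:
        logger.warning("no lumen regions found; returning empty feature list")
        return []
    feats = []
    for rid in range(1, regions.n_regions + 1):
        rings = make_rings(
            regions.region_mask(rid),
            config.n_rings,
            se_size=config.se_size,
            direction=config.direction,
        )
        rings.region_id = rid
        feats.append(proximity_feature(rid, rings, stack))
    return feats


def features_to_frame(
    feats: list[ProximityFeature], class_names: list[str] | None = None
) -> pd.DataFrame:
    """Long-format feature table: region_id, ring, class, value."""
    rows = []
    for f in feats:
        prof = f.profile()
        for r in range(f.n_rings):
            for k in range(f.n_classes):
                name = class_names[k] if class_names else f"class_{k}"
                rows.append((f.region_id, r + 1, name, prof[r, k]))
    return pd.DataFrame(rows, columns=["region_id", "ring", "class", "value"])
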