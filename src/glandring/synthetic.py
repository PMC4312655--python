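"""Seeded synthetic glandular tissue as probability-map stacks.

Generates the two tissue classes the classifier must separate:

* ``C1`` (tubule-forming): star-convex lumen cores wrapped in concentric
  epithelium and nuclei layers, embedded in stroma — the architecture of
  a healthy/low-grade glandular unit.
* ``C0`` (tubule-absent): the same lumen geometry and near-identical
  marginal class proportions, but the annular layer assignment around
  each lumen is scrambled and displaced class material is re-deposited as
  irregular background blobs. Classes therefore differ in SPATIAL
  organization, which is exactly what ring sampling encodes; per-pixel
  class histograms alone cannot separate them.

Per-pixel posteriors are Dirichlet-noised class indicators summing to 1;
at infinite concentration (``dirichlet_concentration=None``) the maps are
crisp indicators. Channel order is fixed: lumen, epithelium, nuclei,
stroma.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any

import numpy as np
from scipy import ndimage
from skimage.draw import disk, polygon

from glandring.core_maps import ProbabilityMapStack
from glandring.mil import Bag
from glandring.proximity import ExtractConfig, extract_image_features
from glandring.core_maps import binarize_lumen, label_lumen_regions
from glandring.shape import shape_features

CLASS_NAMES = ["lumen", "epithelium", "nuclei", "stroma"]
_LUMEN, _EPI, _NUC, _STROMA = range(4)
_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class TissueSimConfig:
    """Parameters of one simulated tissue image.

    ``dirichlet_concentration`` is the weight added to the true class's
    Dirichlet parameter (the other classes keep parameter 1); ``None``
    produces crisp one-hot posteriors. ``disorder`` is the probability
    that a C0 gland's layer classes are scrambled.
    """

    image_size: int = 128
    n_glands: int = 4
    lumen_radius_range: tuple[int, int] = (5, 9)
    epithelium_thickness: int = 4
    nuclei_thickness: int = 3
    boundary_roughness: float = 0.3
    n_vertices: int = 12
    dirichlet_concentration: float | None = 30.0
    disorder: float = 1.0
    tissue_class: str = "C1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epithelium_thickness < 0 or self.nuclei_thickness < 0:
            raise ValueError("layer thicknesses must be >= 0")
        if self.dirichlet_concentration is not None and self.dirichlet_concentration <= 0:
            raise ValueError("Dirichlet concentration must be > 0 or None")
        if self.tissue_class not in ("C0", "C1"):
            raise ValueError("tissue_class must be 'C0' or 'C1'")


@dataclass
class SimulatedDataset:
    """Bags (proximity and shape-baseline), labels and a rerun manifest."""

    bags: list[Bag]
    shape_bags: list[Bag]
    labels: list[str]
    manifest: dict[str, Any] = field(default_factory=dict)


def _star_polygon(
    rng: np.random.Generator, center: tuple[int, int], r0: float, cfg: TissueSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vertices of a star-convex polygon with jittered radii."""
    angles = np.linspace(0, 2 * np.pi, cfg.n_vertices, endpoint=False)
    radii = r0 * (1 + cfg.boundary_roughness * rng.uniform(-1, 1, cfg.n_vertices))
    radii = np.maximum(radii, 2.0)
    return center[0] + radii * np.sin(angles), center[1] + radii * np.cos(angles)


def _place_glands(
    rng: np.random.Generator, cfg: TissueSimConfig
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Rasterize non-touching lumen cores; returns mask and centers."""
    size = cfg.image_size
    r_lo, r_hi = cfg.lumen_radius_range
    margin = int(r_hi * (1 + cfg.boundary_roughness)) + 2
    if 2 * margin >= size:
        raise ValueError("glands cannot fit: lumen radius too large for image")
    min_sep = 2 * r_hi * (1 + cfg.boundary_roughness) + 3
    centers: list[tuple[int, int]] = []
    mask = np.zeros((size, size), dtype=bool)
    attempts = 0
    while len(centers) < cfg.n_glands:
        attempts += 1
        if attempts > 500 * cfg.n_glands:
            raise ValueError("glands cannot fit in image (placement failed)")
        c = (rng.integers(margin, size - margin), rng.integers(margin, size - margin))
        if any(np.hypot(c[0] - p[0], c[1] - p[1]) < min_sep for p in centers):
            continue
        r0 = rng.uniform(r_lo, r_hi)
        rr, cc = polygon(*_star_polygon(rng, c, r0, cfg), shape=mask.shape)
        mask[rr, cc] = True
        centers.append(c)
    return mask, centers


def _layer_classes(rng: np.random.Generator, cfg: TissueSimConfig) -> tuple[int, int]:
    """Classes of the two annular shells around one lumen."""
    if cfg.tissue_class == "C1" or rng.random() >= cfg.disorder:
        return _EPI, _NUC
    inner, outer = rng.choice([_EPI, _NUC, _STROMA], size=2, replace=False)
    return int(inner), int(outer)


def _scatter_blobs(
    rng: np.random.Generator, class_img: np.ndarray, cls: int, deficit: int
) -> None:
    """Deposit irregular blobs of ``cls`` on stroma until ~deficit pixels."""
    size = class_img.shape[0]
    for _ in range(200):
        if deficit <= 0:
            return
        rho = int(rng.integers(3, 7))
        c = (int(rng.integers(rho, size - rho)), int(rng.integers(rho, size - rho)))
        rr, cc = disk(c, rho, shape=class_img.shape)
        on_stroma = class_img[rr, cc] == _STROMA
        class_img[rr[on_stroma], cc[on_stroma]] = cls
        deficit -= int(on_stroma.sum())


def _class_image(
    rng: np.random.Generator, cfg: TissueSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Hard per-pixel class index image and the ground-truth lumen mask."""
    lumen, _ = _place_glands(rng, cfg)
    labels, n_glands = ndimage.label(lumen, structure=_STRUCT_4)
    dist, (ir, ic) = ndimage.distance_transform_edt(~lumen, return_indices=True)
    nearest = labels[ir, ic]
    t1, t2 = cfg.epithelium_thickness, cfg.nuclei_thickness
    shell = np.zeros_like(labels)
    shell[(dist > 0) & (dist <= t1)] = 1
    shell[(dist > t1) & (dist <= t1 + t2)] = 2

    class_img = np.full(lumen.shape, _STROMA, dtype=np.int8)
    class_img[lumen] = _LUMEN
    ordered = (_EPI, _NUC)
    ref_counts = {_EPI: 0, _NUC: 0}
    cur_counts = {_EPI: 0, _NUC: 0}
    for g in range(1, n_glands + 1):
        inner, outer = _layer_classes(rng, cfg)
        for s, cls in ((1, inner), (2, outer)):
            sel = (nearest == g) & (shell == s)
            class_img[sel] = cls
            area = int(sel.sum())
            ref_counts[ordered[s - 1]] += area
            if cls in cur_counts:
                cur_counts[cls] += area
    # re-deposit displaced epithelium/nuclei as background blobs so the
    # marginal class proportions of C0 stay close to C1's
    for cls in (_EPI, _NUC):
        _scatter_blobs(rng, class_img, cls, ref_counts[cls] - cur_counts[cls])
    return class_img, lumen


def simulate_image(
    config: TissueSimConfig,
) -> tuple[ProbabilityMapStack, str, np.ndarray]:
    """Simulate one tissue image.

    Returns the probability-map stack (channels lumen, epithelium,
    nuclei, stroma), the ground-truth tissue class label and the
    ground-truth lumen mask. Bit-identical under a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    class_img, lumen = _class_image(rng, config)
    K = len(CLASS_NAMES)
    onehot = np.eye(K)[class_img]
    if config.dirichlet_concentration is None:
        values = onehot
    else:
        alpha = 1.0 + config.dirichlet_concentration * onehot
        g = rng.gamma(alpha)
        values = g / g.sum(axis=2, keepdims=True)
    stack = ProbabilityMapStack(values, list(CLASS_NAMES))
    return stack, config.tissue_class, lumen


def simulate_dataset(
    config: TissueSimConfig,
    n_images_per_class: int,
    gland_count_range: tuple[int, int] = (2, 8),
    extract_config: ExtractConfig | None = None,
) -> SimulatedDataset:
    """Simulate a labeled bag dataset of C0 and C1 images.

    Per-image gland counts are drawn uniformly from
    ``gland_count_range`` (inclusive), emulating the variable number of
    lumen regions per real image. Each image becomes one bag of proximity
    features and one bag of the four shape features (the classical
    baseline). The manifest records every per-image seed and parameter so
    the dataset regenerates exactly.
    """
    if n_images_per_class < 1:
        raise ValueError("need at least one image per class")
    if extract_config is None:
        # generated channel order is known, so mean-intensity reordering
        # (which assumes lumen-dominant staining) is disabled
        extract_config = ExtractConfig(order_channels=False)
    rng = np.random.default_rng(config.seed)
    bags: list[Bag] = []
    shape_bags: list[Bag] = []
    labels: list[str] = []
    images: list[dict[str, Any]] = []
    for label in ("C0", "C1"):
        for i in range(n_images_per_class):
            img_seed = int(rng.integers(2**31))
            n_glands = int(rng.integers(gland_count_range[0], gland_count_range[1] + 1))
            cfg_i = replace(
                config, seed=img_seed, n_glands=n_glands, tissue_class=label
            )
            stack, _, _ = simulate_image(cfg_i)
            feats = extract_image_features(stack, extract_config)
            if not feats:
                continue
            bag_id = f"{label}_{i:03d}"
            bags.append(
                Bag(bag_id, np.array([f.vector for f in feats]), label=label)
            )
            mask = binarize_lumen(stack, mode=extract_config.binarize_mode)
            regions = label_lumen_regions(mask, min_area=extract_config.min_area)
            shp = np.array(
                [
                    shape_features(regions.region_mask(r)).as_vector()
                    for r in range(1, regions.n_regions + 1)
                ]
            )
            shape_bags.append(Bag(bag_id, shp, label=label))
            labels.append(label)
            images.append({"bag_id": bag_id, "seed": img_seed, "n_glands": n_glands})
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "n_images_per_class": n_images_per_class,
        "gland_count_range": list(gland_count_range),
        "images": images,
    }
    return SimulatedDataset(bags, shape_bags, labels, manifest)
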