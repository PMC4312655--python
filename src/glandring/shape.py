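"""Classical scalar shape features of lumen regions.

Four baseline descriptors computed per lumen region: size (pixel count),
bending energy of the boundary (sum of squared smoothed curvature, minimal
2*pi/R for a circle of radius R), area-to-perimeter ratio 4*pi*A/P^2, and
convexity A_region / A_convex_hull. The boundary is traced as a closed
8-directional Freeman chain code (Moore neighbor tracing); the perimeter
weighs diagonal chain steps by sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import ConvexHull

# Freeman 8-directions in (row, col) offsets, counter-clockwise from East
_DIRS = np.array(
    [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)
_STEP_LEN = np.array([1.0, np.sqrt(2)] * 4)


@dataclass
class ShapeFeatures:
    """The four scalar lumen descriptors."""

    size: int
    bending_energy: float
    area_perimeter_ratio: float
    convexity: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.size, self.bending_energy, self.area_perimeter_ratio, self.convexity]
        )


def trace_boundary(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trace the outer boundary of a single region (Moore tracing).

    Returns ``(points, chain)``: an ordered (N, 2) array of boundary pixel
    coordinates (row, col) and the closed Freeman chain code (direction
    index into the 8-neighborhood for each step; the last step returns to
    the start point). A 1-pixel region yields one point and an empty chain.
    """
    mask = np.asarray(mask, dtype=bool)
    fg = np.argwhere(mask)
    if fg.size == 0:
        raise ValueError("empty mask")
    if fg.shape[0] == 1:
        return fg.copy(), np.zeros(0, dtype=np.int64)
    # pad so neighbor lookups never leave the array
    pad = np.pad(mask, 1)
    start = tuple(fg[0] + 1)  # topmost, then leftmost pixel

    # screen-clockwise neighbor order starting East (row axis points down)
    ring = [0, 7, 6, 5, 4, 3, 2, 1]
    pos_in_ring = {d: i for i, d in enumerate(ring)}

    # state: (current pixel, direction to its known-background backtrack);
    # the West neighbor of the start pixel is background by construction.
    # The walk terminates when it is about to re-traverse its first
    # directed boundary edge (robust on 1-pixel-wide spurs, where the
    # plain revisit-the-start criterion never fires).
    cur, back_dir = start, 4
    points: list[tuple[int, int]] = []
    chain: list[int] = []
    first_edge: tuple[tuple[int, int], int] | None = None
    limit = 8 * pad.size
    while True:
        # scan clockwise from just past the backtrack until foreground
        i0 = pos_in_ring[back_dir]
        for i in range(1, 9):
            d = ring[(i0 + i) % 8]
            nxt = (cur[0] + _DIRS[d][0], cur[1] + _DIRS[d][1])
            if pad[nxt]:
                break
        if first_edge is None:
            first_edge = (cur, d)
        elif (cur, d) == first_edge:
            break
        points.append(cur)
        chain.append(d)
        prev = ring[(i0 + i - 1) % 8]  # last background neighbor scanned
        # backtrack of the new pixel = that background neighbor of cur
        bpix = (cur[0] + _DIRS[prev][0], cur[1] + _DIRS[prev][1])
        back_dir = next(
            k
            for k in range(8)
            if (nxt[0] + _DIRS[k][0], nxt[1] + _DIRS[k][1]) == bpix
        )
        cur = nxt
        if len(chain) > limit:
            raise RuntimeError("boundary tracing failed to close")
    pts = np.array(points, dtype=np.int64) - 1
    return pts, np.array(chain, dtype=np.int64)


def _closed_steps(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic steps (dy, dx) and their lengths along a closed boundary."""
    nxt = np.roll(points, -1, axis=0)
    steps = nxt - points
    lens = np.hypot(steps[:, 0], steps[:, 1])
    return steps, lens


def bending_energy(points: np.ndarray, smoothing_sigma: float = 4.0) -> float:
    """Sum of squared smoothed boundary curvature.

    The direction angle theta of each chain step is differenced cyclically
    (wrapped to (-pi, pi]), smoothed with a circular Gaussian of
    ``smoothing_sigma`` boundary samples, converted to curvature per unit
    arc length, and the squared curvature is integrated over the boundary:
    ``E_b = sum(kappa_i^2 * ds_i)``. A circle of radius R attains the
    minimum 2*pi/R in the continuum limit. Degenerate boundaries (< 3
    points) return 0.
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 3:
        return 0.0
    steps, lens = _closed_steps(points)
    if not np.all(np.abs(steps) <= 1):
        raise ValueError("boundary is not a closed 8-connected chain")
    theta = np.arctan2(steps[:, 0], steps[:, 1])
    dtheta = np.diff(theta, append=theta[0])
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi  # wrap to (-pi, pi]
    if smoothing_sigma > 0:
        dtheta = gaussian_filter1d(dtheta, smoothing_sigma, mode="wrap")
    # arc length attributed to each turning sample: step leaving the vertex
    ds = np.roll(lens, -1)
    kappa = dtheta / ds
    return float(np.sum(kappa**2 * ds))


def turning_sum(points: np.ndarray) -> float:
    """Total unsmoothed turning angle around the boundary (+-2*pi)."""
    points = np.asarray(points, dtype=np.float64)
    steps, _ = _closed_steps(points)
    theta = np.arctan2(steps[:, 0], steps[:, 1])
    dtheta = np.diff(theta, append=theta[0])
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    return float(dtheta.sum())


def perimeter(chain: np.ndarray) -> float:
    """Chain-code perimeter: diagonal steps weigh sqrt(2)."""
    chain = np.asarray(chain, dtype=np.int64)
    if chain.size == 0:
        return 0.0
    return float(_STEP_LEN[chain].sum())


def area_perimeter_ratio(mask: np.ndarray) -> float:
    """Isoperimetric ratio 4*pi*A / P^2 of a single region.

    Approaches 1 for a circle and pi/4 for a square in the continuum
    limit; small for elongated regions. A 1-pixel region is defined as 1.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    _, chain = trace_boundary(mask)
    p = perimeter(chain)
    if p == 0.0:
        return 1.0
    return float(4 * np.pi * area / p**2)


def convexity(mask: np.ndarray) -> float:
    """Solidity: region area over convex-hull area, in [0, 1].

    The hull is taken over pixel-corner points so convex regions (filled
    rectangles) score exactly 1.
    """
    mask = np.asarray(mask, dtype=bool)
    fg = np.argwhere(mask)
    if fg.size == 0:
        raise ValueError("empty mask")
    area = float(fg.shape[0])
    corners = np.concatenate(
        [fg + off for off in ((0, 0), (0, 1), (1, 0), (1, 1))]
    ).astype(np.float64)
    hull_area = ConvexHull(corners).volume
    return float(min(1.0, area / hull_area))


def shape_features(mask: np.ndarray, smoothing_sigma: float = 4.0) -> ShapeFeatures:
    """All four scalar descriptors of one lumen region."""
    mask = np.asarray(mask, dtype=bool)
    pts, chain = trace_boundary(mask)
    p = perimeter(chain)
    area = int(mask.sum())
    apr = 1.0 if p == 0.0 else float(4 * np.pi * area / p**2)
    return ShapeFeatures(
        size=area,
        bending_energy=bending_energy(pts, smoothing_sigma),
        area_perimeter_ratio=apr,
        convexity=convexity(mask),
    )
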