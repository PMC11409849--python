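"""Base 2D coronal lung geometry and randomized defect-cluster placement.

Coordinate convention: axis 0 is y (head-foot, increasing caudally), axis 1
is x (left-right); 0-based with the origin at the image top-left.  The lung
on the image-left half is the anatomical right lung (radiological display
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    LUNG_CLASSES,
    SEEDED_CLASSES,
    ConfigurationError,
    GridSpec,
    LayoutConfig,
    Tissue,
)


class GenerationError(RuntimeError):
    """Raised when randomized placement cannot satisfy the request."""


@dataclass
class ClassMap:
    """Integer label image on the base grid plus its construction parameters."""

    labels: np.ndarray
    grid: GridSpec
    layout: LayoutConfig

    @property
    def lung_roi(self) -> np.ndarray:
        """Boolean union of the eight lung subclasses."""
        roi = np.zeros(self.labels.shape, dtype=bool)
        for label in LUNG_CLASSES:
            roi |= self.labels == label
        return roi

    @property
    def right_lung(self) -> np.ndarray:
        """Anatomical right lung (image-left half)."""
        mask = self.lung_roi.copy()
        mask[:, self.grid.base_matrix // 2 :] = False
        return mask

    @property
    def left_lung(self) -> np.ndarray:
        mask = self.lung_roi.copy()
        mask[:, : self.grid.base_matrix // 2] = False
        return mask

    def counts(self) -> dict[Tissue, int]:
        return {t: int(np.count_nonzero(self.labels == t)) for t in Tissue}

    def upsampled_labels(self, factor: int) -> np.ndarray:
        """Nearest-neighbour label image on a finer grid."""
        return np.repeat(np.repeat(self.labels, factor, axis=0), factor, axis=1)


@dataclass
class QuadrantMasks:
    """Equally sized UR/UL/LR/LL partition of the lung ROI."""

    UR: np.ndarray
    UL: np.ndarray
    LR: np.ndarray
    LL: np.ndarray

    def items(self):
        return (("UR", self.UR), ("UL", self.UL), ("LR", self.LR), ("LL", self.LL))

    def upsampled(self, factor: int) -> "QuadrantMasks":
        up = lambda m: np.repeat(np.repeat(m, factor, axis=0), factor, axis=1)
        return QuadrantMasks(up(self.UR), up(self.UL), up(self.LR), up(self.LL))


def build_base_geometry(grid: GridSpec | None = None,
                        layout: LayoutConfig | None = None) -> ClassMap:
    """Construct the expiration-state geometry.

    Three nested rectangles define background, body and the two lungs; a
    vessel disk sits centered in the inter-lung gap at lung mid-height.  All
    lung voxels start as normally ventilated/perfused tissue.
    """
    grid = grid or GridSpec()
    layout = layout or LayoutConfig()
    n = grid.base_matrix
    labels = np.full((n, n), int(Tissue.BACKGROUND), dtype=np.int16)

    b0 = (n - layout.body_size) // 2
    b1 = b0 + layout.body_size
    if b0 < 0:
        raise ConfigurationError("body does not fit into the grid")
    labels[b0:b1, b0:b1] = Tissue.BODY

    cx = n // 2
    half_gap = layout.lung_gap // 2
    y0 = layout.lung_start
    y1 = y0 + layout.lung_height
    rx0 = cx - half_gap - layout.lung_width  # image-left (anatomical right) lung
    rx1 = cx - half_gap
    lx0 = cx + half_gap
    lx1 = cx + half_gap + layout.lung_width
    if y0 < b0 or y1 > b1 or rx0 < b0 or lx1 > b1:
        raise ConfigurationError("lungs extend outside the body rectangle")
    labels[y0:y1, rx0:rx1] = Tissue.VV_QV
    labels[y0:y1, lx0:lx1] = Tissue.VV_QV

    if layout.vessel_radius > 0:
        vy = y0 + layout.lung_height // 2
        vx = cx
        yy, xx = np.ogrid[:n, :n]
        disk = (yy - vy) ** 2 + (xx - vx) ** 2 <= layout.vessel_radius**2
        disk &= labels == Tissue.BODY  # never overwrite lung voxels
        labels[disk] = Tissue.VESSEL

    return ClassMap(labels=labels, grid=grid, layout=layout)


def _grow_cluster(
    available: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Grow one 4-connected cluster of ``size`` voxels inside ``available``.

    Returns the (size, 2) voxel coordinates, or None if growth got stuck.
    """
    coords = np.argwhere(available)
    seed = coords[rng.integers(len(coords))]
    shape = available.shape
    free = available.copy()
    region = [tuple(seed)]
    free[tuple(seed)] = False
    frontier = [tuple(seed)]
    while len(region) < size:
        # collect free 4-neighbours of the current region boundary
        candidates = []
        for y, x in frontier:
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if 0 <= ny < shape[0] and 0 <= nx < shape[1] and free[ny, nx]:
                    candidates.append((ny, nx))
        if not candidates:
            return None
        pick = candidates[rng.integers(len(candidates))]
        free[pick] = False
        region.append(pick)
        frontier = region  # region stays small (60 voxels); rescan is cheap
    return np.array(region)


def seed_defect_clusters(
    class_map: ClassMap,
    sizes: dict[Tissue, int] | None = None,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 100,
) -> ClassMap:
    """Place each requested defect class as one random 4-connected cluster.

    Clusters are grown from uniform-random seeds over the currently normal
    lung voxels and are mutually disjoint.  The same generator state yields
    byte-identical maps.
    """
    if sizes is None:
        sizes = {label: 60 for label in SEEDED_CLASSES}
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    labels = class_map.labels.copy()
    n_normal = int(np.count_nonzero(labels == Tissue.VV_QV))
    if sum(sizes.values()) > n_normal:
        raise GenerationError("requested defect sizes exceed available lung voxels")

    for label in SEEDED_CLASSES:  # fixed placement order for reproducibility
        size = sizes.get(label, 0)
        if size == 0:
            continue
        available = labels == Tissue.VV_QV
        placed = False
        for _ in range(max_retries):
            cluster = _grow_cluster(available, size, rng)
            if cluster is not None:
                labels[cluster[:, 0], cluster[:, 1]] = label
                placed = True
                break
        if not placed:
            raise GenerationError(f"could not place a {size}-voxel cluster for {label.name}")

    return ClassMap(labels=labels, grid=class_map.grid, layout=class_map.layout)


def quadrant_masks(class_map: ClassMap) -> QuadrantMasks:
    """Split each lung at its vertical midline into upper/lower quadrants.

    For an odd lung height the extra row goes to the lower quadrant.
    """
    roi = class_map.lung_roi
    if not roi.any():
        raise ConfigurationError("empty lung ROI")
    rows = np.flatnonzero(roi.any(axis=1))
    split = rows[0] + (rows[-1] - rows[0] + 1) // 2
    upper = np.zeros_like(roi)
    upper[:split] = True
    right = class_map.right_lung
    left = class_map.left_lung
    return QuadrantMasks(
        UR=right & upper,
        UL=left & upper,
        LR=right & ~upper,
        LL=left & ~upper,
    )
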