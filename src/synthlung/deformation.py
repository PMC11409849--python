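"""Expansion balancing, displacement fields, warping and Jacobians.

Respiratory motion is modelled as a pure y-displacement.  A per-voxel
fractional expansion matrix E is balanced per column so that (C1) the mean
expansion over the lung rows equals the target e in every lung column and
(C2) the total column expansion is zero, the body deflating to compensate.
The forward displacement field (expiration space -> deformed space) is the
cumulative sum of E along y; the inverse field is obtained by linear
scattered interpolation of the forward-transformed grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    ZERO_EXPANSION_CLASSES,
    Tissue,
)
from .geometry import ClassMap, GenerationError


class InversionError(RuntimeError):
    """Raised when a displacement field folds and cannot be inverted."""


@dataclass
class ExpansionMatrix:
    """Balanced per-voxel fractional expansion on the base grid.

    ``E`` is 0 on background and the three non-expanding defect classes,
    ``e_target`` on normally expanding lung voxels, larger on compensatory
    voxels and negative (uniform per column) on body voxels.
    """

    E: np.ndarray
    e_target: float
    class_map: ClassMap

    @property
    def lung_mask(self) -> np.ndarray:
        return self.class_map.lung_roi


def build_expansion_matrix(
    class_map: ClassMap, e_target: float = 0.25
) -> tuple[ExpansionMatrix, ClassMap]:
    """Assign expansion factors meeting the balancing conditions C1 and C2.

    Normal lung voxels in columns containing non-expanding defects take up
    the slack (e_comp = e * (32 - n_fixed) / n_normal per column) and are
    relabeled VV_COMP_QV.  Returns the expansion matrix together with the
    updated class map.

    Raises GenerationError when a column holds defects but no normal voxel
    is left to compensate (the caller should re-seed the clusters).
    """
    labels = class_map.labels.copy()
    n = labels.shape[0]
    E = np.zeros(labels.shape, dtype=np.float64)
    lung = class_map.lung_roi

    zero = np.isin(labels, [int(t) for t in ZERO_EXPANSION_CLASSES])
    fixed = lung & ~zero & (labels != Tissue.VV_QV)  # delayed / QD classes keep e
    normal = labels == Tissue.VV_QV

    E[fixed] = e_target
    bad_columns = []
    for x in range(n):
        col_lung = lung[:, x]
        n_lung = int(col_lung.sum())
        if n_lung == 0:
            continue
        n_fixed = int(fixed[:, x].sum())
        n_normal = int(normal[:, x].sum())
        required = e_target * (n_lung - n_fixed)  # total E the normals must carry
        if n_normal == 0:
            if required > 1e-12:
                bad_columns.append(x)
            continue
        e_comp = required / n_normal
        rows = np.flatnonzero(normal[:, x])
        E[rows, x] = e_comp
        if e_comp > e_target * (1.0 + 1e-9):
            labels[rows, x] = Tissue.VV_COMP_QV
    if bad_columns:
        raise GenerationError(
            f"columns {bad_columns} are fully occupied by non-expanding defects; "
            "lung expansion cannot be balanced (re-seed the clusters)"
        )

    new_map = ClassMap(labels=labels, grid=class_map.grid, layout=class_map.layout)
    E = balance_body(E, new_map)
    return ExpansionMatrix(E=E, e_target=e_target, class_map=new_map), new_map


def balance_body(E: np.ndarray, class_map: ClassMap) -> np.ndarray:
    """Set body-voxel expansion so every column sums to zero (C2).

    The deflation is shared uniformly by all body voxels of the column.
    """
    out = E.copy()
    body = class_map.labels == Tissue.BODY
    lung = class_map.lung_roi
    lung_sum = np.where(lung, out, 0.0).sum(axis=0)
    n_body = body.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        deflation = np.where(n_body > 0, -lung_sum / np.maximum(n_body, 1), 0.0)
    out[body] = np.broadcast_to(deflation, out.shape)[body]
    return out


def time_scaled_expansion(
    expansion: ExpansionMatrix, r: np.ndarray | float
) -> np.ndarray:
    """Expansion matrix at one respiratory state.

    ``r`` is the per-voxel respiration factor in [0, 1] (scalar broadcast
    allowed).  Lung entries scale voxel-wise; the body deflation is
    re-balanced so C2 holds at the scaled state as well.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any((r < -1e-12) | (r > 1 + 1e-12)):
        raise ValueError("respiration factor must lie in [0, 1]")
    lung = expansion.lung_mask
    E_t = np.where(lung, expansion.E * r, 0.0)
    return balance_body(E_t, expansion.class_map)


def forward_field(E: np.ndarray) -> np.ndarray:
    """Forward y-displacement: cumulative sum of the expansion along y."""
    if not np.all(np.isfinite(E)):
        raise ValueError("expansion matrix contains non-finite values")
    return np.cumsum(E, axis=0)


def invert_field(F: np.ndarray) -> np.ndarray:
    """Inverse y-displacement by per-column linear scattered interpolation.

    The forward field maps grid row y to j = y + F(x, y); the scattered
    samples (j, F) are linearly interpolated onto the regular grid of the
    deformed space and negated.  Columns must not fold (j strictly
    increasing).
    """
    H, W = F.shape
    I = np.zeros_like(F, dtype=np.float64)
    y = np.arange(H, dtype=np.float64)
    active = np.flatnonzero(np.any(F != 0.0, axis=0))
    for x in active:
        col = F[:, x]
        j = y + col
        if np.any(np.diff(j) <= 0):
            raise InversionError(f"forward field folds in column {x}")
        I[:, x] = -np.interp(y, j, col)
    return I


def warp_image(image: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    """Sample ``image`` at (x, y + displacement) with linear interpolation.

    Out-of-grid samples take the nearest-edge value.  The displacement is a
    y-component field on the same grid as the image.
    """
    if image.shape != displacement.shape:
        raise ValueError(
            f"image shape {image.shape} != field shape {displacement.shape}"
        )
    H, W = image.shape
    pos = np.arange(H, dtype=np.float64)[:, None] + displacement
    np.clip(pos, 0.0, H - 1.0, out=pos)
    i0 = pos.astype(np.intp)
    np.minimum(i0, H - 2, out=i0)
    frac = pos - i0
    cols = np.arange(W, dtype=np.intp)[None, :]
    img = image.astype(np.float64, copy=False)
    return img[i0, cols] * (1.0 - frac) + img[i0 + 1, cols] * frac


def jacobian_determinant(
    displacement_y: np.ndarray, displacement_x: np.ndarray | None = None
) -> np.ndarray:
    """det of the Jacobian of f = identity + displacement, per voxel.

    Partial derivatives use central differences (one-sided at the borders).
    For a y-only field this reduces to 1 + du_y/dy.
    """
    duy_dy, duy_dx = np.gradient(np.asarray(displacement_y, dtype=np.float64))
    if displacement_x is None:
        return 1.0 + duy_dy
    dux_dy, dux_dx = np.gradient(np.asarray(displacement_x, dtype=np.float64))
    return (1.0 + duy_dy) * (1.0 + dux_dx) - duy_dx * dux_dy


def upsample_field(F: np.ndarray, factor: int) -> np.ndarray:
    """Resample a displacement field to a ``factor``-finer grid.

    Displacements are expressed in voxel units, so values scale with the
    factor; bilinear interpolation with block-center alignment.
    """
    from scipy.ndimage import zoom

    return zoom(F * factor, factor, order=1, mode="nearest", grid_mode=True)
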