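"""File-based interfaces: NIfTI images and fields, label legends, reports.

Image series are stored as 4D NIfTI (x, y, 1, t) with the frame spacing in
the header; displacement fields as 2-component NIfTI (the x-component is
identically zero but kept so external registrators can exchange fields in
the same format); class maps as integer NIfTI next to a JSON label legend.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .config import GridSpec, LayoutConfig, Tissue
from .geometry import ClassMap
from .signals import TimeSeries


def save_series(series: TimeSeries, path: str | Path) -> None:
    data = np.transpose(series.frames.astype(np.float32), (2, 1, 0))[:, :, None, :]
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header["pixdim"][4] = series.config.time.dt
    nib.save(img, str(path))


def load_frames(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    frames = np.transpose(data[:, :, 0, :], (2, 1, 0))
    return frames, float(img.header["pixdim"][4])


def save_displacement_field(field_y: np.ndarray, path: str | Path) -> None:
    """Store a y-displacement field as a 2-component (y, x) NIfTI."""
    stacked = np.stack([field_y, np.zeros_like(field_y)], axis=-1)
    nib.save(nib.Nifti1Image(np.transpose(stacked, (1, 0, 2)).astype(np.float64),
                             affine=np.eye(4)), str(path))


def load_displacement_field(path: str | Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return np.transpose(data, (1, 0, 2))[..., 0]


def save_class_map(class_map: ClassMap, path: str | Path) -> None:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(class_map.labels.T.astype(np.int16), affine=np.eye(4)),
        str(path),
    )
    legend = {int(t): t.name for t in Tissue}
    path.with_suffix("").with_suffix(".labels.json").write_text(
        json.dumps(legend, indent=2)
    )


def load_class_map(
    path: str | Path, grid: GridSpec | None = None, layout: LayoutConfig | None = None
) -> ClassMap:
    labels = np.asarray(nib.load(str(path)).dataobj, dtype=np.int16).T
    return ClassMap(
        labels=labels, grid=grid or GridSpec(), layout=layout or LayoutConfig()
    )


def save_functional_map(values: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64).T,
                             affine=np.eye(4)), str(path))
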