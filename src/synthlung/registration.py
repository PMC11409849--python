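"""Respiratory binning, reference registration, and the external adapter contract.

Frames are sorted by the respiration factor of the normally ventilated
class and split into 10 equally occupied bins (bin 1 = expiration, bin 10 =
inspiration).  The reference (REF) registration warps every frame toward
the expiration state by its own ground-truth forward displacement field, so
its only error source is interpolation between the forward and inverse
fields.  Third-party registrators plug in through a small adapter contract:
callable(moving, fixed) -> y-displacement (or (y, x) pair) on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

from .deformation import warp_image
from .signals import TimeSeries


class ContractViolationError(RuntimeError):
    """An external registrator returned an unusable displacement field."""


N_BINS = 10


@dataclass
class RespiratoryBins:
    """Assignment of frames to respiratory-state bins."""

    assignment: np.ndarray  # (T,) bin index 0..n_bins-1 (0 = expiration)
    frame_order: np.ndarray  # frames sorted by ascending respiration factor
    n_bins: int

    def frames_in(self, bin_index: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == bin_index)

    def bin_mean(self, stack: np.ndarray, bin_index: int) -> np.ndarray:
        return stack[self.frames_in(bin_index)].mean(axis=0)


def bin_by_respiration(series: TimeSeries, n_bins: int = N_BINS) -> RespiratoryBins:
    """Split frames into ``n_bins`` equal-count groups by respiration factor.

    Ties are broken by frame index (stable sort).  If the frame count is not
    divisible by ``n_bins`` the remainder frames (highest r) are dropped
    from the binning.
    """
    r = series.respiration
    order = np.argsort(r, kind="stable")
    per_bin = len(r) // n_bins
    assignment = np.full(len(r), -1, dtype=np.int64)
    for b in range(n_bins):
        assignment[order[b * per_bin : (b + 1) * per_bin]] = b
    return RespiratoryBins(assignment=assignment, frame_order=order, n_bins=n_bins)


@dataclass
class RegistrationResult:
    """Registered data in the fixed (expiration) space."""

    method: str
    registered: np.ndarray  # (K, H, W): per-frame (REF) or per-bin stack
    fields: np.ndarray  # (K, H, W) y-displacement used for each entry
    granularity: str  # "frames" or "bins"
    bins: RespiratoryBins
    fixed: np.ndarray  # average expiration image (the fixed image)

    def bin_mean_registered(self, bin_index: int) -> np.ndarray:
        if self.granularity == "bins":
            return self.registered[bin_index]
        return self.bins.bin_mean(self.registered, bin_index)

    def bin_mean_field(self, bin_index: int) -> np.ndarray:
        if self.granularity == "bins":
            return self.fields[bin_index]
        return self.bins.bin_mean(self.fields, bin_index)


def reference_register(
    series: TimeSeries, frames: np.ndarray | None = None
) -> RegistrationResult:
    """Warp every frame to expiration using the known forward fields.

    ``frames`` defaults to the noisy final-grid stack; pass
    ``series.noiseless`` to register the matched noiseless series.
    """
    stack = series.frames if frames is None else frames
    bins = bin_by_respiration(series)
    T = stack.shape[0]
    registered = np.empty_like(stack, dtype=np.float64)
    fields = np.empty_like(registered)
    for k in range(T):
        F = series.forward_displacement(k, grid="final")
        fields[k] = F
        registered[k] = warp_image(stack[k], F)
    fixed = bins.bin_mean(stack.astype(np.float64), 0)
    return RegistrationResult(
        method="REF",
        registered=registered,
        fields=fields,
        granularity="frames",
        bins=bins,
        fixed=fixed,
    )


class RegistrationAdapter(Protocol):
    def __call__(self, moving: np.ndarray, fixed: np.ndarray) -> np.ndarray: ...


def _validate_field(field: np.ndarray, shape: tuple[int, int], name: str) -> np.ndarray:
    field = np.asarray(field, dtype=np.float64)
    if field.ndim == 3 and field.shape[0] == 2:
        field = field[0]  # y-component; x-displacement is not modelled
    if field.shape != shape:
        raise ContractViolationError(
            f"adapter {name!r} returned field of shape {field.shape}, expected {shape}"
        )
    if not np.all(np.isfinite(field)):
        raise ContractViolationError(f"adapter {name!r} returned non-finite values")
    return field


def register_series(
    series: TimeSeries,
    adapter: RegistrationAdapter | Callable,
    name: str = "EXTERNAL",
) -> RegistrationResult:
    """Register the 10 bin-mean images to the average expiration image.

    The adapter receives (moving, fixed) image pairs and must return the
    y-displacement field that maps fixed-space coordinates into the moving
    image (the convention used by ``warp_image``).
    """
    bins = bin_by_respiration(series)
    stack = series.frames.astype(np.float64)
    fixed = bins.bin_mean(stack, 0)
    shape = fixed.shape
    registered = np.empty((bins.n_bins, *shape))
    fields = np.empty_like(registered)
    for b in range(bins.n_bins):
        moving = bins.bin_mean(stack, b)
        field = _validate_field(adapter(moving, fixed), shape, name)
        fields[b] = field
        registered[b] = warp_image(moving, field)
    return RegistrationResult(
        method=f"EXTERNAL:{name}" if name != "REF" else "REF",
        registered=registered,
        fields=fields,
        granularity="bins",
        bins=bins,
        fixed=fixed,
    )


def zero_adapter(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Identity registration (no displacement)."""
    return np.zeros_like(np.asarray(moving, dtype=np.float64))


def reference_adapter(series: TimeSeries) -> Callable:
    """Wrap the ground-truth fields as a bin-level adapter.

    Each call consumes the next bin's mean forward field; bins are requested
    in order by :func:`register_series`.
    """
    bins = bin_by_respiration(series)
    state = {"b": 0}

    def adapter(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
        b = state["b"]
        state["b"] += 1
        idx = bins.frames_in(b)
        return np.mean(
            [series.forward_displacement(k, grid="final") for k in idx], axis=0
        )

    return adapter
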