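"""Configuration objects for the synthetic lung phantom.

All tunable quantities of the phantom live here so that a run is fully
reconstructible from a config file plus a seed.  Defaults follow the
reference experiment: a 128x128 expiration geometry, 4-fold upscaled
warping, 256x256 output frames, 250 time points at 0.192 s, normal lung
expansion e = 0.25 and a target SNR of 5 for normally ventilated voxels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Any

import yaml


class Tissue(IntEnum):
    """Voxel class labels.

    The lung is subdivided into eight functional subclasses: normally
    ventilated/perfused tissue (VV_QV), three non-ventilating defects
    distinguished by their constant signal level (low / inspiration-level /
    high), delayed ventilation, perfusion defect, delayed perfusion, and
    compensatory hyper-expanded tissue (VV_COMP_QV).
    """

    BACKGROUND = 0
    BODY = 1
    VESSEL = 2
    VV_QV = 3
    VD_QD_LOW = 4
    VD_QD_INSP = 5
    VD_QD_HIGH = 6
    VV_DELAY_QV = 7
    VV_QD = 8
    VV_QV_DELAY = 9
    VV_COMP_QV = 10


#: lung subclasses (members of the lung ROI)
LUNG_CLASSES = frozenset(
    {
        Tissue.VV_QV,
        Tissue.VD_QD_LOW,
        Tissue.VD_QD_INSP,
        Tissue.VD_QD_HIGH,
        Tissue.VV_DELAY_QV,
        Tissue.VV_QD,
        Tissue.VV_QV_DELAY,
        Tissue.VV_COMP_QV,
    }
)

#: classes placed as random clusters
SEEDED_CLASSES = (
    Tissue.VD_QD_LOW,
    Tissue.VD_QD_INSP,
    Tissue.VD_QD_HIGH,
    Tissue.VV_DELAY_QV,
    Tissue.VV_QD,
    Tissue.VV_QV_DELAY,
)

#: non-expanding defect classes (E = 0)
ZERO_EXPANSION_CLASSES = frozenset(
    {Tissue.VD_QD_LOW, Tissue.VD_QD_INSP, Tissue.VD_QD_HIGH}
)

#: ventilation-defect truth classes for scoring VD maps
VD_TRUTH_CLASSES = frozenset({Tissue.VD_QD_LOW, Tissue.VD_QD_INSP, Tissue.VD_QD_HIGH})

#: perfusion-defect truth classes for scoring QD maps
QD_TRUTH_CLASSES = frozenset(
    {Tissue.VD_QD_LOW, Tissue.VD_QD_INSP, Tissue.VD_QD_HIGH, Tissue.VV_QD}
)


class ConfigurationError(ValueError):
    """Raised for inconsistent configuration values."""


@dataclass(frozen=True)
class GridSpec:
    """Matrix sizes of the phantom.

    base_matrix: edge length of the expiration-space geometry grid.
    upscale: integer upsampling factor used for all warping operations.
    final_matrix: edge length of the emitted image frames.
    """

    base_matrix: int = 128
    upscale: int = 4
    final_matrix: int = 256

    def __post_init__(self) -> None:
        if min(self.base_matrix, self.upscale, self.final_matrix) < 1:
            raise ConfigurationError("grid factors must be >= 1")
        if (self.base_matrix * self.upscale) % self.final_matrix:
            raise ConfigurationError(
                "base_matrix * upscale must be divisible by final_matrix"
            )

    @property
    def final_factor(self) -> int:
        """Integer zoom from base to final grid."""
        f = self.final_matrix / self.base_matrix
        if f != int(f):
            raise ConfigurationError("final_matrix must be a multiple of base_matrix")
        return int(f)


@dataclass(frozen=True)
class LayoutConfig:
    """Placement of body, lungs and vessel on the base grid.

    The body is a centered square; the two rectangular lungs are placed
    symmetric about the vertical midline, separated by ``lung_gap`` columns,
    starting at row ``lung_start``; the vessel is a disk centered between
    the lungs at lung mid-height.
    """

    body_size: int = 90
    lung_width: int = 16
    lung_height: int = 32
    lung_gap: int = 12
    lung_start: int = 40
    vessel_radius: int = 2


@dataclass(frozen=True)
class TimeGrid:
    """Temporal sampling of the series."""

    n_frames: int = 250
    dt: float = 0.192

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.dt <= 0:
            raise ConfigurationError("need n_frames >= 2 and dt > 0")

    @property
    def times(self):  # noqa: ANN201 - numpy import kept out of dataclass module top
        import numpy as np

        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class SignalConfig:
    """Parameters of the periodic signal model shared by all classes."""

    s_exp: float = 20.0
    s_body: float = 200.0
    n: int = 3
    m: int = 2
    tau_v: float = 5.0
    tau_q: float = 0.8
    a_q_lung: float = 6.0
    target_snr: float = 5.0
    channels: int = 4


@dataclass(frozen=True)
class ClassSignalParams:
    """Per-class signal time-course parameters.

    s(t) = s0 - a_v * cos^{2n}(pi t / tau_v - phi_v)
              + a_q * sin^{2m}(pi t / tau_q - phi_q)
    """

    s0: float
    a_v: float = 0.0
    a_q: float = 0.0
    tau_v: float = 5.0
    tau_q: float = 0.8
    phi_v: float = 0.0
    phi_q: float = 0.0
    n: int = 3
    m: int = 2

    def __post_init__(self) -> None:
        if self.tau_v <= 0 or self.tau_q <= 0:
            raise ConfigurationError("periods must be positive")
        if self.a_v < 0 or self.a_q < 0:
            raise ConfigurationError("amplitudes must be non-negative")


def ventilation_amplitude(s_exp: float, e: float) -> float:
    """Signal amplitude of a voxel expanding by fractional e.

    Proton density (and hence signal) scales with the inverse of volume, so a
    voxel at base signal ``s_exp`` that expands by the linear factor (1 + e)
    drops to s_exp / (1 + e) at full inspiration.
    """
    return s_exp * (1.0 - 1.0 / (1.0 + e))


def default_class_params(
    signal: SignalConfig, e_target: float
) -> dict[Tissue, ClassSignalParams]:
    """Signal parameter table for every voxel class.

    Compensatory voxels (VV_COMP_QV) are listed with the normal-class
    parameters here; their ventilation amplitude is adjusted per voxel to
    their own column-dependent expansion factor during series generation.
    """
    s = signal
    a_v = ventilation_amplitude(s.s_exp, e_target)
    s_insp = s.s_exp / (1.0 + e_target)
    common = dict(tau_v=s.tau_v, tau_q=s.tau_q, n=s.n, m=s.m)
    normal = ClassSignalParams(s0=s.s_exp, a_v=a_v, a_q=s.a_q_lung, **common)
    return {
        Tissue.BACKGROUND: ClassSignalParams(s0=0.0, **common),
        Tissue.BODY: ClassSignalParams(s0=s.s_body, **common),
        Tissue.VESSEL: ClassSignalParams(
            s0=0.9 * s.s_body, a_q=120.0, phi_q=math.pi / 2, **common
        ),
        Tissue.VV_QV: normal,
        Tissue.VD_QD_LOW: ClassSignalParams(s0=s_insp / 2.0, **common),
        Tissue.VD_QD_INSP: ClassSignalParams(s0=s_insp, **common),
        Tissue.VD_QD_HIGH: ClassSignalParams(s0=s.s_exp * 5.0, **common),
        Tissue.VV_DELAY_QV: dataclasses.replace(normal, phi_v=math.pi / 2),
        Tissue.VV_QD: dataclasses.replace(normal, a_q=0.0),
        Tissue.VV_QV_DELAY: dataclasses.replace(normal, phi_q=math.pi / 2),
        Tissue.VV_COMP_QV: normal,
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one synthetic phantom."""

    grid: GridSpec = field(default_factory=GridSpec)
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    time: TimeGrid = field(default_factory=TimeGrid)
    signal: SignalConfig = field(default_factory=SignalConfig)
    e_target: float = 0.25
    defect_size: int = 60
    noise: bool = True
    seed: int = 0

    def class_params(self) -> dict[Tissue, ClassSignalParams]:
        return default_class_params(self.signal, self.e_target)

    def defect_sizes(self) -> dict[Tissue, int]:
        return {label: self.defect_size for label in SEEDED_CLASSES}


@dataclass(frozen=True)
class ExperimentConfig:
    """A repeated-phantom validation experiment."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_phantoms: int = 20
    base_seed: int = 0
    registrations: tuple[str, ...] = ("REF",)

    def __post_init__(self) -> None:
        if self.n_phantoms < 1:
            raise ConfigurationError("n_phantoms must be >= 1")
        for name in self.registrations:
            if name != "REF" and not name.startswith("external:"):
                raise ConfigurationError(f"unknown registration method: {name!r}")


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, IntEnum):
        return int(obj)
    return obj


def config_to_dict(cfg: Any) -> dict:
    return _to_plain(cfg)


def config_hash(cfg: Any) -> str:
    """Stable short hash used to tag output files."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def experiment_config_from_dict(data: dict) -> ExperimentConfig:
    phantom = data.get("phantom", {})
    pc = PhantomConfig(
        grid=GridSpec(**phantom.get("grid", {})),
        layout=LayoutConfig(**phantom.get("layout", {})),
        time=TimeGrid(**phantom.get("time", {})),
        signal=SignalConfig(**phantom.get("signal", {})),
        e_target=phantom.get("e_target", 0.25),
        defect_size=phantom.get("defect_size", 60),
        noise=phantom.get("noise", True),
        seed=phantom.get("seed", 0),
    )
    return ExperimentConfig(
        phantom=pc,
        n_phantoms=data.get("n_phantoms", 20),
        base_seed=data.get("base_seed", 0),
        registrations=tuple(data.get("registrations", ("REF",))),
    )


def load_experiment_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return experiment_config_from_dict(data)


def save_config(cfg: Any, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
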