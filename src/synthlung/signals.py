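"""Signal time courses, multi-coil noise and full series assembly.

Every voxel class follows the periodic lung signal model

    s(t) = s0 - A_V cos^{2n}(pi t / tau_V - phi_V)
              + A_Q sin^{2m}(pi t / tau_Q - phi_Q)

with a ventilation component (period tau_V ~ 5 s) and a cardiac/perfusion
component (period tau_Q ~ 0.8 s).  The inverse of the ventilation part
serves as a volume surrogate from which a per-voxel respiration factor
r(t) in [0, 1] is derived; r scales the voxel's expansion over time.

Noise mimics a magnitude reconstruction: the signal is split over four
pseudo coil channels, independent Gaussian noise is added per channel and
the channels are combined by sum of squares, yielding (non-central) chi
statistics.  The per-channel standard deviation is calibrated analytically
so normally ventilated voxels reach a target SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom
from scipy.optimize import brentq
from scipy.special import eval_genlaguerre

from .config import (
    ClassSignalParams,
    PhantomConfig,
    Tissue,
    ventilation_amplitude,
)
from .deformation import (
    ExpansionMatrix,
    balance_body,
    build_expansion_matrix,
    forward_field,
    invert_field,
    upsample_field,
    warp_image,
)
from .geometry import (
    ClassMap,
    GenerationError,
    build_base_geometry,
    seed_defect_clusters,
)


def class_signal(params: ClassSignalParams, t: np.ndarray | float) -> np.ndarray:
    """Evaluate the class signal model at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=np.float64)
    vent = params.a_v * np.cos(np.pi * t / params.tau_v - params.phi_v) ** (2 * params.n)
    perf = params.a_q * np.sin(np.pi * t / params.tau_q - params.phi_q) ** (2 * params.m)
    return params.s0 - vent + perf


def ventilation_signal(params: ClassSignalParams, t: np.ndarray) -> np.ndarray:
    """Ventilation-only part of the signal (no cardiac component)."""
    t = np.asarray(t, dtype=np.float64)
    return params.s0 - params.a_v * np.cos(
        np.pi * t / params.tau_v - params.phi_v
    ) ** (2 * params.n)


def respiration_factor(params: ClassSignalParams, times: np.ndarray) -> np.ndarray:
    """Min-max normalized inverse-signal volume surrogate on the time grid.

    r = 1 at the frame of maximal surrogate volume (inspiration) and 0 at
    the minimum (expiration).  A voxel without ventilation amplitude has a
    constant surrogate; by convention its r is identically 0 (no motion).
    """
    if params.s0 <= params.a_v:
        raise ValueError("signal model requires s0 > a_v")
    if params.a_v == 0:
        return np.zeros(np.shape(times), dtype=np.float64)
    v = 1.0 / ventilation_signal(params, times)
    vmin, vmax = v.min(), v.max()
    return (v - vmin) / (vmax - vmin)


def _sos_snr(sigma: float, signal: float, channels: int) -> float:
    """Analytic mean/std ratio of the sum-of-squares magnitude.

    With per-channel signal signal/sqrt(channels) and noise std sigma, the
    combined magnitude is sigma times a non-central chi variate with
    ``channels`` degrees of freedom and non-centrality lam = signal^2/sigma^2.
    """
    lam = (signal / sigma) ** 2
    m1 = sigma * np.sqrt(np.pi / 2.0) * eval_genlaguerre(0.5, channels / 2.0 - 1.0, -lam / 2.0)
    m2 = sigma**2 * (channels + lam)
    var = m2 - m1**2
    return float(m1 / np.sqrt(var))


def calibrate_noise_sigma(
    target_snr: float, reference_signal: float, channels: int = 4
) -> float:
    """Per-channel noise std giving the requested combined-magnitude SNR."""
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    if reference_signal <= 0:
        raise ValueError("reference_signal must be positive")
    lo = reference_signal / target_snr * 1e-3
    hi = reference_signal / target_snr * 1e3
    return float(brentq(lambda s: _sos_snr(s, reference_signal, channels) - target_snr, lo, hi, xtol=1e-12))


def add_coil_noise(
    image: np.ndarray, sigma: float, channels: int = 4,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sum-of-squares combination of noisy pseudo coil channels.

    Each channel carries image/sqrt(channels) plus independent zero-mean
    Gaussian noise of std ``sigma``; sigma = 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.asarray(image, dtype=np.float64).copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    per_channel = np.asarray(image, dtype=np.float64) / np.sqrt(channels)
    total = np.zeros_like(per_channel)
    for _ in range(channels):
        total += (per_channel + rng.normal(0.0, sigma, size=per_channel.shape)) ** 2
    return np.sqrt(total)


@dataclass
class TimeSeries:
    """A generated 2D+t phantom with its ground truth attached."""

    frames: np.ndarray  # (T, final, final) float32
    frames_base: np.ndarray  # (T, base, base) float32, before final interpolation
    class_map: ClassMap  # base grid, compensation voxels relabeled
    expansion: ExpansionMatrix  # full-inspiration balanced E
    r_table: np.ndarray  # (G, T) respiration factor per signal group
    group_map: np.ndarray  # (base, base) int group index per voxel
    sigma: float
    config: PhantomConfig
    noiseless: np.ndarray | None = None
    noiseless_base: np.ndarray | None = None
    _r_normal: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.config.time.times

    @property
    def respiration(self) -> np.ndarray:
        """Respiration factor of the normally ventilated class, per frame."""
        return self._r_normal

    @property
    def lung_roi_final(self) -> np.ndarray:
        return np.repeat(
            np.repeat(self.class_map.lung_roi, self.config.grid.final_factor, axis=0),
            self.config.grid.final_factor,
            axis=1,
        )

    @property
    def labels_final(self) -> np.ndarray:
        return self.class_map.upsampled_labels(self.config.grid.final_factor)

    def expansion_at(self, frame: int) -> np.ndarray:
        """Balanced expansion matrix at one frame (base grid)."""
        r = self.r_table[self.group_map, frame]
        lung = self.class_map.lung_roi
        E_t = np.where(lung, self.expansion.E * r, 0.0)
        return balance_body(E_t, self.class_map)

    def forward_displacement(self, frame: int, grid: str = "base") -> np.ndarray:
        """Ground-truth forward y-displacement of one frame."""
        F = forward_field(self.expansion_at(frame))
        if grid == "base":
            return F
        if grid == "final":
            return upsample_field(F, self.config.grid.final_factor)
        raise ValueError("grid must be 'base' or 'final'")

    def inverse_displacement(self, frame: int) -> np.ndarray:
        return invert_field(self.forward_displacement(frame))


def _unique_groups(arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Group voxels by identical parameter tuples.

    Returns (group_map, index of one representative voxel per group).
    """
    stacked = np.stack([a.ravel() for a in arrays], axis=1)
    _, first, inverse = np.unique(
        stacked, axis=0, return_index=True, return_inverse=True
    )
    return inverse.reshape(arrays[0].shape), first


def _block_mean(img: np.ndarray, factor: int) -> np.ndarray:
    h, w = img.shape
    return img.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def generate_series(
    config: PhantomConfig | None = None, keep_noiseless: bool = False
) -> TimeSeries:
    """Generate one phantom time series.

    Pipeline per frame: evaluate per-voxel signals in expiration space,
    scale the expansion matrix by the per-voxel respiration factor, warp
    with the frame's inverse displacement on the upscaled grid, block-average
    back to the base grid, add coil noise, and linearly interpolate to the
    final matrix.  The series is a pure function of the config (seed
    included).
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)
    base = build_base_geometry(config.grid, config.layout)

    expansion = class_map = None
    for _ in range(25):
        seeded = seed_defect_clusters(base, config.defect_sizes(), rng)
        try:
            expansion, class_map = build_expansion_matrix(seeded, config.e_target)
            break
        except GenerationError:
            continue
    if expansion is None:
        raise GenerationError("could not seed clusters into a balanceable geometry")

    params = config.class_params()
    labels = class_map.labels
    s0 = np.empty(labels.shape)
    a_v = np.empty(labels.shape)
    a_q = np.empty(labels.shape)
    phi_v = np.empty(labels.shape)
    phi_q = np.empty(labels.shape)
    for tissue, p in params.items():
        sel = labels == tissue
        s0[sel], a_v[sel], a_q[sel] = p.s0, p.a_v, p.a_q
        phi_v[sel], phi_q[sel] = p.phi_v, p.phi_q
    # compensatory voxels: ventilation amplitude follows their own expansion
    comp = labels == Tissue.VV_COMP_QV
    a_v[comp] = ventilation_amplitude(config.signal.s_exp, expansion.E[comp])

    group_map, first = _unique_groups([s0, a_v, a_q, phi_v, phi_q])
    times = config.time.times
    n_groups = len(first)
    sig = config.signal
    s_table = np.empty((n_groups, len(times)))
    r_table = np.empty((n_groups, len(times)))
    flat = [a.ravel() for a in (s0, a_v, a_q, phi_v, phi_q)]
    for g, idx in enumerate(first):
        p = ClassSignalParams(
            s0=flat[0][idx], a_v=flat[1][idx], a_q=flat[2][idx],
            phi_v=flat[3][idx], phi_q=flat[4][idx],
            tau_v=sig.tau_v, tau_q=sig.tau_q, n=sig.n, m=sig.m,
        )
        s_table[g] = class_signal(p, times)
        r_table[g] = respiration_factor(p, times) if p.s0 > p.a_v else 0.0

    sigma = (
        calibrate_noise_sigma(sig.target_snr, sig.s_exp, sig.channels)
        if config.noise
        else 0.0
    )

    up = config.grid.upscale
    final_f = config.grid.final_factor
    nb = config.grid.base_matrix
    T = len(times)
    lung = class_map.lung_roi

    frames_base = np.empty((T, nb, nb), dtype=np.float32)
    frames = np.empty((T, nb * final_f, nb * final_f), dtype=np.float32)
    clean_base = np.empty_like(frames_base) if keep_noiseless else None
    clean = np.empty_like(frames) if keep_noiseless else None

    for k in range(T):
        r_k = r_table[group_map, k]
        E_k = balance_body(np.where(lung, expansion.E * r_k, 0.0), class_map)
        E_up = np.repeat(np.repeat(E_k, up, axis=0), up, axis=1)
        inverse_up = invert_field(forward_field(E_up))
        painted = s_table[group_map, k]
        painted_up = np.repeat(np.repeat(painted, up, axis=0), up, axis=1)
        warped = _block_mean(warp_image(painted_up, inverse_up), up)
        if keep_noiseless:
            clean_base[k] = warped
            clean[k] = zoom(warped, final_f, order=1, mode="nearest", grid_mode=True)
        noisy = add_coil_noise(warped, sigma, sig.channels, rng)
        frames_base[k] = noisy
        frames[k] = zoom(noisy, final_f, order=1, mode="nearest", grid_mode=True)

    r_normal = respiration_factor(params[Tissue.VV_QV], times)
    return TimeSeries(
        frames=frames,
        frames_base=frames_base,
        class_map=class_map,
        expansion=expansion,
        r_table=r_table,
        group_map=group_map,
        sigma=sigma,
        config=config,
        noiseless=clean,
        noiseless_base=clean_base,
        _r_normal=r_normal,
    )
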