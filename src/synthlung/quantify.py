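"""Functional maps: signal-based ventilation (RVent), Jacobian ventilation
(JVent), and perfusion amplitude (QA).

RVent follows the inverse signal-volume relation,

    RVent = s_reg * (s_exp - s_insp) / (s_insp * s_exp),

evaluated on bin-averaged registered inspiration/expiration images; with
the expiration average as the fixed image this reduces to s_exp/s_insp - 1.
JVent is det(J(identity + displacement)) - 1 of the averaged inspiration
forward field.  QA is the peak-to-peak amplitude of the high-pass filtered
(cardiac-band) registered signal, with the extremal cardiac phases picked
globally from the ROI-averaged signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import butter, sosfiltfilt
from scipy.special import eval_genlaguerre

from .deformation import jacobian_determinant
from .registration import RegistrationResult
from .signals import TimeSeries


@dataclass
class FunctionalMap:
    """A functional parameter image over the lung ROI."""

    values: np.ndarray
    kind: str  # "rvent" | "jvent" | "qa" | "rvent*"
    method: str  # registration provenance tag
    roi: np.ndarray
    invalid: int = 0  # voxels masked because of non-positive signals

    def mean(self) -> float:
        return float(np.nanmean(self.values[self.roi]))

    def median(self) -> float:
        return float(np.nanmedian(self.values[self.roi]))


def compute_rvent(
    insp_mean: np.ndarray,
    exp_mean: np.ndarray,
    reg_mean: np.ndarray,
    roi: np.ndarray,
    method: str = "REF",
) -> FunctionalMap:
    """Signal-based regional ventilation from registered state averages.

    Voxels with non-positive inspiration or expiration signal inside the
    ROI are masked as NaN and counted.
    """
    insp = np.asarray(insp_mean, dtype=np.float64)
    exp_ = np.asarray(exp_mean, dtype=np.float64)
    reg = np.asarray(reg_mean, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = reg * (exp_ - insp) / (insp * exp_)
    bad = roi & ((insp <= 0) | (exp_ <= 0))
    values[bad] = np.nan
    return FunctionalMap(
        values=values, kind="rvent", method=method, roi=roi,
        invalid=int(bad.sum()),
    )


def _magnitude_mean(signal: np.ndarray, sigma: float, channels: int) -> np.ndarray:
    """Expected sum-of-squares magnitude for true signal level(s)."""
    lam = (np.asarray(signal, dtype=np.float64) / sigma) ** 2
    return sigma * np.sqrt(np.pi / 2.0) * eval_genlaguerre(
        0.5, channels / 2.0 - 1.0, -lam / 2.0
    )


def chi_mean_factor(channels: int = 4) -> float:
    """Mean of the pure-noise combined magnitude in units of sigma."""
    return float(_magnitude_mean(0.0, 1.0, channels))


def estimate_background_sigma(
    frames: np.ndarray, background: np.ndarray, channels: int = 4
) -> float:
    """Per-channel noise std from the mean background magnitude.

    The background carries no signal, so its combined magnitude follows a
    (central) chi law whose mean is sigma times a known factor.
    """
    if not background.any():
        raise ValueError("empty background mask")
    return float(frames[:, background].mean() / chi_mean_factor(channels))


def correct_magnitude_bias(
    values: np.ndarray, sigma: float, channels: int = 4
) -> np.ndarray:
    """Invert the magnitude-operation bias on (nearly noise-free) averages.

    Maps an observed mean combined magnitude back to the underlying signal
    level by inverting the analytic first moment of the non-central chi
    law.  Intended for temporal averages whose residual noise is small.
    """
    values = np.asarray(values, dtype=np.float64)
    if sigma <= 0:
        return values.copy()
    top = max(float(values.max()) / sigma + 2.0, 8.0)
    s_grid = np.linspace(0.0, top * sigma, 4096)
    m_grid = _magnitude_mean(s_grid, sigma, channels)
    return np.interp(values, m_grid, s_grid)


def correct_noise_floor_frames(
    frames: np.ndarray, sigma: float, channels: int = 4
) -> np.ndarray:
    """Per-sample noise-floor correction of combined magnitudes.

    The classical square-root correction sqrt(max(M^2 - (k-1) sigma^2, 0));
    its residual bias is nearly constant over the relevant signal range, so
    signal *differences* (as used by the perfusion amplitude) are restored.
    """
    if sigma <= 0:
        return np.asarray(frames, dtype=np.float64)
    sq = np.asarray(frames, dtype=np.float64) ** 2 - (channels - 1) * sigma**2
    return np.sqrt(np.maximum(sq, 0.0))


def cardiac_waveform(
    registered_frames: np.ndarray,
    roi: np.ndarray,
    dt: float,
    cutoff: float = 0.9,
    cardiac_period: float | None = None,
    phase_bins: int | None = None,
) -> np.ndarray:
    """Non-negative cardiac signal template, one value per frame.

    The ROI-averaged series is high-pass filtered, frames are grouped by
    cardiac phase and averaged, and the minimal phase value is subtracted:
    pulsatile inflow only ever adds signal, so the quietest cardiac phase
    defines the baseline.  Because the template comes from the ROI average
    its noise is negligible compared to per-voxel noise.
    """
    T = registered_frames.shape[0]
    roi_series = registered_frames[:, roi].mean(axis=1).astype(np.float64)
    filt = highpass_filter(roi_series[:, None], dt, cutoff)[:, 0]
    if cardiac_period is None:
        cardiac_period = estimate_cardiac_period(roi_series, dt, cutoff)
    if phase_bins is None:
        phase_bins = _phase_bin_count(dt, cardiac_period, T)
    t = np.arange(T) * dt
    phase = (t % cardiac_period) / cardiac_period
    bins = np.round(phase * phase_bins).astype(int) % phase_bins
    means = np.array(
        [filt[bins == b].mean() if (bins == b).any() else np.nan
         for b in range(phase_bins)]
    )
    template = means[bins]
    return template - np.nanmin(means)


def remove_cardiac_component(
    registered_frames: np.ndarray, template: np.ndarray
) -> np.ndarray:
    """Subtract each voxel's least-squares projection onto the template.

    The per-voxel amplitude is regressed against the zero-mean part of the
    template but the full non-negative template is subtracted, so the
    cardiac oscillation *and* its DC offset are removed together.  The
    regression coefficient has zero-mean noise, so voxels without a cardiac
    component are not biased.
    """
    T = registered_frames.shape[0]
    flat = registered_frames.reshape(T, -1).astype(np.float64)
    g = np.asarray(template, dtype=np.float64)
    gc = g - g.mean()
    denom = float(gc @ gc)
    if denom <= 0:
        return registered_frames.astype(np.float64)
    beta = (gc @ flat) / denom
    return (flat - np.outer(g, beta)).reshape(registered_frames.shape)


def rvent_from_registration(
    reg: RegistrationResult,
    roi: np.ndarray,
    dt: float | None = None,
    cardiac_correction: bool = True,
    noise_sigma: float = 0.0,
    channels: int = 4,
) -> FunctionalMap:
    """RVent from a registration result.

    When the result carries the full registered frame series and ``dt`` is
    given, the cardiac component is separated out (regression against the
    global cardiac template) before the respiratory state averages are
    formed, so the ventilation states reflect proton density alone.  If a
    noise level is supplied, the magnitude-operation bias of the state
    averages is inverted analytically (the noise floor otherwise deflates
    the expiration/inspiration signal ratio).  With per-bin granularity the
    plain bin means are used.
    """
    if cardiac_correction and reg.granularity == "frames" and dt is not None:
        template = cardiac_waveform(reg.registered, roi, dt)
        frames = remove_cardiac_component(reg.registered, template)
        insp = reg.bins.bin_mean(frames, reg.bins.n_bins - 1)
        exp_ = reg.bins.bin_mean(frames, 0)
    else:
        insp = reg.bin_mean_registered(reg.bins.n_bins - 1)
        exp_ = reg.bin_mean_registered(0)
    if noise_sigma > 0:
        insp = correct_magnitude_bias(insp, noise_sigma, channels)
        exp_ = correct_magnitude_bias(exp_, noise_sigma, channels)
    return compute_rvent(insp, exp_, exp_, roi, method=reg.method)


def compute_jvent(
    mean_insp_field: np.ndarray, roi: np.ndarray, method: str = "REF"
) -> FunctionalMap:
    """Deformation-based ventilation: Jacobian determinant minus one."""
    values = jacobian_determinant(mean_insp_field) - 1.0
    return FunctionalMap(values=values, kind="jvent", method=method, roi=roi)


def jvent_from_registration(reg: RegistrationResult, roi: np.ndarray) -> FunctionalMap:
    field = reg.bin_mean_field(reg.bins.n_bins - 1)
    return compute_jvent(field, roi, method=reg.method)


def highpass_filter(
    signals: np.ndarray,
    dt: float,
    cutoff: float = 0.9,
    design: str = "fft",
    order: int = 4,
) -> np.ndarray:
    """Zero-phase high-pass along axis 0.

    The default realization zeroes all Fourier components below the cutoff
    (the standard Fourier-decomposition approach); it is phase-free and
    leaves the cardiac fundamental untouched, where a low-order recursive
    filter would attenuate it appreciably.  ``design="butter"`` selects a
    zero-phase Butterworth of the given order instead.
    """
    fs = 1.0 / dt
    if cutoff >= fs / 2.0:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    n = signals.shape[0]
    if n < 12 * order:
        raise ValueError("series too short for the filter")
    if design == "fft":
        spectrum = np.fft.rfft(signals, axis=0)
        freqs = np.fft.rfftfreq(n, dt)
        spectrum[freqs < cutoff] = 0.0
        return np.fft.irfft(spectrum, n=n, axis=0)
    if design == "butter":
        sos = butter(order, cutoff, btype="highpass", fs=fs, output="sos")
        return sosfiltfilt(sos, signals, axis=0)
    raise ValueError(f"unknown filter design: {design!r}")


def estimate_cardiac_period(
    roi_signal: np.ndarray, dt: float, cutoff: float = 0.9
) -> float:
    """Dominant period of the high-pass band from the ROI-averaged signal."""
    x = roi_signal - roi_signal.mean()
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), dt)
    band = freqs >= cutoff
    if not band.any() or not np.any(spectrum[band] > 0):
        raise ValueError("no spectral content above the cutoff frequency")
    f_peak = freqs[band][np.argmax(spectrum[band])]
    return float(1.0 / f_peak)


def _phase_bin_count(dt: float, period: float, n_frames: int) -> int:
    """Number of distinct cardiac phases sampled by the time grid.

    The phase increment per frame is (dt mod period)/period; its best small
    rational approximation p/q means the grid revisits q distinct phases.
    Capped so each phase is hit a few times.
    """
    frac = Fraction((dt % period) / period).limit_denominator(max(2, n_frames // 8))
    return max(2, frac.denominator)


def compute_qa(
    registered_frames: np.ndarray,
    roi: np.ndarray,
    dt: float,
    cutoff: float = 0.9,
    cardiac_period: float | None = None,
    phase_bins: int | None = None,
    method: str = "REF",
) -> FunctionalMap:
    """Perfusion-weighted amplitude of the registered series.

    The per-voxel series (lung ROI only) is high-pass filtered at ``cutoff``
    (zero-phase Butterworth), frames are grouped by cardiac phase and
    averaged, the maximal and minimal phases are selected from the
    ROI-averaged filtered signal, and QA is the per-voxel difference
    between the two phase averages.  The cardiac period is estimated from
    the spectral peak of the ROI-averaged signal unless given.  With
    ``phase_bins=1`` the grouping degenerates to single-frame extrema.
    """
    T = registered_frames.shape[0]
    series = registered_frames[:, roi].astype(np.float64)  # (T, n_roi)
    filtered = highpass_filter(series, dt, cutoff)
    roi_mean = filtered.mean(axis=1)

    if cardiac_period is None:
        cardiac_period = estimate_cardiac_period(
            registered_frames[:, roi].mean(axis=1), dt, cutoff
        )
    if phase_bins is None:
        phase_bins = _phase_bin_count(dt, cardiac_period, T)

    if phase_bins <= 1:
        qa_roi = filtered[np.argmax(roi_mean)] - filtered[np.argmin(roi_mean)]
    else:
        t = np.arange(T) * dt
        phase = (t % cardiac_period) / cardiac_period
        # nearest phase-center assignment (robust when the sampling grid
        # hits the phase centers exactly up to float rounding)
        bins = np.round(phase * phase_bins).astype(int) % phase_bins
        phase_means = np.full((phase_bins, series.shape[1]), np.nan)
        for b in range(phase_bins):
            sel = bins == b
            if sel.any():
                phase_means[b] = filtered[sel].mean(axis=0)
        valid = ~np.isnan(phase_means[:, 0])
        roi_phase = phase_means.mean(axis=1)
        b_max = np.flatnonzero(valid)[np.argmax(roi_phase[valid])]
        b_min = np.flatnonzero(valid)[np.argmin(roi_phase[valid])]
        qa_roi = phase_means[b_max] - phase_means[b_min]

    values = np.zeros(roi.shape, dtype=np.float64)
    values[roi] = qa_roi
    return FunctionalMap(values=values, kind="qa", method=method, roi=roi)


def qa_from_registration(
    reg: RegistrationResult,
    roi: np.ndarray,
    series: TimeSeries,
    noise_sigma: float = 0.0,
    channels: int = 4,
    **kwargs,
) -> FunctionalMap:
    if reg.granularity != "frames":
        raise ValueError("QA needs a per-frame registered series")
    frames = reg.registered
    if noise_sigma > 0:
        frames = correct_noise_floor_frames(frames, noise_sigma, channels)
    return compute_qa(
        frames, roi, series.config.time.dt,
        cardiac_period=kwargs.pop("cardiac_period", None),
        method=reg.method, **kwargs,
    )


def guided_filter(
    values: np.ndarray, guide: np.ndarray, radius: int = 3, eps: float | None = None
) -> np.ndarray:
    """Edge-preserving guided-filter smoothing (box-filter formulation).

    ``eps`` defaults to (0.1 * guide dynamic range)^2.  Constant inputs are
    fixed points; eps -> inf approaches a plain box mean.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    I = np.asarray(guide, dtype=np.float64)
    p = np.asarray(values, dtype=np.float64)
    if eps is None:
        rng = float(I.max() - I.min())
        eps = (0.1 * rng) ** 2 if rng > 0 else 1e-8
    size = 2 * radius + 1
    box = lambda a: uniform_filter(a, size=size, mode="nearest")
    mean_I, mean_p = box(I), box(p)
    corr_I, corr_Ip = box(I * I), box(I * p)
    var_I = corr_I - mean_I**2
    cov_Ip = corr_Ip - mean_I * mean_p
    a = cov_Ip / (var_I + eps)
    b = mean_p - a * mean_I
    return box(a) * I + box(b)


def guided_filter_rvent(
    rvent: FunctionalMap, guide: np.ndarray, radius: int = 3,
    eps: float | None = None,
) -> FunctionalMap:
    """RVent* : guided-filtered RVent using the mean anatomical image."""
    values = rvent.values.copy()
    nan = np.isnan(values)
    if nan.any():
        values[nan] = 0.0
    smooth = guided_filter(values, guide, radius=radius, eps=eps)
    return FunctionalMap(
        values=smooth, kind="rvent*", method=rvent.method, roi=rvent.roi,
        invalid=rvent.invalid,
    )
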