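"""Orchestration of repeated-phantom validation experiments.

``run_experiment`` generates N phantoms (seeds base_seed + i), registers
each with the requested methods, computes the RVent/JVent/QA maps, scores
them against the ground truth and collects everything into one tidy table
(one row per phantom x registration x map x scope x metric).
"""

from __future__ import annotations

import dataclasses
import logging
import time as _time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ExperimentConfig, PhantomConfig, Tissue, config_hash
from .defects import (
    defect_mask,
    overlap_coefficient,
    paired_tests,
    relative_difference_stats,
    sensitivity_specificity,
    truth_mask,
)
from .geometry import quadrant_masks
from .quantify import (
    FunctionalMap,
    jvent_from_registration,
    qa_from_registration,
    rvent_from_registration,
)
from .registration import reference_register
from .signals import TimeSeries, generate_series

logger = logging.getLogger("synthlung")


def ventilation_truth_map(series: TimeSeries) -> np.ndarray:
    """Per-voxel reference ventilation at the normal inspiration state.

    Classes whose ventilation is in phase with the normal class carry their
    balanced expansion factor; non-expanding defects carry 0.  Delayed
    ventilation is half a respiratory period out of phase, so its realized
    expansion at the evaluated (normal-class) inspiration state is also 0.
    """
    labels = series.class_map.labels
    in_phase = np.isin(
        labels,
        [int(Tissue.VV_QV), int(Tissue.VV_COMP_QV), int(Tissue.VV_QD),
         int(Tissue.VV_QV_DELAY)],
    )
    truth = np.where(in_phase, series.expansion.E, 0.0)
    f = series.config.grid.final_factor
    return np.repeat(np.repeat(truth, f, axis=0), f, axis=1)


def measured_snr(series: TimeSeries, tolerance: float = 0.5) -> float:
    """Empirical SNR of normally ventilated voxels at the reference level.

    Uses the matched noiseless series: mean combined signal divided by the
    standard deviation of (noisy - noiseless), over the (frame, voxel)
    samples of ventilated voxels whose noiseless signal is within
    ``tolerance`` AU of the expiration base level, on the
    pre-interpolation grid.  Conditioning on the reference level keeps the
    ventilation and cardiac signal dynamics out of the noise estimate.
    """
    if series.noiseless_base is None:
        raise ValueError("series was generated without keep_noiseless=True")
    vv = np.isin(
        series.class_map.labels, [int(Tissue.VV_QV), int(Tissue.VV_COMP_QV)]
    )
    noisy = series.frames_base[:, vv].astype(np.float64)
    clean = series.noiseless_base[:, vv].astype(np.float64)
    at_ref = np.abs(clean - series.config.signal.s_exp) < tolerance
    return float(noisy[at_ref].mean() / (noisy[at_ref] - clean[at_ref]).std())


def ref_jvent_map(series: TimeSeries, bins) -> FunctionalMap:
    """JVent of the averaged inspiration ground-truth field.

    Deformation calculations run on the upscaled grid (as in series
    generation): the bin-averaged expansion matrix is upsampled, cumulated
    into the forward field, differentiated there, block-averaged back to
    the base grid and interpolated to the final matrix.  This keeps defect
    boundaries sharp in the Jacobian map.
    """
    from scipy.ndimage import zoom

    from .deformation import forward_field as _forward
    from .deformation import jacobian_determinant as _jacdet

    idx = bins.frames_in(bins.n_bins - 1)
    E_mean = np.mean([series.expansion_at(int(k)) for k in idx], axis=0)
    up = series.config.grid.upscale
    E_up = np.repeat(np.repeat(E_mean, up, axis=0), up, axis=1)
    det = _jacdet(_forward(E_up))
    h = det.shape[0] // up
    det_base = det.reshape(h, up, h, up).mean(axis=(1, 3))
    f = series.config.grid.final_factor
    values = zoom(det_base - 1.0, f, order=1, mode="nearest", grid_mode=True)
    return FunctionalMap(
        values=values, kind="jvent", method="REF", roi=series.lung_roi_final
    )


@dataclass
class PhantomAnalysis:
    """Functional maps and scores of one phantom under one registration."""

    series: TimeSeries
    maps: dict[str, FunctionalMap]
    rows: pd.DataFrame


def _tidy(rows: list[dict], **common) -> list[dict]:
    for r in rows:
        r.update(common)
    return rows


def analyze_phantom(
    config: PhantomConfig,
    registrations: tuple[str, ...] = ("REF",),
    delayed_as_positive: bool = True,
    keep_series: bool = False,
) -> PhantomAnalysis:
    """Generate, register, quantify and score a single phantom.

    Functional maps are computed on the final (interpolated) grid; defect
    masks are scored on the base grid, where the ground-truth classes are
    defined, after majority-vote downsampling.  ``delayed_as_positive``
    counts the delayed-ventilation / delayed-perfusion classes as defect
    truth in the all-classes scoring: both are half a period out of phase,
    so ventilation/perfusion maps referenced to the normal class flag them.
    """
    t0 = _time.perf_counter()
    series = generate_series(config, keep_noiseless=True)
    logger.info("phantom seed=%d generated in %.1fs", config.seed, _time.perf_counter() - t0)

    roi = series.lung_roi_final
    labels = series.labels_final
    roi_base = series.class_map.lung_roi
    labels_base = series.class_map.labels
    quads_base = quadrant_masks(series.class_map)
    quads = quads_base.upsampled(series.config.grid.final_factor)
    vent_truth = ventilation_truth_map(series)

    rows: list[dict] = []
    maps: dict[str, FunctionalMap] = {}
    for method in registrations:
        if method != "REF":
            raise NotImplementedError(
                "external registrators are driven through registration.register_series"
            )
        reg = reference_register(series)
        reg_clean = reference_register(series, frames=series.noiseless)

        from scipy.ndimage import binary_erosion

        from .quantify import estimate_background_sigma

        background = binary_erosion(
            labels == int(Tissue.BACKGROUND), iterations=2
        )
        channels = config.signal.channels
        sigma_hat = (
            estimate_background_sigma(reg.registered, background, channels)
            if config.noise
            else 0.0
        )
        rvent = rvent_from_registration(
            reg, roi, dt=config.time.dt, noise_sigma=sigma_hat, channels=channels
        )
        jvent = ref_jvent_map(series, reg.bins)
        qa = qa_from_registration(
            reg, roi, series, noise_sigma=sigma_hat, channels=channels
        )
        qa_truth = qa_from_registration(reg_clean, roi, series)
        maps.update({"rvent": rvent, "jvent": jvent, "qa": qa})

        truth_by_map = {"rvent": vent_truth, "jvent": vent_truth, "qa": qa_truth.values}
        # Parameter statistics run on the lung core: the outer ROI ring is
        # partial-volume (body signal mixed in by the interpolation chain)
        # and reflects resampling, not lung function.  Ventilation
        # statistics additionally exclude the delayed-ventilation class: it
        # sits at its own expiration during the normal-class inspiration
        # state, so both RVent and JVent see (correctly) no expansion there
        # and its defined value for this state is zero.
        core = binary_erosion(roi, iterations=2)
        vent_stats_roi = core & (labels != int(Tissue.VV_DELAY_QV))
        stats_roi_by_map = {"rvent": vent_stats_roi, "jvent": vent_stats_roi, "qa": core}
        min_truth_by_map = {
            "rvent": 0.0, "jvent": 0.0,
            "qa": 0.1 * float(np.nanpercentile(np.abs(qa_truth.values[roi]), 90)),
        }
        from .defects import downsample_mask_majority

        vd_truth_base = truth_mask(labels_base, "VD", delayed_as_positive) & roi_base
        factor = series.config.grid.final_factor
        for name, fmap in (("rvent", rvent), ("jvent", jvent), ("qa", qa)):
            common = dict(registration=method, map=name)
            stats_roi = stats_roi_by_map[name]
            rows += _tidy(
                [
                    {"scope": "lung", "metric": "mean",
                     "value": float(np.nanmean(fmap.values[stats_roi]))},
                    {"scope": "lung", "metric": "median",
                     "value": float(np.nanmedian(fmap.values[stats_roi]))},
                ],
                **common,
            )
            mask = defect_mask(fmap)
            rows += _tidy(
                [{"scope": "lung", "metric": "defect_percentage",
                  "value": mask.defect_percentage},
                 {"scope": "lung", "metric": "threshold", "value": mask.threshold}],
                **common,
            )
            rel = relative_difference_stats(
                fmap, truth_by_map[name], quads,
                min_truth=min_truth_by_map[name], roi=stats_roi,
            )
            for _, r in rel.iterrows():
                rows += _tidy(
                    [{"scope": r["quadrant"], "metric": "rel_diff_mean", "value": r["mean"]},
                     {"scope": r["quadrant"], "metric": "rel_diff_median", "value": r["median"]}],
                    **common,
                )
            mask_base = downsample_mask_majority(mask, factor, roi_base)
            rates = sensitivity_specificity(
                mask_base, labels_base, quads_base,
                delayed_as_positive=delayed_as_positive,
            )
            for _, r in rates.iterrows():
                rows += _tidy(
                    [{"scope": r["quadrant"], "metric": "tp_rate", "value": r["tp_rate"]},
                     {"scope": r["quadrant"], "metric": "tn_rate", "value": r["tn_rate"]}],
                    **common,
                )
            if name in ("rvent", "jvent"):
                rows += _tidy(
                    [{"scope": "lung", "metric": "overlap",
                      "value": overlap_coefficient(
                          mask_base.mask, vd_truth_base, roi_base)}],
                    **common,
                )
        rows += _tidy(
            [{"scope": "lung", "metric": "snr", "value": measured_snr(series)}],
            registration=method, map="series",
        )

    df = pd.DataFrame(rows)
    df.insert(0, "seed", config.seed)
    analysis = PhantomAnalysis(series=series if keep_series else None, maps=maps, rows=df)
    return analysis


def run_experiment(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Run the full repeated-phantom experiment.

    Returns the tidy metric table with one row per phantom, tagged with the
    config hash for provenance.  A failing phantom is logged and surfaced
    as rows with metric ``error``.
    """
    config = config or ExperimentConfig()
    tables = []
    for i in range(config.n_phantoms):
        cfg = dataclasses.replace(config.phantom, seed=config.base_seed + i)
        try:
            analysis = analyze_phantom(cfg, registrations=config.registrations)
            df = analysis.rows
        except Exception as exc:  # noqa: BLE001 - surfaced in the report
            logger.exception("phantom %d failed", i)
            df = pd.DataFrame(
                [{"seed": cfg.seed, "registration": "-", "map": "-",
                  "scope": "-", "metric": "error", "value": np.nan,
                  "detail": str(exc)}]
            )
        df.insert(0, "phantom", i)
        tables.append(df)
    report = pd.concat(tables, ignore_index=True)
    report.attrs["config_hash"] = config_hash(config)
    report.attrs["base_seed"] = config.base_seed
    return report


def _median_iqr(values: np.ndarray) -> str:
    v = np.asarray(values, dtype=np.float64)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return ""
    med = np.median(v)
    q1, q3 = np.percentile(v, [25, 75])
    return f"{med:.2f} ({q1:.2f}–{q3:.2f})"


def export_summary(report: pd.DataFrame, style: str = "functional") -> pd.DataFrame:
    """Median (IQR) summary tables of an experiment report.

    styles: ``functional`` (whole-lung parameter values), ``relative``
    (quadrant-wise relative differences), ``defects`` (quadrant-wise
    TP/TN rates).
    """
    if report.empty:
        return pd.DataFrame()
    if style == "functional":
        sel = report[(report["scope"] == "lung") & (report["metric"] == "mean")]
        metric_cols = ["map"]
        index = "registration"
        pivot = sel.pivot_table(
            index=index, columns=metric_cols, values="value", aggfunc=_median_iqr
        )
        return pivot
    if style == "relative":
        sel = report[report["metric"].isin(["rel_diff_mean", "rel_diff_median"])]
    elif style == "defects":
        sel = report[report["metric"].isin(["tp_rate", "tn_rate"])]
    else:
        raise ValueError(f"unknown summary style: {style!r}")
    if sel.empty:
        return pd.DataFrame()
    return sel.pivot_table(
        index="scope", columns=["map", "registration", "metric"],
        values="value", aggfunc=_median_iqr,
    )


def compare_quadrant_pairs(
    report: pd.DataFrame, map_name: str, metric: str = "rel_diff_mean",
    pairs: tuple[tuple[str, str], ...] = (("UR", "LR"), ("UL", "LL")),
) -> pd.DataFrame:
    """Omnibus + post-hoc paired tests of a metric across quadrants."""
    sel = report[(report["map"] == map_name) & (report["metric"] == metric)]
    groups = {
        q: sel[sel["scope"] == q].sort_values("phantom")["value"].to_numpy()
        for q in ("UR", "UL", "LR", "LL")
    }
    result = paired_tests(groups)
    keep = {"omnibus"} | {f"{a} vs {b}" for a, b in pairs}
    return result[result["comparison"].isin(keep)].reset_index(drop=True)
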