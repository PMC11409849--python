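"""Defect masks and validation metrics.

A ventilation (VD) or perfusion (QD) defect mask collects voxels whose
functional value falls strictly below 0.4 times the 90th percentile of the
in-ROI values (linear-interpolation percentile).  Masks are scored against
the ground-truth class map quadrant-wise: true-positive rate over the
defect-truth classes, true-negative rate over the remaining lung, relative
differences against the configured functional values, plus RMSRE,
y-profile correlation and a two-class overlap coefficient for comparing
registrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    QD_TRUTH_CLASSES,
    SEEDED_CLASSES,
    VD_TRUTH_CLASSES,
    Tissue,
)
from .geometry import QuadrantMasks
from .quantify import FunctionalMap


@dataclass
class DefectMask:
    mask: np.ndarray
    threshold: float
    kind: str  # "VD" | "QD"
    roi: np.ndarray

    @property
    def defect_percentage(self) -> float:
        """Defect voxels as a percentage of the lung ROI."""
        return 100.0 * float(self.mask.sum()) / float(self.roi.sum())


def defect_mask(
    fmap: FunctionalMap,
    kind: str | None = None,
    percentile: float = 90.0,
    factor: float = 0.4,
) -> DefectMask:
    """Threshold a functional map into a binary defect mask.

    Ties at the threshold count as non-defect (strict ``<``).  NaN voxels
    (invalid signals) are treated as defect.
    """
    roi = fmap.roi
    if not roi.any():
        raise ValueError("empty ROI")
    values = fmap.values[roi]
    if values.size < 10:
        raise ValueError("need at least 10 in-ROI voxels")
    threshold = factor * float(np.nanpercentile(values, percentile))
    mask = np.zeros(roi.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        mask[roi] = (values < threshold) | np.isnan(values)
    if kind is None:
        kind = "QD" if fmap.kind == "qa" else "VD"
    return DefectMask(mask=mask, threshold=threshold, kind=kind, roi=roi)


def downsample_mask_majority(mask: DefectMask, factor: int, roi: np.ndarray) -> DefectMask:
    """Carry a defect mask to a ``factor``-coarser grid by majority vote.

    A coarse voxel is defect when at least half of its sub-voxels are.
    """
    h, w = mask.mask.shape
    frac = mask.mask.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))
    coarse = (frac >= 0.5) & roi
    return DefectMask(mask=coarse, threshold=mask.threshold, kind=mask.kind, roi=roi)


def truth_mask(
    labels: np.ndarray, kind: str, delayed_as_positive: bool = False
) -> np.ndarray:
    """Ground-truth defect voxels for a map kind.

    Delayed classes ventilate/perfuse (half a period out of phase) and are
    truth-negative by default; ``delayed_as_positive`` flips that reading.
    """
    classes = set(VD_TRUTH_CLASSES if kind == "VD" else QD_TRUTH_CLASSES)
    if delayed_as_positive:
        classes.add(Tissue.VV_DELAY_QV if kind == "VD" else Tissue.VV_QV_DELAY)
    out = np.zeros(labels.shape, dtype=bool)
    for t in classes:
        out |= labels == t
    return out


def sensitivity_specificity(
    mask: DefectMask,
    labels: np.ndarray,
    quadrants: QuadrantMasks,
    per_class: Tissue | None = None,
    delayed_as_positive: bool = False,
) -> pd.DataFrame:
    """Quadrant-wise TP (sensitivity) and TN (specificity) rates.

    In per-class mode the quadrant ROI excludes every seeded defect class
    other than the one under test, and the positives are that class alone.
    Quadrants without truth-positive (or truth-negative) voxels report NaN
    rather than 0 so they drop out of medians.
    """
    rows = []
    for name, quad in quadrants.items():
        scope = quad & mask.roi
        if per_class is not None:
            others = np.zeros(labels.shape, dtype=bool)
            for t in SEEDED_CLASSES:
                if t != per_class:
                    others |= labels == t
            scope = scope & ~others
            positive = scope & (labels == per_class)
        else:
            positive = scope & truth_mask(labels, mask.kind, delayed_as_positive)
        negative = scope & ~positive
        tp = float(np.count_nonzero(mask.mask & positive)) / positive.sum() if positive.any() else np.nan
        tn = float(np.count_nonzero(~mask.mask & negative)) / negative.sum() if negative.any() else np.nan
        rows.append({"quadrant": name, "tp_rate": tp, "tn_rate": tn,
                     "n_positive": int(positive.sum()), "n_negative": int(negative.sum())})
    return pd.DataFrame(rows)


def rmsre(
    registered: np.ndarray, reference: np.ndarray, roi: np.ndarray
) -> float:
    """Root mean squared relative error inside the ROI.

    Voxels with zero reference signal are excluded from the mean.
    """
    reg = np.asarray(registered, dtype=np.float64)[roi]
    ref = np.asarray(reference, dtype=np.float64)[roi]
    ok = ref != 0
    if not ok.any():
        raise ValueError("reference is zero everywhere in the ROI")
    rel = (reg[ok] - ref[ok]) / ref[ok]
    return float(np.sqrt(np.mean(np.abs(rel) ** 2)))


def yprofile_correlation(
    field: np.ndarray, ref_field: np.ndarray, roi: np.ndarray
) -> float:
    """Pearson correlation of per-row mean y-displacement profiles over the ROI."""
    rows = roi.any(axis=1)
    prof = np.array([field[r][roi[r]].mean() for r in np.flatnonzero(rows)])
    ref_prof = np.array([ref_field[r][roi[r]].mean() for r in np.flatnonzero(rows)])
    if np.std(prof) == 0 or np.std(ref_prof) == 0:
        return float("nan")
    return float(np.corrcoef(prof, ref_prof)[0, 1])


def relative_difference_stats(
    fmap: FunctionalMap,
    truth_values: np.ndarray,
    quadrants: QuadrantMasks,
    min_truth: float = 0.0,
    roi: np.ndarray | None = None,
) -> pd.DataFrame:
    """Quadrant-wise mean and median of (measured - truth) / truth.

    Voxels with zero truth (non-functional classes for the map at the
    evaluated respiratory state) are excluded; ``min_truth`` additionally
    excludes near-zero truth magnitudes (relevant when the truth map is
    itself a computed, slightly noisy reference).  ``roi`` overrides the
    map's own ROI (e.g. to evaluate on the boundary-eroded lung core).
    """
    if roi is None:
        roi = fmap.roi
    rows = []
    for name, quad in quadrants.items():
        scope = (
            quad & roi & (np.abs(truth_values) > max(min_truth, 0.0))
            & (truth_values != 0) & ~np.isnan(fmap.values)
        )
        if not scope.any():
            rows.append({"quadrant": name, "mean": np.nan, "median": np.nan, "n": 0})
            continue
        rel = (fmap.values[scope] - truth_values[scope]) / truth_values[scope]
        rows.append({
            "quadrant": name,
            "mean": float(rel.mean()),
            "median": float(np.median(rel)),
            "n": int(scope.sum()),
        })
    return pd.DataFrame(rows)


def overlap_coefficient(
    pred_mask: np.ndarray, truth: np.ndarray, roi: np.ndarray
) -> float:
    """Fraction of ROI voxels on which the binary defect labels agree."""
    if not roi.any():
        raise ValueError("empty ROI")
    agree = (pred_mask == truth) & roi
    return float(agree.sum() / roi.sum())


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return "-"
    for cutoff, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p <= cutoff:
            return stars
    return "n.s."


def paired_tests(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Friedman omnibus test with post-hoc Wilcoxon signed-rank pairs.

    With exactly two groups the omnibus test is skipped and Wilcoxon is run
    directly.  Post-hoc pairs are only evaluated when the omnibus test is
    significant at ``alpha``.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=np.float64) for n in names]
    n = {a.shape[0] for a in arrays}
    if len(n) != 1:
        raise ValueError("groups must be paired (equal lengths)")
    rows = []
    if len(arrays) >= 3:
        try:
            with np.errstate(invalid="ignore"):
                stat, p = stats.friedmanchisquare(*arrays)
        except ValueError:
            stat, p = np.nan, 1.0
        if not np.isfinite(p):  # degenerate (e.g. identical) groups
            stat, p = np.nan, 1.0
        rows.append({"comparison": "omnibus", "statistic": float(stat),
                     "p_value": float(p), "stars": significance_stars(p)})
        run_posthoc = p <= alpha
    else:
        run_posthoc = True
    if run_posthoc:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = arrays[i] - arrays[j]
                if np.allclose(diff, 0):
                    stat, p = np.nan, 1.0
                else:
                    stat, p = stats.wilcoxon(arrays[i], arrays[j])
                rows.append({
                    "comparison": f"{names[i]} vs {names[j]}",
                    "statistic": float(stat), "p_value": float(p),
                    "stars": significance_stars(p),
                })
    return pd.DataFrame(rows)
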