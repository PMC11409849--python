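import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import synthlung as sl
from synthlung.config import Tissue
from synthlung.defects import (
    DefectMask,
    defect_mask,
    downsample_mask_majority,
    overlap_coefficient,
    paired_tests,
    relative_difference_stats,
    rmsre,
    sensitivity_specificity,
    significance_stars,
    truth_mask,
    yprofile_correlation,
)
from synthlung.geometry import QuadrantMasks
from synthlung.quantify import FunctionalMap


def fmap_from(values, kind="jvent"):
    values = np.asarray(values, dtype=float)
    return FunctionalMap(
        values=values, kind=kind, method="REF", roi=np.ones(values.shape, bool)
    )


class TestDefectMask:
    def test_linear_percentile_threshold_oracle(self):
        # values 1..10: 90th percentile (linear interpolation) = 9.1,
        # threshold 3.64, defect set {1, 2, 3}
        fmap = fmap_from(np.arange(1, 11, dtype=float).reshape(2, 5))
        mask = defect_mask(fmap)
        assert mask.threshold == pytest.approx(3.64)
        assert mask.mask.sum() == 3
        assert mask.defect_percentage == pytest.approx(30.0)

    def test_constant_positive_map_has_no_defects(self):
        mask = defect_mask(fmap_from(np.full((4, 4), 2.0)))
        assert not mask.mask.any()

    def test_all_zero_map_is_defect_free_under_strict_inequality(self):
        mask = defect_mask(fmap_from(np.zeros((4, 4))))
        assert mask.threshold == 0.0
        assert not mask.mask.any()

    def test_too_small_roi_rejected(self):
        with pytest.raises(ValueError):
            defect_mask(fmap_from(np.ones((3, 3))))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        values=arrays(
            float, (4, 5),
            elements=st.floats(min_value=0.01, max_value=100.0),
        ),
        scale=st.floats(min_value=0.1, max_value=50.0),
    )
    def test_threshold_scales_with_map_and_mask_is_invariant(self, values, scale):
        a = defect_mask(fmap_from(values))
        b = defect_mask(fmap_from(values * scale))
        assert b.threshold == pytest.approx(a.threshold * scale, rel=1e-9)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_majority_downsampling(self):
        fine = np.zeros((8, 8), dtype=bool)
        fine[:2, :2] = True  # full block
        fine[0, 2] = True  # quarter block
        fine[2:4, 0] = True  # half block
        mask = DefectMask(fine, 1.0, "VD", np.ones((8, 8), bool))
        coarse = downsample_mask_majority(mask, 2, np.ones((4, 4), bool))
        assert coarse.mask[0, 0] and coarse.mask[1, 0]
        assert not coarse.mask[0, 1]


def square_quadrants(n):
    h = n // 2
    q = lambda ys, xs: np.pad(
        np.ones((h, h), bool), ((ys, n - h - ys), (xs, n - h - xs))
    )
    return QuadrantMasks(UR=q(0, 0), UL=q(0, h), LR=q(h, 0), LL=q(h, h))


class TestSensitivitySpecificity:
    def make_case(self, n=8):
        labels = np.full((n, n), int(Tissue.VV_QV), dtype=np.int16)
        labels[:2, :2] = Tissue.VD_QD_LOW
        labels[5:7, 5:7] = Tissue.VD_QD_HIGH
        return labels

    def test_perfect_prediction_scores_one(self):
        labels = self.make_case()
        truth = truth_mask(labels, "VD")
        mask = DefectMask(truth, 0.1, "VD", np.ones_like(truth))
        rates = sensitivity_specificity(mask, labels, square_quadrants(8))
        present = rates.dropna(subset=["tp_rate"])
        assert (present["tp_rate"] == 1.0).all()
        assert (rates["tn_rate"] == 1.0).all()

    def test_inverted_prediction_scores_zero(self):
        labels = self.make_case()
        truth = truth_mask(labels, "VD")
        mask = DefectMask(~truth, 0.1, "VD", np.ones_like(truth))
        rates = sensitivity_specificity(mask, labels, square_quadrants(8))
        present = rates.dropna(subset=["tp_rate"])
        assert (present["tp_rate"] == 0.0).all()
        assert (rates["tn_rate"] == 0.0).all()

    def test_quadrant_without_truth_reports_nan_not_zero(self):
        labels = self.make_case()
        truth = truth_mask(labels, "VD")
        mask = DefectMask(truth, 0.1, "VD", np.ones_like(truth))
        rates = sensitivity_specificity(mask, labels, square_quadrants(8))
        by_quadrant = rates.set_index("quadrant")["tp_rate"]
        assert np.isnan(by_quadrant["UL"])  # no defect seeded there
        assert by_quadrant["UR"] == 1.0

    def test_per_class_mode_masks_other_defects(self):
        labels = self.make_case()
        # flag only the LOW cluster; HIGH must not count against it
        pred = labels == int(Tissue.VD_QD_LOW)
        mask = DefectMask(pred, 0.1, "VD", np.ones_like(pred))
        rates = sensitivity_specificity(
            mask, labels, square_quadrants(8), per_class=Tissue.VD_QD_LOW
        )
        ur = rates.set_index("quadrant").loc["UR"]
        assert ur["tp_rate"] == 1.0 and ur["tn_rate"] == 1.0

    def test_delayed_class_truth_is_configurable(self):
        labels = self.make_case()
        labels[6:8, 0:2] = Tissue.VV_DELAY_QV
        truth_neg = truth_mask(labels, "VD", delayed_as_positive=False)
        truth_pos = truth_mask(labels, "VD", delayed_as_positive=True)
        assert truth_pos.sum() - truth_neg.sum() == 4


class TestScalarMetrics:
    def test_rmsre_of_identical_images_is_zero(self, rng):
        img = rng.uniform(1, 2, (10, 10))
        roi = np.ones((10, 10), bool)
        assert rmsre(img, img, roi) == 0.0

    def test_rmsre_uniform_ten_percent(self, rng):
        img = rng.uniform(1, 2, (10, 10))
        roi = np.ones((10, 10), bool)
        assert rmsre(1.1 * img, img, roi) == pytest.approx(0.1)

    def test_rmsre_alternating_errors(self):
        ref = np.full((4, 4), 10.0)
        reg = ref.copy()
        reg[::2] *= 1.1
        reg[1::2] *= 0.9
        assert rmsre(reg, ref, np.ones((4, 4), bool)) == pytest.approx(0.1)

    def test_yprofile_self_correlation_is_one(self, rng):
        field = rng.normal(size=(12, 12)) + np.arange(12)[:, None]
        roi = np.ones((12, 12), bool)
        assert yprofile_correlation(field, field, roi) == pytest.approx(1.0)

    def test_yprofile_anticorrelation(self, rng):
        field = np.arange(12, dtype=float)[:, None] * np.ones((1, 12))
        roi = np.ones((12, 12), bool)
        assert yprofile_correlation(field, -field, roi) == pytest.approx(-1.0)

    def test_yprofile_matches_direct_pearson(self, rng):
        a = rng.normal(size=(16, 10))
        b = a + rng.normal(0, 0.5, size=(16, 10))
        roi = np.ones((16, 10), bool)
        expected = np.corrcoef(a.mean(axis=1), b.mean(axis=1))[0, 1]
        assert yprofile_correlation(a, b, roi) == pytest.approx(expected)

    def test_zero_variance_profile_is_undefined(self):
        roi = np.ones((6, 6), bool)
        assert np.isnan(yprofile_correlation(np.zeros((6, 6)), np.ones((6, 6)), roi))


class TestRelativeDifference:
    def test_perfect_map_has_zero_difference(self):
        truth = np.full((8, 8), 0.25)
        fmap = fmap_from(truth.copy())
        stats = relative_difference_stats(fmap, truth, square_quadrants(8))
        np.testing.assert_allclose(stats["mean"], 0.0)
        np.testing.assert_allclose(stats["median"], 0.0)

    def test_doubled_map_reads_plus_one(self):
        truth = np.full((8, 8), 0.2)
        fmap = fmap_from(2 * truth)
        stats = relative_difference_stats(fmap, truth, square_quadrants(8))
        np.testing.assert_allclose(stats["mean"], 1.0)

    def test_zero_truth_voxels_are_excluded(self):
        truth = np.full((8, 8), 0.25)
        truth[:4] = 0.0
        fmap = fmap_from(np.full((8, 8), 99.0))
        stats = relative_difference_stats(fmap, truth, square_quadrants(8))
        by_quad = stats.set_index("quadrant")
        assert by_quad.loc["UR", "n"] == 0
        assert by_quad.loc["LR", "n"] == 16


class TestOverlap:
    def test_identical_masks_overlap_fully(self, rng):
        roi = np.ones((10, 10), bool)
        mask = rng.random((10, 10)) > 0.7
        assert overlap_coefficient(mask, mask, roi) == 1.0

    def test_complementary_masks_do_not_overlap(self):
        roi = np.ones((6, 6), bool)
        mask = np.zeros((6, 6), bool)
        mask[:3] = True
        assert overlap_coefficient(mask, ~mask, roi) == 0.0

    def test_permutation_expectation(self, rng):
        # random shuffles of a p-fraction mask agree with probability
        # p^2 + (1-p)^2 on average
        p = 0.2
        n = 40
        roi = np.ones((n, n), bool)
        truth = np.zeros(n * n, bool)
        truth[: int(p * n * n)] = True
        truth = truth.reshape(n, n)
        values = [
            overlap_coefficient(
                rng.permutation(truth.ravel()).reshape(n, n), truth, roi
            )
            for _ in range(200)
        ]
        assert np.mean(values) == pytest.approx(p**2 + (1 - p) ** 2, abs=0.01)


class TestPairedTests:
    def test_identical_groups_are_not_significant(self, rng):
        base = rng.normal(size=20)
        out = paired_tests({"a": base, "b": base.copy(), "c": base.copy()})
        omnibus = out[out.comparison == "omnibus"].iloc[0]
        assert omnibus["p_value"] > 0.05
        assert len(out) == 1  # no post-hoc rows

    def test_large_shift_detected(self, rng):
        base = rng.normal(size=20)
        out = paired_tests({"a": base, "b": base + 0.01 * rng.normal(size=20),
                            "c": base + 5.0})
        omnibus = out[out.comparison == "omnibus"].iloc[0]
        assert omnibus["p_value"] < 0.05
        ac = out[out.comparison == "a vs c"].iloc[0]
        assert ac["p_value"] < 0.05 and ac["stars"] != "n.s."

    def test_two_groups_skip_omnibus(self, rng):
        base = rng.normal(size=15)
        out = paired_tests({"a": base, "b": base + 2.0})
        assert "omnibus" not in set(out["comparison"])
        assert out.iloc[0]["p_value"] < 0.05

    def test_unpaired_groups_rejected(self):
        with pytest.raises(ValueError):
            paired_tests({"a": np.zeros(5), "b": np.zeros(6)})

    def test_star_conventions(self):
        assert significance_stars(0.3) == "n.s."
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(5e-5) == "****"
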