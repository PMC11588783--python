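import numpy as np
import pytest
from scipy.spatial.distance import cdist

from usborder.borders import BorderSplit, extract_border
from usborder.io import LabelVolume
from usborder.metrics import (UndefinedMetricError, aggregate,
                              compute_class_weights, dice, hd95, nsd,
                              reference_border_fractions, tp_decomposition)


def surface_of(mask):
    from scipy import ndimage
    er = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(mask.ndim, 1),
                                border_value=0)
    return mask & ~er


def brute_surface_distances(pred, gt, spacing):
    """O(n^2) all-pairs oracle for the pooled symmetric surface distances."""
    sp = np.argwhere(surface_of(pred)) * np.asarray(spacing)
    sg = np.argwhere(surface_of(gt)) * np.asarray(spacing)
    d = cdist(sp, sg)
    return np.concatenate([d.min(axis=1), d.min(axis=0)])


def random_mask(rng, shape, p=0.2):
    from scipy import ndimage
    m = ndimage.gaussian_filter(rng.normal(size=shape), 2) > rng.normal(0, 0.2)
    if not m.any():
        m.flat[0] = True
    return m


class TestDice:
    def test_identical(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True
        b[0, 2:] = True
        b[1, :2] = True
        assert dice(a, b) == 0.5

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), bool)
        assert dice(z, z) == 1.0


class TestSurfaceMetrics:
    def test_identical_masks(self):
        m = np.zeros((6, 6), bool)
        m[2:5, 2:5] = True
        assert hd95(m, m) == 0.0
        assert nsd(m, m, tau=1.0) == 1.0

    def test_two_voxels_axis_distance(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[4, 2] = True
        b[4, 5] = True
        assert hd95(a, b, (1.0, 1.0)) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[4, 2] = True
        b[4, 5] = True
        assert hd95(a, b, (1.0, 0.5)) == pytest.approx(1.5)

    def test_nsd_zero_when_far(self):
        a = np.zeros((12, 12), bool)
        b = np.zeros((12, 12), bool)
        a[0, 0] = True
        b[11, 11] = True
        assert nsd(a, b, tau=2.0) == 0.0

    def test_nsd_constructed_distances(self):
        # pred surface voxels at distances {0,1,2,5} from gt surface (a line)
        gt = np.zeros((12, 12), bool)
        gt[2, 2:6] = True
        pred = np.zeros((12, 12), bool)
        pred[2, 2] = True   # 0
        pred[3, 3] = True   # 1
        pred[4, 4] = True   # 2
        pred[7, 5] = True   # 5
        pooled = brute_surface_distances(pred, gt, (1, 1))
        expected = (pooled <= 2.0).mean()
        assert nsd(pred, gt, (1, 1), tau=2.0) == pytest.approx(expected)
        assert expected == pytest.approx((pooled <= 2).sum() / pooled.size)

    @pytest.mark.parametrize("ndim,seed", [(2, 0), (2, 5), (3, 1), (3, 7)])
    def test_oracle_equivalence_random_masks(self, ndim, seed):
        rng = np.random.default_rng(seed)
        shape = (16, 16) if ndim == 2 else (12, 12, 12)
        spacing = tuple(rng.uniform(0.5, 2.0, ndim))
        a, b = random_mask(rng, shape), random_mask(rng, shape)
        pooled = brute_surface_distances(a, b, spacing)
        assert hd95(a, b, spacing) == pytest.approx(np.percentile(pooled, 95),
                                                    abs=1e-9)
        tau = float(np.median(pooled)) + 1e-9
        assert nsd(a, b, spacing, tau) == pytest.approx((pooled <= tau).mean(),
                                                        abs=1e-12)

    def test_empty_mask_is_error_not_zero(self):
        m = np.zeros((4, 4), bool)
        full = ~m
        with pytest.raises(UndefinedMetricError):
            hd95(m, full)
        with pytest.raises(UndefinedMetricError):
            nsd(full, m)


def make_split(border, distinct):
    return BorderSplit(1, border, distinct, border & ~distinct)


class TestReferenceFractions:
    def test_edges_everywhere(self):
        border = np.zeros((6, 6), bool)
        border[2, 1:5] = True
        assert reference_border_fractions(make_split(border, border.copy())) \
            == (100.0, 0.0)

    def test_analytic_60_40(self):
        border = np.zeros((8, 8), bool)
        border[1:7, 1:7] = True
        border[2:6, 2:6] = False
        idx = np.argwhere(border)
        distinct = np.zeros_like(border)
        distinct[tuple(idx[:12].T)] = True
        d, c = reference_border_fractions(make_split(border, distinct))
        assert (d, c) == (60.0, 40.0)
        assert d + c == 100.0

    def test_empty_border_error(self):
        z = np.zeros((4, 4), bool)
        with pytest.raises(UndefinedMetricError):
            reference_border_fractions(make_split(z, z))


class TestTPDecomposition:
    def test_perfect_prediction_all_distinct(self):
        border = np.zeros((8, 8), bool)
        border[3, 1:7] = True
        row = tp_decomposition(make_split(border, border.copy()), border, 0)
        assert (row.tp_total_pct, row.tp_distinct_pct, row.tp_completed_pct) \
            == (100.0, 100.0, 0.0)

    def test_empty_prediction_zeros_with_warning(self, caplog):
        border = np.zeros((8, 8), bool)
        border[3, 1:7] = True
        with caplog.at_level("WARNING", logger="usborder"):
            row = tp_decomposition(make_split(border, border.copy()),
                                   np.zeros((8, 8), bool), 1)
        assert (row.tp_total_pct, row.tp_distinct_pct, row.tp_completed_pct) \
            == (0.0, 0.0, 0.0)
        assert caplog.records

    def test_enumerated_80_50_30(self):
        # 20-voxel ring, 12 distinct / 8 completed; prediction covers
        # 10 distinct + 6 completed voxels => (80, 50, 30) at tolerance 0
        border = np.zeros((8, 8), bool)
        border[1:7, 1:7] = True
        border[2:6, 2:6] = False
        idx = np.argwhere(border)
        distinct = np.zeros_like(border)
        distinct[tuple(idx[:12].T)] = True
        pred = np.zeros_like(border)
        pred[tuple(idx[:10].T)] = True      # 10 distinct voxels
        pred[tuple(idx[12:18].T)] = True    # 6 completed voxels
        row = tp_decomposition(make_split(border, distinct), pred, 0)
        assert (row.tp_total_pct, row.tp_distinct_pct, row.tp_completed_pct) \
            == (80.0, 50.0, 30.0)

    def test_chebyshev_tolerance_matches_brute_force(self):
        rng = np.random.default_rng(4)
        from conftest import random_label_map
        lab = LabelVolume(random_label_map(rng, (20, 20)))
        border = extract_border(lab, 1)
        distinct = border & (rng.random((20, 20)) < 0.5)
        pred = rng.random((20, 20)) < 0.05
        for tol in (0, 1, 2):
            row = tp_decomposition(make_split(border, distinct), pred, tol)
            # brute force: a border voxel is TP iff some pred voxel within
            # Chebyshev distance tol
            bidx, pidx = np.argwhere(border), np.argwhere(pred)
            if len(pidx):
                cheb = np.abs(bidx[:, None, :] - pidx[None, :, :]).max(-1)
                tp = (cheb.min(1) <= tol)
            else:
                tp = np.zeros(len(bidx), bool)
            expected_total = 100.0 * tp.sum() / len(bidx)
            assert row.tp_total_pct == pytest.approx(expected_total, abs=1e-12)
            assert row.tp_distinct_pct + row.tp_completed_pct \
                == pytest.approx(row.tp_total_pct, abs=1e-12)


class TestAggregate:
    def test_single_row(self):
        out = aggregate([{"v": 5.0}])
        assert out["v"] == (5.0, 0.0)

    def test_sample_sd(self):
        out = aggregate([{"v": 80.0}, {"v": 84.0}])
        assert out["v"][0] == 82.0
        assert out["v"][1] == pytest.approx(2.8284271, abs=1e-6)

    def test_mean_additivity(self):
        rng = np.random.default_rng(8)
        rows = []
        for _ in range(10):
            d, c = rng.random() * 60, rng.random() * 40
            rows.append({"tp_distinct_pct": d, "tp_completed_pct": c,
                         "tp_total_pct": d + c})
        out = aggregate(rows)
        assert out["tp_distinct_pct"][0] + out["tp_completed_pct"][0] \
            == pytest.approx(out["tp_total_pct"][0], abs=1e-12)


class TestClassWeights:
    def test_equal_frequencies(self):
        lab = np.repeat(np.arange(4), 4).reshape(4, 4)
        w = compute_class_weights([LabelVolume(lab)], 4)
        np.testing.assert_allclose(w, 0.25)

    def test_analytic_inverse_freq(self):
        lab = np.array([[0, 0, 1, 2]] * 2)
        w = compute_class_weights([LabelVolume(lab)], 3)
        np.testing.assert_allclose(w, [0.2, 0.4, 0.4])

    def test_normalization_random(self):
        rng = np.random.default_rng(10)
        labs = [LabelVolume(rng.integers(0, 5, (12, 12))) for _ in range(3)]
        w = compute_class_weights(labs, 5)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_absent_class_named(self):
        with pytest.raises(ValueError, match="2"):
            compute_class_weights([LabelVolume(np.zeros((4, 4), int))], 3)
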