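import numpy as np
import pytest

from usborder.borders import BorderSplit
from usborder.cam import (CAMTarget, TargetError, cam_for_split, compute_cam,
                          perturb_and_compare, render_overlay, scalar_target)
from usborder.models import FixedLinearModel, SmallUNet


def fd_cam(model, img, target, layer, eps=1e-3):
    """Finite-difference oracle: perturb every activation entry, re-run the
    head, pool the gradients, combine with activations, ReLU."""
    model.forward(img)
    A0 = model.activations(layer).copy()
    grads = np.zeros_like(A0)
    it = np.nditer(A0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        up, down = A0.copy(), A0.copy()
        up[i] += eps
        down[i] -= eps
        s_up = scalar_target(model.forward_from(layer, up), target)
        s_dn = scalar_target(model.forward_from(layer, down), target)
        grads[i] = (s_up - s_dn) / (2 * eps)
    w = grads.mean(axis=tuple(range(1, grads.ndim)))
    return np.maximum(np.tensordot(w, A0, axes=1), 0.0)


@pytest.fixture
def img8():
    return np.random.default_rng(3).random((8, 8))


@pytest.fixture
def pixel_set():
    m = np.zeros((8, 8), bool)
    m[2:5, 3:6] = True
    return m


class TestScalarTarget:
    def test_single_pixel(self):
        scores = np.arange(2 * 3 * 3, dtype=float).reshape(2, 3, 3)
        m = np.zeros((3, 3), bool)
        m[1, 2] = True
        assert scalar_target(scores, CAMTarget(1, m)) == scores[1, 1, 2]

    def test_two_pixels_sum(self):
        scores = np.zeros((2, 2, 2))
        scores[0, 0, 0], scores[0, 1, 1] = 1.5, 2.5
        m = np.eye(2, dtype=bool)
        assert scalar_target(scores, CAMTarget(0, m)) == 4.0

    def test_full_grid(self):
        rng = np.random.default_rng(1)
        scores = rng.random((3, 4, 4))
        assert scalar_target(scores, CAMTarget(2, np.ones((4, 4), bool))) \
            == pytest.approx(scores[2].sum())

    def test_empty_set_rejected(self):
        with pytest.raises(TargetError):
            CAMTarget(0, np.zeros((3, 3), bool))


class TestComputeCAM:
    def test_linear_head_closed_form(self, img8, pixel_set):
        # with an identity-style (1x1 conv) head, pooled gradients reduce
        # to head weight x mean of the pixel-set indicator
        model = FixedLinearModel(n_features=4, n_classes=3, seed=1)
        target = CAMTarget(1, pixel_set)
        cam = compute_cam(model, img8, target, "features")
        A = model.activations("features")
        w_closed = model.head.w[1, :, 0, 0] * pixel_set.mean()
        np.testing.assert_allclose(cam.weights, w_closed, atol=1e-14)
        np.testing.assert_allclose(
            cam.map, np.maximum(np.tensordot(w_closed, A, axes=1), 0))

    def test_disconnected_class_zero_cam(self, img8, pixel_set):
        model = FixedLinearModel(n_features=4, n_classes=3, seed=1)
        model.head.w[2] = 0.0  # class 2 no longer depends on the features
        cam = compute_cam(model, img8, CAMTarget(2, pixel_set), "features")
        assert not cam.map.any()

    @pytest.mark.parametrize("layer", ["features", "scores"])
    def test_fd_oracle_fixed_linear(self, img8, pixel_set, layer):
        model = FixedLinearModel(n_features=4, n_classes=3, seed=1)
        target = CAMTarget(1, pixel_set)
        cam = compute_cam(model, img8, target, layer)
        fd = fd_cam(model, img8, target, layer)
        scale = max(np.abs(fd).max(), 1e-12)
        assert np.abs(cam.map - fd).max() / scale < 1e-3

    @pytest.mark.parametrize("layer", ["features", "enc2", "enc1"])
    def test_fd_oracle_small_unet(self, img8, pixel_set, layer):
        model = SmallUNet(n_classes=3, width=4, seed=1)
        target = CAMTarget(1, pixel_set)
        cam = compute_cam(model, img8, target, layer)
        fd = fd_cam(model, img8, target, layer)
        scale = max(np.abs(fd).max(), 1e-12)
        assert np.abs(cam.map - fd).max() / scale < 1e-3

    def test_nonnegativity_and_reconstruction(self, img8, pixel_set):
        model = SmallUNet(n_classes=3, width=4, seed=2)
        cam = compute_cam(model, img8, CAMTarget(1, pixel_set))
        assert cam.map.min() >= 0
        np.testing.assert_array_equal(cam.map, cam.reconstruct())

    def test_pre_relu_set_additivity(self, img8):
        # by linearity of differentiation, pre-ReLU maps add over disjoint sets
        model = SmallUNet(n_classes=3, width=4, seed=2)
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[1:4, 1:4] = True
        b[5:7, 5:7] = True
        maps = {}
        for name, m in (("a", a), ("b", b), ("ab", a | b)):
            cam = compute_cam(model, img8, CAMTarget(1, m))
            maps[name] = np.tensordot(cam.weights, cam.activations, axes=1)
        np.testing.assert_allclose(maps["ab"], maps["a"] + maps["b"], atol=1e-12)

    def test_unknown_layer_lists_available(self, img8, pixel_set):
        from usborder.models import AdapterError
        model = SmallUNet(n_classes=3, width=4, seed=0)
        with pytest.raises(AdapterError, match="features"):
            compute_cam(model, img8, CAMTarget(0, pixel_set), "bottleneck7")

    def test_upsampled_resolution(self, img8, pixel_set):
        model = SmallUNet(n_classes=3, width=4, seed=0)
        cam = compute_cam(model, img8, CAMTarget(1, pixel_set), "enc2")
        assert cam.map.shape == (4, 4)
        assert cam.upsampled.shape == (8, 8)


class TestCamForSplit:
    def _split(self, distinct, completed):
        return BorderSplit(1, distinct | completed, distinct, completed)

    def test_empty_completed_flagged_missing(self, img8, caplog):
        d = np.zeros((8, 8), bool)
        d[2, 2:6] = True
        model = SmallUNet(n_classes=3, width=4, seed=0)
        with caplog.at_level("WARNING", logger="usborder"):
            dm, cm = cam_for_split(model, img8, self._split(d, np.zeros_like(d)))
        assert dm is not None and cm is None
        assert caplog.records

    def test_deterministic_repeat(self, img8):
        d = np.zeros((8, 8), bool)
        c = np.zeros((8, 8), bool)
        d[2, 2:6] = True
        c[5, 2:6] = True
        model = SmallUNet(n_classes=3, width=4, seed=0)
        r1 = cam_for_split(model, img8, self._split(d, c))
        r2 = cam_for_split(model, img8, self._split(d, c))
        np.testing.assert_array_equal(r1[0].map, r2[0].map)
        np.testing.assert_array_equal(r1[1].map, r2[1].map)


class TestPerturbAndCompare:
    def test_identity_perturbations(self, img8, pixel_set):
        model = SmallUNet(n_classes=3, width=4, seed=0)
        target = CAMTarget(1, pixel_set)
        r = perturb_and_compare(model, img8, target, "features",
                                "gaussian_noise", {"sd": 0.0})
        assert r.similarity == pytest.approx(1.0)
        r = perturb_and_compare(model, img8, target, "features",
                                "contrast_scale", {"factor": 1.0})
        assert r.similarity == pytest.approx(1.0)
        assert r.baseline_region_mean == pytest.approx(r.perturbed_region_mean)

    def test_invalid_params(self, img8, pixel_set):
        model = SmallUNet(n_classes=3, width=4, seed=0)
        target = CAMTarget(1, pixel_set)
        with pytest.raises(ValueError):
            perturb_and_compare(model, img8, target, "features",
                                "zero_patch", {"patch": ((0, 12), (0, 4))})
        with pytest.raises(ValueError):
            perturb_and_compare(model, img8, target, "features",
                                "gaussian_noise", {"sd": -1})


class TestRenderOverlay:
    def test_zero_cam_writes_grayscale(self, tmp_path, img8, pixel_set):
        model = FixedLinearModel(n_features=4, n_classes=3, seed=1)
        model.head.w[2] = 0.0
        cam = compute_cam(model, img8, CAMTarget(2, pixel_set), "features")
        out = tmp_path / "overlay.png"
        render_overlay(img8, cam, out, contour_mask=pixel_set)
        assert out.stat().st_size > 0

    def test_3d_triplanar(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = rng.random((6, 8, 8))
        from usborder.cam import CAMMap
        heat = rng.random((6, 8, 8))
        cam = CAMMap(heat, np.ones(1), heat[None], "features",
                     CAMTarget(1, np.ones((6, 8, 8), bool)), upsampled=heat)
        out = tmp_path / "tri.png"
        render_overlay(vol, cam, out)
        assert out.stat().st_size > 0
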