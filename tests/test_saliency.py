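"""Attribution methods vs closed forms and double-loop oracles."""

import numpy as np
import pytest

from wsunet.saliency import (
    IGConfig,
    OcclusionConfig,
    SaliencyMap,
    grad_cam,
    integrated_gradients,
    normalise_joint,
    occlusion_sensitivity,
    upsample_nearest,
    wsunet_voxel_map,
)

# ---------------------------------------------------------------------------
# toy handles implementing the model contract
# ---------------------------------------------------------------------------


class StubActivationModel:
    """Fixed activations/gradients at a fake layer, for Grad-CAM checks."""

    def __init__(self, acts, grads):
        self._acts, self._grads = acts, grads

    def activations_and_gradients(self, x, layer_index):
        return self._acts, self._grads


class LinearModel:
    """f(x) = sum(w * x); gradient is w everywhere."""

    def __init__(self, w):
        self.w = w

    def predict_image(self, x):
        return (x[..., 0] * self.w).sum(axis=(1, 2))

    def input_gradient(self, x):
        return np.broadcast_to(self.w[..., None], x.shape).copy()


class ConstantModel:
    def predict_image(self, x):
        return np.full(len(x), 0.42)


class BrightPixelModel:
    """Indicator of one specific bright pixel."""

    def __init__(self, i, j):
        self.i, self.j = i, j

    def predict_image(self, x):
        return (x[:, self.i, self.j, 0] > 0.5).astype(float)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------


def test_gradcam_single_channel_closed_form(rng):
    acts = rng.random((1, 4, 4, 1))
    grads = np.full((1, 4, 4, 1), 0.3)
    smap = grad_cam(StubActivationModel(acts, grads), 0, np.zeros((8, 8)))
    np.testing.assert_allclose(smap.values, 0.3 * acts[0, ..., 0])

    neg = grad_cam(StubActivationModel(acts, -grads), 0, np.zeros((8, 8)))
    np.testing.assert_array_equal(neg.values, np.zeros((4, 4)))


def test_gradcam_matches_double_loop_oracle(rng):
    acts = rng.normal(size=(1, 4, 4, 3))
    grads = rng.normal(size=(1, 4, 4, 3))
    smap = grad_cam(StubActivationModel(acts, grads), 0, np.zeros((8, 8)))
    # oracle: loop over channels and pixels explicitly
    expected = np.zeros((4, 4))
    for c in range(3):
        w = 0.0
        for i in range(4):
            for j in range(4):
                w += grads[0, i, j, c]
        w /= 16.0
        for i in range(4):
            for j in range(4):
                expected[i, j] += w * acts[0, i, j, c]
    expected = np.maximum(expected, 0.0)
    np.testing.assert_allclose(smap.values, expected, rtol=1e-6)
    assert np.all(smap.values >= 0)


def test_gradcam_on_real_model_is_nonnegative(tiny_scnn, rng):
    patch = rng.normal(size=(16, 16)).astype(np.float32)
    smap = grad_cam(tiny_scnn, tiny_scnn.conv_layer_index(3), patch)
    assert np.all(smap.values >= 0)
    assert smap.native_shape == smap.values.shape


def test_gradcam_rejects_non_spatial_layer(tiny_scnn, rng):
    dense_idx = [i.index for i in tiny_scnn.layer_catalogue if i.kind == "dense"][0]
    with pytest.raises(ValueError):
        grad_cam(tiny_scnn, dense_idx, rng.normal(size=(16, 16)))


# ---------------------------------------------------------------------------
# nearest-neighbour upsampling
# ---------------------------------------------------------------------------


def test_upsample_nearest_integer_factor_and_identity(rng):
    src = SaliencyMap(np.array([[1.0, 2.0], [3.0, 4.0]]), "gradcam")
    up = upsample_nearest(src, (4, 4))
    np.testing.assert_array_equal(
        up.values, np.kron(src.values, np.ones((2, 2))))
    same = upsample_nearest(src, (2, 2))
    np.testing.assert_array_equal(same.values, src.values)
    with pytest.raises(ValueError):
        upsample_nearest(src, (1, 1))


def test_upsample_nearest_preserves_distinct_values(rng):
    src = SaliencyMap(rng.random((16, 16)), "gradcam")
    up = upsample_nearest(src, (128, 128))
    assert set(np.unique(up.values)) == set(np.unique(src.values))
    assert up.values.shape == (128, 128)


# ---------------------------------------------------------------------------
# integrated gradients
# ---------------------------------------------------------------------------


def test_ig_zero_path_when_baseline_equals_input(rng):
    x = rng.random((6, 6)).astype(np.float32)
    model = LinearModel(rng.normal(size=(6, 6)))
    smap = integrated_gradients(model, x, IGConfig(steps=5, baseline=x))
    np.testing.assert_array_equal(smap.values, np.zeros((6, 6)))


@pytest.mark.parametrize("steps", [1, 3, 10])
def test_ig_exact_for_linear_model_any_step_count(steps, rng):
    w = rng.normal(size=(6, 6))
    x = rng.random((6, 6)).astype(np.float64)
    smap = integrated_gradients(LinearModel(w), x, IGConfig(steps=steps))
    np.testing.assert_allclose(smap.values, w * x, rtol=1e-6)


def test_ig_completeness_on_nonlinear_model(tiny_wsunet, rng):
    """At a fine discretisation the attributions sum to f(x) - f(baseline)."""
    x = rng.normal(scale=0.5, size=(16, 16)).astype(np.float32)
    smap = integrated_gradients(tiny_wsunet, x, IGConfig(steps=200))
    fx = tiny_wsunet.predict_image(x[None, ..., None])[0]
    f0 = tiny_wsunet.predict_image(np.zeros((1, 16, 16, 1), np.float32))[0]
    assert smap.values.sum() == pytest.approx(fx - f0, rel=0.01)


def test_ig_baseline_shape_mismatch(rng):
    with pytest.raises(ValueError):
        integrated_gradients(LinearModel(np.ones((4, 4))), rng.random((4, 4)),
                             IGConfig(baseline=np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# occlusion sensitivity
# ---------------------------------------------------------------------------


def test_occlusion_zero_for_constant_model(rng):
    smap = occlusion_sensitivity(ConstantModel(), rng.random((12, 12)),
                                 OcclusionConfig(window_width=4))
    np.testing.assert_array_equal(smap.values, np.zeros((12, 12)))


def test_occlusion_localises_decisive_pixel():
    x = np.zeros((12, 12), dtype=np.float32)
    x[5, 7] = 1.0
    model = BrightPixelModel(5, 7)
    smap = occlusion_sensitivity(model, x, OcclusionConfig(window_width=3))
    covering = smap.values[4:7, 6:9]  # windows touching (5,7) lose the score
    assert np.all(covering > 0)
    outside = smap.values.copy()
    outside[3:8, 5:10] = 0
    np.testing.assert_array_equal(outside[:3], 0)
    assert smap.values[0, 0] == 0.0


def test_occlusion_full_window_gives_uniform_map(rng):
    x = rng.random((8, 8)).astype(np.float32)
    model = LinearModel(np.ones((8, 8)))
    smap = occlusion_sensitivity(model, x, OcclusionConfig(window_width=8))
    assert len(np.unique(smap.values)) == 1


def test_occlusion_uncovered_pixels_are_exactly_zero(rng):
    x = rng.random((10, 10)).astype(np.float32)
    model = LinearModel(np.ones((10, 10)))
    smap = occlusion_sensitivity(model, x, OcclusionConfig(window_width=2, stride=4))
    # top-left corners at 0, 4, 8: rows/cols 2, 3, 6, 7 are never covered
    for k in (2, 3, 6, 7):
        np.testing.assert_array_equal(smap.values[k], 0)
        np.testing.assert_array_equal(smap.values[:, k], 0)


def test_occlusion_window_too_large(rng):
    with pytest.raises(ValueError):
        occlusion_sensitivity(ConstantModel(), rng.random((8, 8)),
                              OcclusionConfig(window_width=9))


# ---------------------------------------------------------------------------
# joint normalisation and the intrinsic voxel map
# ---------------------------------------------------------------------------


def test_normalise_joint_uses_pooled_range():
    a = SaliencyMap(np.array([[0.0, 1.0]]), "gradcam")
    b = SaliencyMap(np.array([[2.0, 0.5]]), "gradcam")
    na, nb = normalise_joint([a, b])
    np.testing.assert_allclose(na.values, [[0.0, 0.5]])
    np.testing.assert_allclose(nb.values, [[1.0, 0.25]])
    pooled = np.concatenate([na.values.ravel(), nb.values.ravel()])
    assert pooled.min() == 0.0 and pooled.max() == 1.0

    single = SaliencyMap(np.array([[0.0, 0.3, 1.0]]), "occlusion")
    (ns,) = normalise_joint([single])
    np.testing.assert_array_equal(ns.values, single.values)


def test_normalise_joint_constant_warns_and_zeroes():
    flat = SaliencyMap(np.full((3, 3), 0.7), "occlusion")
    with pytest.warns(UserWarning):
        (out,) = normalise_joint([flat])
    np.testing.assert_array_equal(out.values, np.zeros((3, 3)))


def test_normalise_joint_rejects_mixed_methods():
    with pytest.raises(ValueError):
        normalise_joint([SaliencyMap(np.zeros((2, 2)), "gradcam"),
                         SaliencyMap(np.zeros((2, 2)), "occlusion")])


def test_wsunet_voxel_map_max_equals_image_prediction(tiny_wsunet, rng):
    """Causal faithfulness: the explanation's maximum IS the decision."""
    patch = rng.normal(size=(16, 16)).astype(np.float32)
    smap = wsunet_voxel_map(tiny_wsunet, patch)
    pred = tiny_wsunet.predict_image(patch[None, ..., None])[0]
    assert smap.values.max() == pred
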