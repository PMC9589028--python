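"""Cascade architecture contracts."""

import numpy as np
import pytest

import ssdr.autodiff as ad
from ssdr.autodiff import Tensor
from ssdr.containers import MultiViewInput
from ssdr.geometry import make_scheme
from ssdr.network import (CascadeConfig, CascadeModel, UNetConfig,
                          patched_apply, receptive_field_half)

DESK = CascadeConfig(stage1=UNetConfig(depth=2, base_features=4),
                     stage2=UNetConfig(depth=2, base_features=4),
                     patch_z=None)


def _mvi(rng, n_views, shape, scale="low"):
    scheme = make_scheme(n_views, 180.0)
    ch = rng.random((n_views,) + shape).astype(np.float32)
    return MultiViewInput(ch, scheme, scale)


def test_unet_config_validation():
    with pytest.raises(ValueError):
        UNetConfig(depth=0)
    with pytest.raises(ValueError):
        UNetConfig(kernel=4)
    with pytest.raises(ValueError):
        UNetConfig(fusion="max")
    assert UNetConfig(depth=3, base_features=4).widths == (4, 8, 16, 32)


def test_zero_input_gives_zero_features_and_output(rng):
    """All biases start at zero, so an all-zero multi-view input flows
    through lift, U-Net and head as exactly zero."""
    model = CascadeModel(DESK, seed=0)
    mvi = MultiViewInput(np.zeros((8, 16, 16, 16), dtype=np.float32),
                         make_scheme(8, 180.0), "low")
    pred = model.stage1_predict(mvi)
    assert np.all(pred.data == 0.0)


def test_lift_feature_count_independent_of_views(rng):
    model = CascadeModel(DESK, seed=0)
    for n in (4, 6, 8, 10, 12):
        with ad.no_grad():
            feats = model.lift1(Tensor(_mvi(rng, n, (16, 16, 16)).channels))
        assert feats.data.shape == (4, 16, 16, 16)


def test_lift_positive_homogeneity_without_bias(rng):
    """With zero biases the lift (conv + min fusion) is positively
    homogeneous: doubling the input doubles the fused features."""
    model = CascadeModel(DESK, seed=1)
    x = _mvi(rng, 4, (8, 8, 8)).channels
    with ad.no_grad():
        f1 = model.lift1(Tensor(x)).data
        f2 = model.lift1(Tensor(2.0 * x)).data
    np.testing.assert_allclose(f2, 2.0 * f1, atol=1e-5)


def test_parameter_count_independent_of_view_count():
    m = CascadeModel(DESK, seed=0)
    n_params = m.parameter_count()
    rng = np.random.default_rng(0)
    for n in (4, 12):
        m.stage1_predict(_mvi(rng, n, (16, 16, 16)))
    assert m.parameter_count() == n_params


@pytest.mark.parametrize("n_views", [4, 6, 8, 10, 12])
def test_forward_shape_contracts_all_view_counts(rng, n_views):
    model = CascadeModel(DESK, seed=0)
    low = _mvi(rng, n_views, (8, 8, 8))
    y1 = model.stage1_predict(low)
    assert y1.data.shape == (8, 8, 8)
    assert y1.data.min() >= 0.0 and y1.data.max() <= 1.0
    high = _mvi(rng, n_views, (16, 16, 16), "high")
    with ad.no_grad():
        up = ad.resample_linear(Tensor(y1.data), (16, 16, 16)).data
    from ssdr.containers import Volume
    y2 = model.stage2_predict(high, Volume(up))
    assert y2.data.shape == (16, 16, 16)
    assert y2.data.min() >= 0.0 and y2.data.max() <= 1.0


def test_stage_predict_deterministic(rng):
    model = CascadeModel(DESK, seed=0)
    mvi = _mvi(rng, 8, (16, 16, 16))
    a = model.stage1_predict(mvi).data
    b = model.stage1_predict(mvi).data
    np.testing.assert_array_equal(a, b)


def test_stage2_grid_mismatch_raises(rng):
    from ssdr.containers import Volume
    model = CascadeModel(DESK, seed=0)
    high = _mvi(rng, 4, (16, 16, 16), "high")
    with pytest.raises(ValueError):
        model.stage2_predict(high, Volume(np.zeros((8, 8, 8))))


def test_refiner_with_identity_cascade_input_correlates_with_y1(rng):
    """Setting the y1 pass-through tap to identity makes the refiner
    output correlate positively with the coarse prediction."""
    model = CascadeModel(DESK, seed=0)
    c = model.config.stage2.kernel // 2
    model.lift2_y1.w.data[:, 0, c, c, c] = 1.0
    from ssdr.containers import Volume
    high = _mvi(rng, 4, (16, 16, 16), "high")
    y1 = rng.random((16, 16, 16)).astype(np.float32)
    out = model.stage2_predict(high, Volume(y1)).data
    base = model.stage2_predict(high, Volume(np.zeros_like(y1))).data
    diff = (out - base).ravel()
    r = np.corrcoef(diff, y1.ravel())[0, 1]
    assert r > 0


def test_checkpoint_roundtrip(tmp_path, rng):
    model = CascadeModel(DESK, seed=0)
    mvi = _mvi(rng, 4, (16, 16, 16))
    before = model.stage1_predict(mvi).data
    path = tmp_path / "cascade.ckpt"
    model.save(path)
    loaded = CascadeModel.load(path)
    after = loaded.stage1_predict(mvi).data
    np.testing.assert_array_equal(before, after)


# ---------------------------------------------------------------------------
# Z-slab patching
# ---------------------------------------------------------------------------

def _net_fn(model):
    def fn(channels):
        with ad.no_grad():
            return model.forward_stage1(Tensor(channels)).data
    return fn


def test_patched_apply_single_patch_is_identity(rng):
    model = CascadeModel(DESK, seed=0)
    ch = rng.random((4, 16, 16, 16)).astype(np.float32)
    direct = _net_fn(model)(ch)
    patched = patched_apply(_net_fn(model), ch, patch_z=16, multiple=4)
    np.testing.assert_array_equal(direct, patched)


def test_patched_apply_restitches_to_original_z(rng):
    model = CascadeModel(DESK, seed=0)
    ch = rng.random((4, 16, 16, 64)).astype(np.float32)
    out = patched_apply(_net_fn(model), ch, patch_z=32, multiple=4)
    assert out.shape == (16, 16, 64)


def test_patched_apply_zero_input_zero_output():
    model = CascadeModel(DESK, seed=0)
    ch = np.zeros((4, 16, 16, 32), dtype=np.float32)
    out = patched_apply(_net_fn(model), ch, patch_z=16, multiple=4)
    assert np.all(out == 0.0)


def test_patched_apply_divisibility_error():
    with pytest.raises(ValueError):
        patched_apply(lambda c: c[0], np.zeros((1, 8, 8, 16)), patch_z=6,
                      multiple=4)


def test_patched_agrees_on_interior_voxels(rng):
    """Patched and direct application agree on voxels at least one
    receptive-field half-width away from slab boundaries."""
    cfg = CascadeConfig(stage1=UNetConfig(depth=1, base_features=2),
                        stage2=UNetConfig(depth=1, base_features=2),
                        patch_z=None)
    model = CascadeModel(cfg, seed=0)
    band = receptive_field_half(cfg.stage1)
    ch = rng.random((2, 16, 16, 64)).astype(np.float32)
    direct = _net_fn(model)(ch)
    patched = patched_apply(_net_fn(model), ch, patch_z=32, multiple=2)
    for z0 in (0, 32):
        interior = slice(z0 + band, z0 + 32 - band)
        assert interior.stop > interior.start, "band leaves no interior"
        np.testing.assert_allclose(direct[:, :, interior],
                                   patched[:, :, interior], atol=1e-5)
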