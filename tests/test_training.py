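"""Projection-consistency loss and self-supervised optimisation."""

import numpy as np
import pytest

from ssdr.containers import Projection, ProjectionSet
from ssdr.geometry import forward_mip, make_scheme, project_set
from ssdr.network import CascadeConfig, UNetConfig
from ssdr.phantom import PhantomSpec, make_dataset
from ssdr.training import (LossRecord, SelfSupervisedReconstruction,
                           TrainConfig, TrainingDiverged, build_cases,
                           projection_loss, train_cascade, train_stage)

TINY_NET = CascadeConfig(stage1=UNetConfig(depth=1, base_features=2),
                         stage2=UNetConfig(depth=1, base_features=2),
                         patch_z=None)
TINY_SPEC = PhantomSpec(grid_shape=(16, 16, 16), n_branches=2,
                        radius_range=(0.8, 1.6),
                        aneurysm_radius_range=(1.0, 1.6), n_aneurysms=0,
                        background_noise_sd=0.0)


def tiny_train_config(**kw):
    base = dict(lr_stage1=2e-3, lr_stage2=2e-3, lr_decay=0.98,
                epochs_stage1=2, epochs_stage2=2, seed=0)
    base.update(kw)
    return TrainConfig(**base)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def test_loss_zero_when_projections_match(rng):
    vol = rng.random((16, 16, 16))
    scheme = make_scheme(8, 180.0)
    ps = project_set(vol, scheme)
    assert projection_loss(vol, ps, reduction="sum") == 0.0
    assert projection_loss(vol, ps, reduction="mean") == 0.0


def test_loss_single_pixel_closed_form():
    """One view, one pixel off by 0.1, sum reduction -> 0.1^2 = 0.01."""
    pred = np.zeros((8, 8, 8))
    target = np.zeros((8, 8))
    target[3, 5] = 0.1
    ps = ProjectionSet([Projection(target, 180.0)])
    assert projection_loss(pred, ps, reduction="sum") == pytest.approx(0.01)
    assert projection_loss(pred, ps, reduction="mean") == pytest.approx(
        0.01 / 64)


def test_loss_matches_exhaustive_recomputation(rng):
    vol = rng.random((16, 16, 16))
    angles = [45.0, 90.0, 180.0]
    targets = [rng.random((16, 16)) for _ in angles]
    ps = ProjectionSet.from_arrays(targets, angles)
    got = projection_loss(vol, ps, reduction="sum")
    expected = 0.0
    for angle, target in zip(angles, targets):
        mip = forward_mip(vol, angle).image
        for u in range(16):
            for v in range(16):
                expected += (mip[u, v] - target[u, v]) ** 2
    assert got == pytest.approx(expected, abs=1e-6)


def test_loss_view_permutation_symmetry(rng):
    vol = rng.random((12, 12, 12))
    angles = [60.0, 120.0, 180.0]
    targets = [rng.random((12, 12)) for _ in angles]
    fwd = projection_loss(vol, ProjectionSet.from_arrays(targets, angles),
                          reduction="sum")
    rev = projection_loss(vol, ProjectionSet.from_arrays(targets[::-1],
                                                         angles[::-1]),
                          reduction="sum")
    assert fwd == pytest.approx(rev, rel=1e-12)


def test_loss_differentiable_path_matches_numpy_path(rng):
    import ssdr.autodiff as ad
    vol = rng.random((12, 12, 12)).astype(np.float32)
    scheme = make_scheme(4, 180.0)
    targets = [rng.random((12, 12)).astype(np.float32) for _ in scheme]
    ps = ProjectionSet.from_arrays(targets, list(scheme))
    scalar = projection_loss(vol, ps, reduction="mean")
    t = projection_loss(ad.Tensor(vol, requires_grad=True), ps,
                        reduction="mean")
    assert float(t.data) == pytest.approx(scalar, rel=1e-5)


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _cases(n, seed=0):
    vols = make_dataset(n, TINY_SPEC, seed)
    scheme = make_scheme(8, 180.0)
    psets = [project_set(v, scheme) for v in vols]
    return build_cases(psets, scheme, (8, 8, 8), (16, 16, 16)), scheme


def test_train_stage_reduces_loss_and_records():
    from ssdr.network import CascadeModel
    cases, _ = _cases(1)
    model = CascadeModel(TINY_NET, seed=0)
    rec = train_stage(model, cases, tiny_train_config(), 1, epochs=30)
    assert isinstance(rec, LossRecord)
    assert len(rec.train) == 30 and len(rec.val) == 30
    assert all(np.isfinite(v) and v >= 0 for v in rec.train + rec.val)
    assert rec.train[-1] < rec.train[0]
    assert 0 <= rec.best_epoch < 30


def test_decay_one_keeps_lr_constant():
    from ssdr.network import CascadeModel
    cases, _ = _cases(1)
    model = CascadeModel(TINY_NET, seed=0)
    rec = train_stage(model, cases, tiny_train_config(lr_decay=1.0), 1,
                      epochs=4)
    assert rec.lr_history == [2e-3] * 4


def test_training_is_deterministic():
    results = []
    for _ in range(2):
        cases, _ = _cases(2)
        from ssdr.network import CascadeModel
        model = CascadeModel(TINY_NET, seed=0)
        rec = train_stage(model, cases, tiny_train_config(), 1, epochs=3)
        results.append((tuple(rec.train), tuple(rec.val)))
    assert results[0] == results[1]


def test_nan_loss_aborts_with_epoch_diagnostic():
    from ssdr.network import CascadeModel
    cases, _ = _cases(1)
    model = CascadeModel(TINY_NET, seed=0)
    model.unet1.head.b.data[:] = np.nan
    with pytest.raises(TrainingDiverged, match="epoch 0"):
        train_stage(model, cases, tiny_train_config(), 1, epochs=2)


def test_train_cascade_returns_both_records():
    vols = make_dataset(2, TINY_SPEC, 3)
    scheme = make_scheme(4, 180.0)
    psets = [project_set(v, scheme) for v in vols]
    cfg = tiny_train_config(epochs_stage1=1, epochs_stage2=1)
    model, records = train_cascade(psets, scheme, (8, 8, 8), (16, 16, 16),
                                   TINY_NET, cfg)
    assert set(records) == {"stage1", "stage2"}


def test_freeze_keeps_stage1_weights_bit_identical():
    vols = make_dataset(2, TINY_SPEC, 3)
    scheme = make_scheme(4, 180.0)
    psets = [project_set(v, scheme) for v in vols]
    cfg = tiny_train_config(epochs_stage1=2, epochs_stage2=2,
                            freeze_stage1=True)
    model, _ = train_cascade(psets, scheme, (8, 8, 8), (16, 16, 16),
                             TINY_NET, cfg, mode="stage1")
    snap = [p.data.copy() for p in model.stage1_params]
    from ssdr.training import _attach_y1, train_stage as ts
    cases = build_cases(psets, scheme, (8, 8, 8), (16, 16, 16))
    _attach_y1(model, cases)
    ts(model, cases, cfg, 2, epochs=2)
    for before, p in zip(snap, model.stage1_params):
        np.testing.assert_array_equal(before, p.data)


def test_ablation_modes_train_expected_stages():
    vols = make_dataset(1, TINY_SPEC, 3)
    scheme = make_scheme(4, 180.0)
    psets = [project_set(v, scheme) for v in vols]
    cfg = tiny_train_config(epochs_stage1=1, epochs_stage2=1)
    _, rec1 = train_cascade(psets, scheme, (8, 8, 8), (16, 16, 16),
                            TINY_NET, cfg, mode="stage1")
    assert set(rec1) == {"stage1"}
    _, rec2 = train_cascade(psets, scheme, (8, 8, 8), (16, 16, 16),
                            TINY_NET, cfg, mode="stage2")
    assert set(rec2) == {"stage2"}


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

def test_fit_reconstruct_and_summary():
    vols = make_dataset(2, TINY_SPEC, 11)
    scheme = make_scheme(4, 180.0)
    model = SelfSupervisedReconstruction.from_volumes(
        vols, scheme, low_shape=(8, 8, 8), high_shape=(16, 16, 16),
        cascade_config=TINY_NET,
        train_config=tiny_train_config(epochs_stage1=2, epochs_stage2=1))
    fit = model.fit(seed=0)
    rec = fit.reconstruct(project_set(vols[0], scheme))
    assert rec.data.shape == (16, 16, 16)
    assert rec.data.min() >= 0.0 and rec.data.max() <= 1.0
    text = fit.summary()
    assert "views" in text and "stage1" in text and "stage2" in text
    df = fit.loss_dataframe()
    assert set(df.columns) == {"stage", "epoch", "train_loss", "val_loss"}
    ax = fit.plot_loss()
    assert ax.get_ylabel() == "projection-consistency loss"
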