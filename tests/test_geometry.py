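"""Parallel-beam MIP projection and back-projection geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssdr.containers import AngleScheme, Projection
from ssdr.geometry import (backproject_view, crop_common_support, forward_mip,
                           make_scheme, project_set)


def brute_force_axis_mip(vol, angle):
    """Exhaustive-loop axis max for the two clinical axis-aligned views.

    Follows the package convention: pixel (u, v) of the anteroposterior
    view (180) is max over y of vol[u, y, v]; the lateral view (90) is
    the 90-degree in-plane rotation of the grid followed by the same
    axis max.
    """
    nx, ny, nz = vol.shape
    out = np.zeros((nx, nz))
    for u in range(nx):
        for v in range(nz):
            best = -np.inf
            for y in range(ny):
                s = vol[u, y, v] if angle == 180 else vol[y, ny - 1 - u, v]
                if s > best:
                    best = s
            out[u, v] = best
    return out


@pytest.mark.parametrize("angle", [90.0, 180.0])
def test_mip_equals_brute_force_axis_max(rng, angle):
    for _ in range(5):
        vol = rng.random((16, 16, 16))
        got = forward_mip(vol, angle).image
        np.testing.assert_array_equal(got, brute_force_axis_mip(vol, angle))


def test_mip_of_zero_volume_is_zero():
    p = forward_mip(np.zeros((8, 8, 8)), 123.4)
    assert p.image.shape == (8, 8)
    assert np.all(p.image == 0)


def test_single_bright_voxel_lands_at_documented_pixel():
    vol = np.zeros((8, 8, 8))
    vol[2, 3, 4] = 1.0
    p = forward_mip(vol, 180.0).image
    assert p[2, 4] == 1.0 and p.sum() == 1.0
    p90 = forward_mip(vol, 90.0).image
    # after the exact quarter turn the voxel sits at row ny-1-y = 4
    assert p90[4, 4] == 1.0 and p90.sum() == 1.0


def test_empty_volume_raises():
    with pytest.raises(ValueError):
        forward_mip(np.zeros((0, 0, 0)), 90.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(angle=st.floats(1.0, 360.0), scale=st.floats(0.0, 2.0))
def test_mip_positive_homogeneity(angle, scale):
    vol = np.random.default_rng(7).random((12, 12, 12))
    p1 = forward_mip(vol, angle).image
    p2 = forward_mip(scale * vol, angle).image
    np.testing.assert_allclose(p2, scale * p1, atol=1e-10)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(angle=st.floats(1.0, 360.0))
def test_mip_monotonicity(angle):
    r = np.random.default_rng(8)
    v1 = r.random((12, 12, 12))
    v2 = v1 + r.random((12, 12, 12))
    p1 = forward_mip(v1, angle).image
    p2 = forward_mip(v2, angle).image
    assert np.all(p2 >= p1 - 1e-12)


def test_project_set_contract(rng):
    vol = rng.random((16, 16, 16))
    one = AngleScheme((180.0,), 180.0)
    ps = project_set(vol, one)
    assert len(ps) == 1
    np.testing.assert_array_equal(ps[0].image, forward_mip(vol, 180.0).image)
    scheme = make_scheme(8, 180.0)
    ps8 = project_set(vol, scheme)
    assert len(ps8) == 8
    assert ps8.angles == sorted(ps8.angles)
    half = project_set(0.5 * vol, scheme)
    for a, b in zip(ps8, half):
        np.testing.assert_allclose(b.image, 0.5 * a.image, atol=1e-12)


def test_axis_aligned_backprojection_replicates_slabs(rng):
    img = rng.random((16, 16))
    vol = backproject_view(Projection(img, 180.0), depth=16).data
    for y in range(16):
        np.testing.assert_array_equal(vol[:, y, :], img)


def test_axis_aligned_roundtrip_identity(rng):
    for angle in (90.0, 180.0):
        img = rng.random((16, 16))
        p = Projection(img, angle)
        back = backproject_view(p, depth=16)
        p2 = forward_mip(back, angle)
        np.testing.assert_array_equal(p2.image, img)


def test_oblique_roundtrip_within_tolerance(smooth_blob):
    p = forward_mip(smooth_blob, 45.0)
    back = backproject_view(p, depth=32)
    p2 = forward_mip(back, 45.0)
    assert np.abs(p2.image - p.image).max() <= 0.05


def test_crop_common_support_geometry():
    vol = np.ones((64, 64, 4))
    cropped = crop_common_support(vol).data
    assert cropped[0, 0, 1] == 0.0            # corner outside cylinder
    assert cropped[32, 32, 1] == 1.0          # center untouched
    frac_zeroed = 1.0 - cropped[:, :, 0].mean()
    assert abs(frac_zeroed - (1.0 - np.pi / 4.0)) <= 0.02


def test_make_scheme_angle_lists():
    s4 = make_scheme(4, 180.0)
    assert s4.angles == (45.0, 90.0, 135.0, 180.0)
    s8 = make_scheme(8, 180.0)
    assert len(s8) == 8
    assert 90.0 in s8.angles and 180.0 in s8.angles
    np.testing.assert_allclose(np.diff(s8.angles), 22.5)
    s45 = make_scheme(8, 45.0)
    assert max(s45.angles) - min(s45.angles) <= 45.0
    with pytest.raises(ValueError):
        make_scheme(1, 180.0)


def test_mip_gradient_matches_finite_difference(rng):
    """Autodiff subgradient of sum(MIP) against central differences at
    non-tied maxima."""
    import ssdr.autodiff as ad
    vol = rng.permutation(4096).reshape(16, 16, 16) / 4096.0  # all distinct
    t = ad.Tensor(vol, requires_grad=True)
    ad.mip(t, 67.0).sum().backward()
    eps = 1e-3
    for _ in range(10):
        i, j, k = rng.integers(0, 16, 3)
        vp, vm = vol.copy(), vol.copy()
        vp[i, j, k] += eps
        vm[i, j, k] -= eps
        fd = (forward_mip(vp, 67.0).image.sum()
              - forward_mip(vm, 67.0).image.sum()) / (2 * eps)
        assert abs(fd - t.grad[i, j, k]) <= 1e-4 + 1e-2 * abs(fd)
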