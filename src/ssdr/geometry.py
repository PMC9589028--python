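"""Parallel-beam projection geometry.

The forward model is a rotational parallel-beam *maximum intensity
projection* (MIP): for a view angle ``theta`` every detector pixel takes
the maximum voxel value along the parallel ray through it, the rays
being orthogonal to the detector plane. The clinical cone beam is
approximated by this parallel geometry.

Implementation: the volume is rotated about its Z axis so that the rays
become the +Y grid axis, then a plain axis max is taken. Multiples of
90 degrees are pure index permutations and therefore exact; oblique
angles use bilinear in-plane resampling. The same rotation "plans"
(gather indices + weights) are reused by the autodiff engine so the
projector is differentiable with the gradient routed to the first
maximal sample of each ray.
"""

from __future__ import annotations

import functools

import numpy as np

from .containers import AngleScheme, Projection, ProjectionSet, Volume, as_volume_array

__all__ = [
    "forward_mip",
    "project_set",
    "backproject_view",
    "crop_common_support",
    "make_scheme",
    "rotation_plan",
    "apply_rotation",
    "apply_rotation_adjoint",
]


# ---------------------------------------------------------------------------
# rotation machinery
# ---------------------------------------------------------------------------

def _is_multiple_of_90(alpha: float) -> bool:
    return abs(alpha / 90.0 - round(alpha / 90.0)) < 1e-9


@functools.lru_cache(maxsize=256)
def rotation_plan(shape_xy: tuple[int, int], alpha_deg: float):
    """Plan for rotating the X-Y plane by ``alpha_deg`` (counterclockwise).

    Returns ``("exact", k)`` for multiples of 90 degrees (k quarter
    turns), else ``("bilinear", idx, w)`` where the rotated plane,
    flattened, is ``sum_k w[k] * plane.ravel()[idx[k]]`` (4 neighbours,
    out-of-grid samples get weight 0).
    """
    nx, ny = shape_xy
    alpha = alpha_deg % 360.0
    if _is_multiple_of_90(alpha):
        return ("exact", int(round(alpha / 90.0)) % 4)
    if nx != ny:
        raise ValueError(
            f"oblique rotation needs a square X-Y grid, got {shape_xy}"
        )
    c = (nx - 1) / 2.0
    a = np.deg2rad(alpha)
    cos_a, sin_a = np.cos(a), np.sin(a)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    u = ii - c
    v = jj - c
    # inverse rotation R(-alpha) of the output coordinate
    src_x = cos_a * u + sin_a * v + c
    src_y = -sin_a * u + cos_a * v + c
    x0 = np.floor(src_x).astype(np.int64)
    y0 = np.floor(src_y).astype(np.int64)
    fx = src_x - x0
    fy = src_y - y0
    idx_list, w_list = [], []
    for dx, wx in ((0, 1.0 - fx), (1, fx)):
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            xs = x0 + dx
            ys = y0 + dy
            valid = (xs >= 0) & (xs < nx) & (ys >= 0) & (ys < ny)
            w = np.where(valid, wx * wy, 0.0)
            flat = np.where(valid, xs * ny + ys, 0)
            idx_list.append(flat.ravel())
            w_list.append(w.ravel())
    idx = np.stack(idx_list, axis=0)
    w = np.stack(w_list, axis=0)
    return ("bilinear", idx, w)


def _rot90_xy(vol: np.ndarray, k: int) -> np.ndarray:
    """Exact quarter-turn rotation of (X, Y, ...) axes, counterclockwise
    in the package's coordinate convention."""
    k = k % 4
    out = vol
    for _ in range(k):
        out = out.transpose(1, 0, *range(2, out.ndim))[::-1]
    return out


def apply_rotation(vol: np.ndarray, alpha_deg: float) -> np.ndarray:
    """Rotate a volume (X, Y, Z) about Z by ``alpha_deg``."""
    plan = rotation_plan(vol.shape[:2], float(alpha_deg))
    if plan[0] == "exact":
        return np.ascontiguousarray(_rot90_xy(vol, plan[1]))
    _, idx, w = plan
    nx, ny = vol.shape[:2]
    rest = vol.shape[2:]
    flat = vol.reshape(nx * ny, -1)
    out = np.zeros((nx * ny, flat.shape[1]), dtype=vol.dtype)
    for k in range(idx.shape[0]):
        out += w[k][:, None].astype(vol.dtype) * flat[idx[k]]
    return out.reshape((nx, ny) + rest)


def apply_rotation_adjoint(grad: np.ndarray, alpha_deg: float) -> np.ndarray:
    """Adjoint (transpose) of :func:`apply_rotation` for gradient flow."""
    plan = rotation_plan(grad.shape[:2], float(alpha_deg))
    if plan[0] == "exact":
        # inverse of a pure permutation
        return np.ascontiguousarray(_rot90_xy(grad, (-plan[1]) % 4))
    _, idx, w = plan
    nx, ny = grad.shape[:2]
    rest = grad.shape[2:]
    gflat = grad.reshape(nx * ny, -1)
    out = np.zeros_like(gflat)
    for k in range(idx.shape[0]):
        np.add.at(out, idx[k], w[k][:, None].astype(grad.dtype) * gflat)
    return out.reshape((nx, ny) + rest)


# ---------------------------------------------------------------------------
# forward / backward projection
# ---------------------------------------------------------------------------

def forward_mip(volume, angle: float) -> Projection:
    """Parallel-beam maximum intensity projection at ``angle`` degrees.

    The returned image is indexed (U, V) = (in-plane detector
    coordinate, Z). For the anteroposterior view (180 deg) pixel (u, v)
    is ``max_y volume[u, y, v]``.
    """
    vol = as_volume_array(volume)
    if vol.size == 0:
        raise ValueError("cannot project an empty volume")
    rotated = apply_rotation(vol, 180.0 - float(angle))
    return Projection(rotated.max(axis=1), float(angle))


def project_set(volume, scheme: AngleScheme) -> ProjectionSet:
    """One MIP per scheme angle, order preserved."""
    return ProjectionSet([forward_mip(volume, a) for a in scheme])


def backproject_view(projection: Projection, angle: float | None = None,
                     depth: int | None = None) -> Volume:
    """Smear back-projection: replicate a view ``depth`` times along its
    ray direction, then resample onto the canonical grid.

    For oblique angles the replicated slab is rotated back with bilinear
    interpolation, which requires ``depth == U`` (square X-Y grid).
    """
    angle = projection.angle if angle is None else float(angle)
    img = np.asarray(projection.image)
    n_u, n_v = img.shape
    depth = n_u if depth is None else int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    slab = np.broadcast_to(img[:, None, :], (n_u, depth, n_v)).copy()
    alpha = 180.0 - angle
    if _is_multiple_of_90(alpha):
        out = apply_rotation(slab, -alpha)
    else:
        if depth != n_u:
            raise ValueError(
                "oblique back-projection needs depth == detector width"
            )
        out = apply_rotation(slab, -alpha)
    return Volume(np.clip(out, 0.0, 1.0))


def support_mask(shape_xy: tuple[int, int]) -> np.ndarray:
    """Boolean in-plane mask of the inscribed cylinder (the 3D space
    swept by a full 180-degree rotation)."""
    nx, ny = shape_xy
    r = min(nx, ny) / 2.0
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return (ii - cx) ** 2 + (jj - cy) ** 2 <= r * r


def crop_common_support(volume, scheme: AngleScheme | None = None) -> Volume:
    """Zero voxels outside the inscribed cylinder of the X-Y plane.

    This is the 3D space formed under a full 180-degree sweep; it is
    applied to every view channel so that all channels live in the same
    support regardless of the scheme (``scheme`` is accepted for API
    symmetry but the cropped region is always the 180-degree support).
    """
    vol = as_volume_array(volume)
    mask = support_mask(vol.shape[:2])
    return Volume(vol * mask[:, :, None])


def make_scheme(n_views: int, coverage_span: float = 180.0) -> AngleScheme:
    """Evenly spaced angles ``span * k / n`` for ``k = 1..n``.

    For a 180-degree span and even ``n`` the set contains both the
    lateral (90) and anteroposterior (180) views, which are part of
    every supervision group.
    """
    n_views = int(n_views)
    if n_views < 2:
        raise ValueError("a scheme needs at least 2 views")
    if not (0.0 < coverage_span <= 360.0):
        raise ValueError("coverage_span must be in (0, 360] degrees")
    angles = tuple(coverage_span * k / n_views for k in range(1, n_views + 1))
    return AngleScheme(angles, coverage_span)
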