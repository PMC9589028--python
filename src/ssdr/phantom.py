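"""Synthetic cerebrovascular phantoms.

Real 3D-DSA volumes are bright, sparse tubular trees on a dark
background (well over 90% of voxels are background). The generator
emulates exactly that: seeded random-walk centerlines with optional
bifurcations, smoothed and rasterised as anti-aliased tubes with a
one-voxel linear intensity ramp at the wall, optional spheroidal
aneurysm bulges attached to a centerline point, and additive clipped
Gaussian background noise. Identical spec + seed gives a bit-identical
volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import Volume

__all__ = [
    "PhantomSpec",
    "PhantomConfigError",
    "Polyline",
    "generate_tree",
    "rasterize",
    "make_dataset",
]


class PhantomConfigError(ValueError):
    """Invalid phantom configuration; the message names the field."""


@dataclass(frozen=True)
class PhantomSpec:
    """Controls for one synthetic vascular volume.

    Defaults describe a desk-scale 64^3 phantom: a handful of vessels
    with radii of one to a few voxels, one aneurysm, and faint
    background noise, keeping the foreground fraction well under 10%.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    n_branches: int = 4
    radius_range: tuple[float, float] = (1.2, 2.6)
    bifurcation_prob: float = 0.3
    n_aneurysms: int = 1
    aneurysm_radius_range: tuple[float, float] = (2.0, 3.5)
    intensity_range: tuple[float, float] = (0.7, 1.0)
    background_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        g = tuple(int(s) for s in self.grid_shape)
        if len(g) != 3 or any(s < 4 for s in g):
            raise PhantomConfigError(f"grid_shape must be 3 ints >= 4, got {self.grid_shape}")
        object.__setattr__(self, "grid_shape", g)
        if int(self.n_branches) < 1:
            raise PhantomConfigError(f"n_branches must be >= 1, got {self.n_branches}")
        object.__setattr__(self, "n_branches", int(self.n_branches))
        lo, hi = self.radius_range
        if not (0 < lo < hi):
            raise PhantomConfigError(f"radius_range needs 0 < min < max, got {self.radius_range}")
        if not (0.0 <= self.bifurcation_prob <= 1.0):
            raise PhantomConfigError(f"bifurcation_prob must be in [0, 1], got {self.bifurcation_prob}")
        if int(self.n_aneurysms) < 0:
            raise PhantomConfigError(f"n_aneurysms must be >= 0, got {self.n_aneurysms}")
        object.__setattr__(self, "n_aneurysms", int(self.n_aneurysms))
        alo, ahi = self.aneurysm_radius_range
        if not (0 < alo <= ahi):
            raise PhantomConfigError(
                f"aneurysm_radius_range needs 0 < min <= max, got {self.aneurysm_radius_range}")
        ilo, ihi = self.intensity_range
        if not (0.0 < ilo <= ihi <= 1.0):
            raise PhantomConfigError(
                f"intensity_range must lie in (0, 1], got {self.intensity_range}")
        if self.background_noise_sd < 0:
            raise PhantomConfigError(
                f"background_noise_sd must be >= 0, got {self.background_noise_sd}")
        max_r = max(hi, ahi if self.n_aneurysms else 0.0)
        if max_r > min(g) / 2.0:
            raise PhantomConfigError(
                f"radius_range/aneurysm_radius_range: radius {max_r} exceeds half "
                f"the smallest grid dimension {min(g) / 2.0}")


@dataclass(frozen=True)
class Polyline:
    """A centerline: ordered points (M, 3) with per-point radii (M,)."""

    points: np.ndarray
    radii: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        rad = np.asarray(self.radii, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or rad.shape != (pts.shape[0],):
            raise ValueError("Polyline needs points (M, 3) and radii (M,)")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "radii", rad)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _walk(rng, start, direction, spec: PhantomSpec, r_start: float,
          max_steps: int) -> tuple[np.ndarray, np.ndarray]:
    grid = np.asarray(spec.grid_shape, dtype=np.float64)
    pos = np.asarray(start, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    d /= np.linalg.norm(d)
    pts = [pos.copy()]
    for _ in range(max_steps):
        d = d + 0.25 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pos = pos + d
        if np.any(pos < 0.5) or np.any(pos > grid - 1.5):
            break
        pts.append(pos.copy())
    pts = np.asarray(pts)
    # taper from the starting radius towards the minimum radius
    t = np.linspace(0.0, 1.0, len(pts))
    radii = r_start + (spec.radius_range[0] - r_start) * t
    return pts, radii


def _smooth_polyline(pts: np.ndarray, radii: np.ndarray,
                     grid: tuple[int, int, int]) -> Polyline:
    if len(pts) >= 5:
        pts = gaussian_filter1d(pts, sigma=1.5, axis=0, mode="nearest")
    hi = np.asarray(grid, dtype=np.float64) - 1.0
    pts = np.clip(pts, 0.0, hi)
    return Polyline(pts, radii)


def generate_tree(spec: PhantomSpec) -> list[Polyline]:
    """Seeded random-walk vessel tree; returns >= 1 smoothed polylines."""
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(spec.grid_shape, dtype=np.float64)
    max_steps = int(3 * max(spec.grid_shape))
    polylines: list[Polyline] = []
    raw: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(spec.n_branches):
        # start near a random face, heading inward
        face = rng.integers(0, 6)
        start = rng.uniform(0.15, 0.85, size=3) * (grid - 1)
        axis, side = face // 2, face % 2
        start[axis] = 1.0 if side == 0 else grid[axis] - 2.0
        inward = np.zeros(3)
        inward[axis] = 1.0 if side == 0 else -1.0
        direction = inward + 0.5 * rng.normal(size=3)
        r0 = rng.uniform(*spec.radius_range)
        raw.append(_walk(rng, start, direction, spec, r0, max_steps))
    # one optional child per primary branch
    for pts, radii in list(raw):
        if len(pts) >= 8 and rng.uniform() < spec.bifurcation_prob:
            k = rng.integers(3, len(pts) - 3)
            tangent = pts[min(k + 1, len(pts) - 1)] - pts[k - 1]
            child_dir = tangent + 1.5 * _random_unit(rng)
            r_child = float(np.clip(0.7 * radii[k], spec.radius_range[0],
                                    spec.radius_range[1]))
            raw.append(_walk(rng, pts[k], child_dir, spec, r_child,
                             max_steps // 2))
    for pts, radii in raw:
        polylines.append(_smooth_polyline(pts, radii, spec.grid_shape))
    return polylines


def _stamp_ball(vol: np.ndarray, center: np.ndarray, radius: float,
                intensity: float):
    """Max-combine an anti-aliased ball (1-voxel linear wall ramp)."""
    lo = np.maximum(np.floor(center - radius - 1.0).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius + 2.0).astype(int),
                    np.asarray(vol.shape))
    if np.any(lo >= hi):
        return
    xs = np.arange(lo[0], hi[0])
    ys = np.arange(lo[1], hi[1])
    zs = np.arange(lo[2], hi[2])
    dx = (xs - center[0])[:, None, None]
    dy = (ys - center[1])[None, :, None]
    dz = (zs - center[2])[None, None, :]
    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
    val = intensity * np.clip(radius + 1.0 - dist, 0.0, 1.0)
    region = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(region, val, out=region)


def _resample_polyline(poly: Polyline, step: float = 0.5):
    pts, radii = poly.points, poly.radii
    if len(pts) < 2:
        return pts, radii
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    if arclen[-1] <= 0:
        return pts[:1], radii[:1]
    s = np.arange(0.0, arclen[-1] + step, step)
    out_pts = np.stack([np.interp(s, arclen, pts[:, k]) for k in range(3)], axis=1)
    out_r = np.interp(s, arclen, radii)
    return out_pts, out_r


def rasterize(centerlines: list[Polyline], spec: PhantomSpec) -> Volume:
    """Render centerlines as bright tubes, add aneurysms and noise.

    Deterministic given the spec (intensities, aneurysm placement and
    noise use a stream derived from ``spec.seed``).
    """
    rng = np.random.default_rng((int(spec.seed), 0xA5))
    vol = np.zeros(spec.grid_shape, dtype=np.float32)
    for poly in centerlines:
        if np.any(poly.radii > min(spec.grid_shape) / 2.0):
            raise PhantomConfigError(
                "radius_range: centerline radius exceeds half the smallest "
                "grid dimension")
        intensity = rng.uniform(*spec.intensity_range)
        pts, radii = _resample_polyline(poly)
        for p, r in zip(pts, radii):
            _stamp_ball(vol, p, float(r), float(intensity))
    if centerlines:
        for _ in range(spec.n_aneurysms):
            poly = centerlines[rng.integers(0, len(centerlines))]
            k = rng.integers(0, len(poly.points))
            center = poly.points[k] + 0.8 * poly.radii[k] * _random_unit(rng)
            radius = rng.uniform(*spec.aneurysm_radius_range)
            intensity = rng.uniform(*spec.intensity_range)
            _stamp_ball(vol, center, float(radius), float(intensity))
    if spec.background_noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.background_noise_sd,
                               size=spec.grid_shape).astype(np.float32)
    return Volume(np.clip(vol, 0.0, 1.0))


def make_dataset(n_cases: int, spec: PhantomSpec, base_seed: int) -> list[Volume]:
    """``n_cases`` deterministic phantoms with seeds base_seed + i."""
    if int(n_cases) < 1:
        raise PhantomConfigError(f"n_cases must be >= 1, got {n_cases}")
    out = []
    for i in range(int(n_cases)):
        s = replace(spec, seed=int(base_seed) + i)
        out.append(rasterize(generate_tree(s), s))
    return out
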