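"""Multi-view preprocessing.

Raw 2D views are min-max normalised to [0, 1], linearly resized to the
working resolution of each stage, back-projected along their viewing
angle into a 3D channel ("dimensional ascending"), and cropped to the
common 180-degree support so every channel lives in the same space.
The learned per-channel feature lift lives in :mod:`ssdr.network`.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import zoom

from .containers import AngleScheme, MultiViewInput, Projection, ProjectionSet
from .geometry import backproject_view, crop_common_support

__all__ = ["normalize_views", "resize_views", "assemble", "resize_image"]


def normalize_views(raw_projections: ProjectionSet) -> ProjectionSet:
    """Min-max scale every view to [0, 1]; a constant image maps to zeros."""
    out = []
    for p in raw_projections:
        img = np.asarray(p.image, dtype=np.float64)
        if not np.all(np.isfinite(img)):
            raise ValueError("projection contains NaN/Inf")
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = (img - lo) / (hi - lo)
        else:
            img = np.zeros_like(img)
        out.append(Projection(img, p.angle))
    return ProjectionSet(out)


def resize_image(image: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Linear-interpolation resize of a 2D image (aspect change allowed)."""
    image = np.asarray(image, dtype=np.float64)
    tu, tv = int(target_shape[0]), int(target_shape[1])
    if tu < 1 or tv < 1:
        raise ValueError(f"target_shape must be positive, got {target_shape}")
    if image.shape == (tu, tv):
        return image.copy()
    factors = (tu / image.shape[0], tv / image.shape[1])
    out = zoom(image, factors, order=1, grid_mode=True, mode="nearest")
    # zoom can over/undershoot the target by one sample on odd factors
    if out.shape != (tu, tv):
        out = out[:tu, :tv]
    return out


def resize_views(projections: ProjectionSet,
                 target_shape: tuple[int, int]) -> ProjectionSet:
    """Resize every view to ``target_shape`` (U, V) by linear interpolation."""
    return ProjectionSet(
        [Projection(resize_image(p.image, target_shape), p.angle)
         for p in projections]
    )


def assemble(projections: ProjectionSet, scheme: AngleScheme,
             scale: str = "high", depth: int | None = None) -> MultiViewInput:
    """Back-project each view into a 3D channel and crop to common support.

    Channel ``i`` is ``crop_common_support(backproject_view(P_i, theta_i))``.
    All projections must share one shape; the output grid is
    ``(U, depth, V)`` with ``depth`` defaulting to ``U``.
    """
    if len(projections) != len(scheme):
        raise ValueError(
            f"{len(projections)} projections but {len(scheme)} angles")
    shapes = {p.shape for p in projections}
    if len(shapes) != 1:
        raise ValueError(f"mismatched projection shapes: {shapes}")
    channels = []
    for p, angle in zip(projections, scheme):
        vol = backproject_view(Projection(p.image, angle), depth=depth)
        channels.append(crop_common_support(vol).data)
    return MultiViewInput(np.stack(channels).astype(np.float32), scheme, scale)
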