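"""Shared in-memory containers for volumes, projections and view schemes.

Conventions used throughout the package
---------------------------------------
* Volumes are 3D scalar grids with axes ``(X, Y, Z)``; ``Z`` is the
  cranio-caudal rotation axis. Values live in ``[0, 1]``.
* View angles are stored in degrees; the rotation happens in the X-Y
  plane. ``theta = 180`` is the anteroposterior view (rays along +Y) and
  ``theta = 90`` the lateral view (rays along X), matching the clinical
  labels for those two projections.
* A projection image is indexed ``(U, V)`` where ``U`` is the in-plane
  detector coordinate and ``V`` the Z (axial) coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Volume",
    "Projection",
    "ProjectionSet",
    "AngleScheme",
    "MultiViewInput",
    "as_volume_array",
]


def as_volume_array(volume) -> np.ndarray:
    """Return the underlying 3D ndarray of a :class:`Volume` or array-like."""
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    return data


@dataclass(frozen=True)
class Volume:
    """A dense 3D scalar grid with values in ``[0, 1]``."""

    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"Volume needs a 3D array, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("Volume contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def clipped(self) -> "Volume":
        return Volume(np.clip(self.data, 0.0, 1.0))


@dataclass(frozen=True)
class Projection:
    """A single 2D view: image indexed (U, V) plus its acquisition angle."""

    image: np.ndarray
    angle: float

    def __post_init__(self):
        img = np.asarray(self.image)
        if img.ndim != 2:
            raise ValueError(f"Projection image must be 2D, got {img.shape}")
        if not np.all(np.isfinite(img)):
            raise ValueError("Projection image contains non-finite values")
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "angle", float(self.angle))

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


class ProjectionSet:
    """An ordered collection of projections, the network input/supervision."""

    def __init__(self, projections: Sequence[Projection]):
        projections = list(projections)
        if not projections:
            raise ValueError("ProjectionSet cannot be empty")
        self.projections = projections

    @classmethod
    def from_arrays(cls, images: Sequence[np.ndarray], angles: Sequence[float]):
        if len(images) != len(angles):
            raise ValueError("images and angles differ in length")
        return cls([Projection(im, a) for im, a in zip(images, angles)])

    @property
    def angles(self) -> list[float]:
        return [p.angle for p in self.projections]

    @property
    def images(self) -> list[np.ndarray]:
        return [p.image for p in self.projections]

    def stack(self) -> np.ndarray:
        """Images stacked to (N, U, V); requires a common shape."""
        shapes = {p.shape for p in self.projections}
        if len(shapes) != 1:
            raise ValueError(f"projections have mismatched shapes: {shapes}")
        return np.stack(self.images, axis=0)

    def __len__(self) -> int:
        return len(self.projections)

    def __iter__(self) -> Iterator[Projection]:
        return iter(self.projections)

    def __getitem__(self, i) -> Projection:
        return self.projections[i]


@dataclass(frozen=True)
class AngleScheme:
    """Ordered view angles with their stated angular coverage span."""

    angles: tuple[float, ...]
    coverage_span: float = 180.0

    def __post_init__(self):
        angles = tuple(float(a) for a in self.angles)
        if len(angles) < 1:
            raise ValueError("AngleScheme needs at least one angle")
        if any(not (0.0 < a <= 360.0) for a in angles):
            raise ValueError("angles must lie in (0, 360] degrees")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("angles must be strictly increasing")
        if angles[-1] - angles[0] > self.coverage_span + 1e-9:
            raise ValueError("angles exceed the stated coverage span")
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "coverage_span", float(self.coverage_span))

    def __len__(self) -> int:
        return len(self.angles)

    def __iter__(self) -> Iterator[float]:
        return iter(self.angles)


@dataclass(frozen=True)
class MultiViewInput:
    """Per-view back-projected 3D channels on a common grid.

    ``channels`` has shape ``(N, X, Y, Z)`` with one channel per view.
    """

    channels: np.ndarray
    scheme: AngleScheme
    scale: str = "high"

    def __post_init__(self):
        ch = np.asarray(self.channels)
        if ch.ndim != 4:
            raise ValueError(f"channels must be (N, X, Y, Z), got {ch.shape}")
        if ch.shape[0] != len(self.scheme):
            raise ValueError(
                f"{ch.shape[0]} channels but {len(self.scheme)} scheme angles"
            )
        if self.scale not in ("low", "high"):
            raise ValueError("scale must be 'low' or 'high'")
        object.__setattr__(self, "channels", ch)

    @property
    def n_views(self) -> int:
        return self.channels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]
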