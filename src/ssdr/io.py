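"""Volume and projection readers/writers plus seeded run records.

Volumes: NIfTI (``.nii``/``.nii.gz``, axis order X, Y, Z with Z the
rotation axis) or flat 32-bit binary with a JSON sidecar recording
shape/dtype/spacing. Projections: 16-bit grayscale TIFF or PNG stacks
with a CSV manifest ``(filename, angle_degrees)``; the [0, 1] range is
quantised to 16 bits, so a write/read round trip is exact to 1/65535
per pixel. Every artifact-producing command writes one RunRecord JSON
next to its outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .containers import Projection, ProjectionSet, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_projection_set",
    "write_projection_set",
    "RunRecord",
]

_Q = 65535.0


@dataclass
class RunRecord:
    """Provenance of one artifact-producing command."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    software_version: str = "0.1.0"
    epochs: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, directory) -> Path:
        path = Path(directory) / "run_record.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        return path


def write_volume(volume, path) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz) or raw float32 + sidecar."""
    path = Path(path)
    data = np.asarray(volume.data if isinstance(volume, Volume) else volume,
                      dtype=np.float32)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.Nifti1Image(data, affine=np.eye(4))
        nib.save(img, str(path))
    elif path.suffix == ".raw":
        data.tofile(path)
        sidecar = {"shape": list(data.shape), "dtype": "float32",
                   "axis_order": "XYZ", "spacing": [1.0, 1.0, 1.0]}
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return path


def read_volume(path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.load(str(path))
        return Volume(np.asarray(img.dataobj, dtype=np.float32))
    if path.suffix == ".raw":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar for {path}")
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        data = np.fromfile(path, dtype=meta["dtype"])
        return Volume(data.reshape(meta["shape"]))
    raise ValueError(f"unsupported volume format: {path.name}")


def write_projection_set(projections: ProjectionSet, directory,
                         fmt: str = "tiff") -> Path:
    """16-bit grayscale images plus ``manifest.csv`` (filename, angle)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(projections):
        img = np.clip(np.asarray(p.image, dtype=np.float64), 0.0, 1.0)
        q = np.round(img * _Q).astype(np.uint16)
        if fmt == "tiff":
            fname = f"view_{i:03d}.tif"
            tifffile.imwrite(directory / fname, q)
        elif fmt == "png":
            fname = f"view_{i:03d}.png"
            iio.imwrite(directory / fname, q)
        else:
            raise ValueError(f"unsupported projection format: {fmt}")
        rows.append({"filename": fname, "angle_degrees": p.angle})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return directory


def read_projection_set(directory) -> ProjectionSet:
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"missing manifest: {manifest}")
    table = pd.read_csv(manifest)
    missing = [f for f in table["filename"] if not (directory / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"manifest references missing images: {missing}")
    projections = []
    for _, row in table.iterrows():
        fpath = directory / row["filename"]
        if fpath.suffix in (".tif", ".tiff"):
            q = tifffile.imread(fpath)
        else:
            q = iio.imread(fpath)
        projections.append(
            Projection(np.asarray(q, dtype=np.float64) / _Q,
                       float(row["angle_degrees"])))
    return ProjectionSet(projections)
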