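"""NIfTI-1 volume I/O and run manifests.

All volumes of one case must share a single voxel grid; reading a case
refuses silently mismatched geometries. Scalar volumes round-trip at
32-bit float precision, label/mask volumes bit-exactly as integers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GeometryError
from .geometry import ImageGeometry


def write_volume(
    volume: np.ndarray, geometry: ImageGeometry, path: str | Path
) -> Path:
    """Write a 3D (or 4D) volume as NIfTI-1 with the geometry's spacing.

    Integer and boolean arrays are stored as int16 (labels/masks), floats
    as float32.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(volume)
    if arr.dtype == bool or np.issubdtype(arr.dtype, np.integer):
        data = arr.astype(np.int16)
    else:
        data = arr.astype(np.float32)
    img = nib.Nifti1Image(data, geometry.affine())
    img.header.set_zooms(geometry.spacing + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, ImageGeometry]:
    """Read a NIfTI volume; returns the array and its grid geometry."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    geometry = ImageGeometry(tuple(data.shape[:3]), tuple(float(z) for z in zooms))
    return data, geometry


def check_case_geometry(volumes: dict[str, tuple[np.ndarray, ImageGeometry]]) -> None:
    """Raise if any volume of a case disagrees in shape or spacing."""
    geos = {name: geo for name, (_, geo) in volumes.items()}
    ref_name, ref = next(iter(geos.items()))
    bad = {
        name: (geo.shape, geo.spacing)
        for name, geo in geos.items()
        if geo.shape != ref.shape or not np.allclose(geo.spacing, ref.spacing)
    }
    if bad:
        raise GeometryError(
            f"volumes disagree with {ref_name} {ref.shape}/{ref.spacing}: {bad}"
        )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path
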