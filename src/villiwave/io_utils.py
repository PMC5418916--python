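"""Readers/writers for volumes, tables and summaries.

Volumes are written both as multi-page TIFF stacks (page k = z-slice k,
chorionic plate first) and as NIfTI-1 with the isotropic pixel size in the
affine, so they open with correct physical scaling in standard viewers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile


def write_tiff(volume: np.ndarray, path, pixel_size_um: float) -> Path:
    """Write a 3D volume as a z-paged TIFF stack with pixel-size metadata."""
    path = Path(path)
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    pages = np.moveaxis(vol, 2, 0)  # (z, x, y)
    tifffile.imwrite(
        path,
        pages,
        resolution=(1e4 / pixel_size_um, 1e4 / pixel_size_um),
        resolutionunit="CENTIMETER",
        metadata={"spacing": pixel_size_um, "unit": "um", "axes": "ZXY"},
    )
    return path


def read_tiff(path) -> np.ndarray:
    """Read a z-paged TIFF stack back into (x, y, z) axis order."""
    pages = tifffile.imread(path)
    return np.moveaxis(pages, 0, 2)


def write_nifti(volume: np.ndarray, path, pixel_size_um: float) -> Path:
    """Write a 3D volume as NIfTI-1 with the pixel size (mm) in the affine."""
    path = Path(path)
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    v = pixel_size_um / 1000.0
    img = nib.Nifti1Image(vol, affine=np.diag([v, v, v, 1.0]))
    img.header.set_zooms((v, v, v))
    nib.save(img, str(path))
    return path


def write_vector_nifti(vectors: np.ndarray, path, pixel_size_um: float) -> Path:
    """Write an (nx, ny, nz, 3) vector volume as a 4D NIfTI."""
    v = pixel_size_um / 1000.0
    img = nib.Nifti1Image(np.asarray(vectors), affine=np.diag([v, v, v, 1.0]))
    nib.save(img, str(path))
    return Path(path)


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)
    return path


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()
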