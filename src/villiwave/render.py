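"""Slice rendering of magnitude / phi / theta volumes.

Each quantity gets a fixed, documented color scale so images from
different z positions and conditions are directly comparable: magnitude is
linear from 0 to xi_0 (viridis), phi linear over [0, 180] deg (viridis),
theta over [-180, 180) deg on a cyclic map (twilight) so -180 and +180
meet in the same color.  Undefined voxels render black.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import numpy as np
from matplotlib import colormaps
from matplotlib.colors import Normalize

SCALES = {
    "magnitude": {"cmap": "viridis", "vmin": 0.0, "vmax": None},  # vmax = xi_0
    "phi": {"cmap": "viridis", "vmin": 0.0, "vmax": 180.0},
    "theta": {"cmap": "twilight", "vmin": -180.0, "vmax": 180.0},
}


def colorize(values: np.ndarray, quantity: str, xi0_um: float = 0.1) -> np.ndarray:
    """Map a 2D slice of a quantity to RGBA uint8 under the fixed scale."""
    if quantity not in SCALES:
        raise ValueError(f"unknown quantity {quantity!r}")
    spec = SCALES[quantity]
    vmax = xi0_um if spec["vmax"] is None else spec["vmax"]
    norm = Normalize(vmin=spec["vmin"], vmax=vmax, clip=True)
    cmap = colormaps[spec["cmap"]]
    vals = np.asarray(values, dtype=float)
    rgba = cmap(norm(np.nan_to_num(vals, nan=spec["vmin"])), bytes=True)
    rgba[~np.isfinite(vals)] = (0, 0, 0, 255)
    return rgba


def uncolorize(rgba: np.ndarray, quantity: str, xi0_um: float = 0.1) -> np.ndarray:
    """Invert :func:`colorize` by nearest-color lookup (for verification)."""
    spec = SCALES[quantity]
    vmax = xi0_um if spec["vmax"] is None else spec["vmax"]
    cmap = colormaps[spec["cmap"]]
    lut = (cmap(np.linspace(0.0, 1.0, cmap.N))[:, :3] * 255).astype(float)
    rgb = np.asarray(rgba, dtype=float)[..., :3]
    d2 = ((rgb[..., None, :] - lut[None, ...]) ** 2).sum(axis=-1)
    frac = np.argmin(d2, axis=-1) / (cmap.N - 1)
    return spec["vmin"] + frac * (vmax - spec["vmin"])


def render_slices(
    volumes: dict[str, np.ndarray],
    z_list_mm,
    pixel_mm: float,
    out_dir,
    xi0_um: float = 0.1,
) -> list[Path]:
    """Write one PNG per (quantity, z); skips z outside the volume."""
    from matplotlib.image import imsave

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, vol in volumes.items():
        nz = vol.shape[2]
        for z in z_list_mm:
            k = int(round(z / pixel_mm - 0.5))
            if not (0 <= k < nz):
                warnings.warn(f"requested z={z} mm outside the volume; skipped")
                continue
            rgba = colorize(vol[:, :, k], name, xi0_um)
            path = out_dir / f"{name}_z{z:.2f}mm.png"
            imsave(path, np.transpose(rgba, (1, 0, 2)), origin="lower")
            written.append(path)
    return written
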