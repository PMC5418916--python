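"""Polar decomposition and per-slice statistics of the displacement field.

The displacement is described in polar form: magnitude, phi (angle from the
+z axis, 0-180 deg; 90 deg means parallel to the chorionic plate) and theta
(azimuth in the xy-plane, [-180, 180) deg; undefined for purely axial
displacement).  Statistics are taken per z-slice over the displaced area
(|u| > 0), and four characteristic positions recur across conditions:

* ``z_d``   - peak of the normalized SD of the magnitude, near the
  truncus-rami boundary;
* ``z_phi1``/``z_phi2`` - the two peaks of SD(phi); the displaced area is
  mostly in-plane (phi in [45, 135] deg) at z_phi1 and mostly axial at
  z_phi2;
* ``z_theta`` - dip of mean theta near the rami-ramuli boundary, caused by
  the asymmetry of the ramuli.

Tier midpoints z_t, z_r, z_rl complete the reporting positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .tree_model import TIER_Z_BOUNDS
from .wavefield import DisplacementField


@dataclass
class PolarField:
    """Polar decomposition of a displacement vector volume.

    ``phi`` in degrees [0, 180], ``theta`` in degrees [-180, 180) (NaN
    where undefined), ``theta_defined`` where the in-plane component is
    non-negligible, ``displaced`` where |u| > 0.
    """

    magnitude: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    theta_defined: np.ndarray
    displaced: np.ndarray
    pixel_mm: float


def to_polar(
    vectors: np.ndarray,
    displaced: np.ndarray | None = None,
    pixel_mm: float = 1.0,
    inplane_rtol: float = 1e-9,
) -> PolarField:
    """Decompose a (..., 3) vector volume into magnitude / phi / theta.

    theta is undefined (NaN, ``theta_defined`` False) where the in-plane
    component is below ``inplane_rtol`` times the magnitude, i.e. where the
    displacement is perpendicular to the chorionic plate.
    """
    v = np.asarray(vectors, dtype=np.float64)
    mag = np.linalg.norm(v, axis=-1)
    inplane = np.hypot(v[..., 0], v[..., 1])
    nonzero = mag > 0
    phi = np.zeros_like(mag)
    np.divide(v[..., 2], mag, out=phi, where=nonzero)
    phi = np.degrees(np.arccos(np.clip(phi, -1.0, 1.0)))
    phi[~nonzero] = np.nan
    defined = nonzero & (inplane > inplane_rtol * mag)
    theta = np.full_like(mag, np.nan)
    theta[defined] = np.degrees(np.arctan2(v[..., 1][defined], v[..., 0][defined]))
    theta[theta >= 180.0] = -180.0  # atan2(+0, x<0) maps to the open edge
    if displaced is None:
        displaced = nonzero
    return PolarField(
        magnitude=mag,
        phi=phi,
        theta=theta,
        theta_defined=defined,
        displaced=np.asarray(displaced, bool),
        pixel_mm=pixel_mm,
    )


def polar_of_field(field: DisplacementField) -> PolarField:
    return to_polar(
        field.vectors, displaced=field.displaced, pixel_mm=field.grid.pixel_mm
    )


def area_fraction_phi(
    phi_deg: np.ndarray, lo: float = 45.0, hi: float = 135.0
) -> float:
    """Fraction of values with lo <= phi <= hi (band edges inclusive)."""
    phi_deg = np.asarray(phi_deg, dtype=float)
    phi_deg = phi_deg[np.isfinite(phi_deg)]
    if phi_deg.size == 0:
        return np.nan
    return float(np.mean((phi_deg >= lo) & (phi_deg <= hi)))


def theta_histogram(theta_deg: np.ndarray, bin_deg: float = 1.0) -> np.ndarray:
    """Area-fraction histogram of theta over [-180, 180) in 1-deg bins."""
    theta_deg = np.asarray(theta_deg, dtype=float)
    theta_deg = theta_deg[np.isfinite(theta_deg)]
    n_bins = int(round(360.0 / bin_deg))
    counts, _ = np.histogram(theta_deg, bins=n_bins, range=(-180.0, 180.0))
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def theta_histogram_sd(theta_deg: np.ndarray, bin_deg: float = 1.0) -> float:
    """SD_in: population SD of the per-bin area fractions of theta."""
    theta_deg = np.asarray(theta_deg, dtype=float)
    if not np.isfinite(theta_deg).any():
        return np.nan
    return float(np.std(theta_histogram(theta_deg, bin_deg)))


def slice_stats(polar: PolarField) -> pd.DataFrame:
    """Per-z-slice statistics over the displaced area.

    All SDs are population SDs (divide by N).  theta statistics use only
    theta-defined voxels.  Slices with no displaced voxels get area 0 and
    NaN statistics.
    """
    nz = polar.magnitude.shape[2]
    rows = []
    for k in range(nz):
        disp = polar.displaced[:, :, k]
        area = int(disp.sum())
        row = {
            "k": k,
            "z_mm": (k + 0.5) * polar.pixel_mm,
            "displaced_area": area,
            "mag_mean": np.nan,
            "mag_sd": np.nan,
            "mag_norm_sd": np.nan,
            "phi_mean": np.nan,
            "phi_sd": np.nan,
            "frac_phi_45_135": np.nan,
            "theta_mean": np.nan,
            "theta_sd": np.nan,
            "sd_in": np.nan,
        }
        if area:
            mag = polar.magnitude[:, :, k][disp]
            phi = polar.phi[:, :, k][disp]
            row["mag_mean"] = mag.mean()
            row["mag_sd"] = mag.std()
            row["mag_norm_sd"] = row["mag_sd"] / row["mag_mean"] if row["mag_mean"] else np.nan
            row["phi_mean"] = phi.mean()
            row["phi_sd"] = phi.std()
            row["frac_phi_45_135"] = area_fraction_phi(phi)
            tdef = disp & polar.theta_defined[:, :, k]
            if tdef.any():
                th = polar.theta[:, :, k][tdef]
                row["theta_mean"] = th.mean()
                row["theta_sd"] = th.std()
                row["sd_in"] = theta_histogram_sd(th)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# characteristic positions
# ---------------------------------------------------------------------------

@dataclass
class CharacteristicPositions:
    """Detected characteristic z positions (mm) plus the tier midpoints."""

    z_d: float | None
    z_phi1: float | None
    z_phi2: float | None
    z_theta: float | None
    z_t: float
    z_r: float
    z_rl: float
    incomplete: list[str] = field(default_factory=list)
    phi_peak_candidates: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "z_d": self.z_d,
            "z_phi1": self.z_phi1,
            "z_phi2": self.z_phi2,
            "z_theta": self.z_theta,
            "z_t": self.z_t,
            "z_r": self.z_r,
            "z_rl": self.z_rl,
            "incomplete": list(self.incomplete),
            "phi_peak_candidates": list(self.phi_peak_candidates),
        }


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Moving average ignoring NaNs (window centered, edges shrink)."""
    y = np.asarray(y, dtype=float)
    valid = np.isfinite(y)
    num = np.convolve(np.where(valid, y, 0.0), np.ones(window), mode="same")
    den = np.convolve(valid.astype(float), np.ones(window), mode="same")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def find_characteristic_positions(
    table: pd.DataFrame,
    tier_bounds: dict[str, tuple[float, float]] = TIER_Z_BOUNDS,
    smooth_window: int = 5,
    prominence_frac: float = 0.10,
    z_d_window_mm: float = 2.0,
    z_theta_window_mm: float = 2.5,
) -> CharacteristicPositions:
    """Detect z_d, z_phi1, z_phi2 and z_theta from a slice-statistics table.

    z_d is the maximum of the (smoothed) normalized magnitude SD within
    +/- ``z_d_window_mm`` of the truncus-rami boundary; z_theta is the
    minimum of mean theta within +/- ``z_theta_window_mm`` of the
    rami-ramuli boundary.  Missing features are reported in ``incomplete``
    rather than raised.

    z_phi2 is the most prominent local maximum of SD(phi) (prominence
    threshold = ``prominence_frac`` of the profile range after
    ``smooth_window``-slice smoothing): the slice whose displaced area is
    most strongly split between the two axial poles.  z_phi1 is the slice
    maximizing the smoothed in-plane area fraction (phi in [45, 135]).
    The in-plane-dominant slice is detected from the area-fraction profile
    rather than from SD(phi) because the per-slice phi distribution is a
    mixture of sign-flipped populations: its SD is a weighted average of
    the subpopulation SDs and therefore cannot form a local maximum where
    the in-plane population dominates, while in-plane dominance is
    precisely the property that defines z_phi1.

    The characteristic positions interleave with the tier midpoints as
    z_t < z_phi1 < z_r < z_phi2 < z_rl, so the z_phi1 search is windowed
    to (z_t, min(z_r_boundary, z_phi2)) and the z_phi2 search to z > z_r.
    """
    z = table["z_mm"].to_numpy()
    incomplete: list[str] = []

    z_t = 0.5 * sum(tier_bounds["truncus"])
    z_r = 0.5 * sum(tier_bounds["rami"])
    z_rl = 0.5 * sum(tier_bounds["ramuli"])
    tr_boundary = tier_bounds["truncus"][1]
    rl_boundary = tier_bounds["rami"][1]

    # z_d: peak of normalized SD of magnitude near the truncus-rami boundary
    nsd = _smooth(table["mag_norm_sd"].to_numpy(), smooth_window)
    win = np.isfinite(nsd) & (np.abs(z - tr_boundary) <= z_d_window_mm)
    if win.any():
        z_d = float(z[win][np.argmax(nsd[win])])
    else:
        z_d = None
        incomplete.append("z_d")

    # z_phi2: the most prominent peak of SD(phi) (axial-dominant slice),
    # preferring peaks beyond the rami midpoint per the position ordering
    sd_phi = _smooth(table["phi_sd"].to_numpy(), smooth_window)
    valid = np.isfinite(sd_phi)
    z_phi2 = None
    candidates: list[float] = []
    rng = float(np.nanmax(sd_phi) - np.nanmin(sd_phi)) if valid.any() else 0.0
    if valid.sum() >= 3 and rng > 0:
        y = sd_phi.copy()
        y[~valid] = np.nanmin(sd_phi)
        peaks, props = find_peaks(y, prominence=prominence_frac * rng)
        prom = props["prominences"]
        keep = valid[peaks]
        peaks, prom = peaks[keep], prom[keep]
        candidates = [float(z[p]) for p in sorted(peaks)]
        if len(peaks):
            beyond = z[peaks] > z_r
            if beyond.any():
                peaks, prom = peaks[beyond], prom[beyond]
            z_phi2 = float(z[peaks[np.argmax(prom)]])
    if z_phi2 is None:
        incomplete.append("z_phi2")

    # z_phi1: in-plane-dominant slice between z_t and min(z_r, z_phi2)
    frac = _smooth(table["frac_phi_45_135"].to_numpy(), smooth_window)
    upper = z_r if z_phi2 is None else min(z_r, z_phi2)
    fvalid = np.isfinite(frac) & (z > z_t) & (z < upper)
    frange = float(np.nanmax(frac[fvalid]) - np.nanmin(frac[fvalid])) if fvalid.any() else 0.0
    if fvalid.any() and frange > 0:
        z_phi1 = float(z[fvalid][np.argmax(frac[fvalid])])
    else:
        z_phi1 = None
        incomplete.append("z_phi1")

    # z_theta: dip of mean theta near the rami-ramuli boundary
    mth = _smooth(table["theta_mean"].to_numpy(), smooth_window)
    win = np.isfinite(mth) & (np.abs(z - rl_boundary) <= z_theta_window_mm)
    if win.any():
        z_theta = float(z[win][np.argmin(mth[win])])
    else:
        z_theta = None
        incomplete.append("z_theta")

    return CharacteristicPositions(
        z_d=z_d,
        z_phi1=z_phi1,
        z_phi2=z_phi2,
        z_theta=z_theta,
        z_t=z_t,
        z_r=z_r,
        z_rl=z_rl,
        incomplete=incomplete,
        phi_peak_candidates=candidates,
    )
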