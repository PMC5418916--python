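"""Shear-wave displacement field in the surroundings of the stem villi.

The surroundings (intermediate/terminal villi plus intervillous space) are
treated as one incompressible continuum, so only the shear (transverse)
wave survives and the shear modulus is mu = rho lambda^2 nu^2.  Every
surface element of the contracting villi launches a wave; a voxel of the
surroundings takes the direction of its *nearest* surface element and the
amplitude

    u(r) = xi_0 cos(Phi(r)),   Phi(r) = integral_0^r 2 pi / lambda(s) ds

evaluated at t = 0, where r is the Euclidean distance from the villous
surface.  Viscoelastic attenuation is idealized as a hard cutoff: u = 0
beyond the maximum propagation distance d_max.  The wavelength is either
constant or increases stepwise (0.29 / 0.58 / 1.45 mm in thirds of d_max)
with distance from the surface; the phase is accumulated across the steps
so the amplitude stays continuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
from scipy.spatial import cKDTree

from .contraction import ContractionSurface
from .tree_model import DomainError, VoxelGrid

#: wavelengths studied (mm); also the steps of the increasing profile
LAMBDAS_MM = (0.29, 0.58, 1.45)
#: hard propagation cutoffs studied (mm)
D_MAX_MM = (1.45, 2.9, 4.35)

INCREASING = "increasing"


@dataclass(frozen=True)
class WaveParams:
    """Parameters of one computational condition.

    ``lambda_profile`` is a constant wavelength in mm or the string
    ``"increasing"``; ``t`` is fixed at 0 (no time dependence).
    """

    lambda_profile: float | str = 1.45
    d_max_mm: float = 4.35
    xi0_um: float = 0.1
    nu_hz: float = 1.0
    rho_kg_m3: float = 1000.0

    def __post_init__(self) -> None:
        if isinstance(self.lambda_profile, str):
            if self.lambda_profile != INCREASING:
                raise ValueError(f"unknown lambda profile {self.lambda_profile!r}")
        elif self.lambda_profile <= 0:
            raise ValueError("constant wavelength must be positive")
        if min(self.d_max_mm, self.xi0_um, self.nu_hz, self.rho_kg_m3) <= 0:
            raise ValueError("wave parameters must be positive")

    @property
    def label(self) -> str:
        lam = (
            INCREASING
            if self.lambda_profile == INCREASING
            else f"{self.lambda_profile:g}mm"
        )
        return f"lambda={lam}_dmax={self.d_max_mm:g}mm"

    @property
    def mu_pa(self) -> float:
        """Shear modulus of the constant profile (or of the first step)."""
        lam = (
            LAMBDAS_MM[0]
            if self.lambda_profile == INCREASING
            else float(self.lambda_profile)
        )
        return shear_modulus(self.rho_kg_m3, lam, self.nu_hz)


def shear_modulus(rho_kg_m3: float, lambda_mm: float, nu_hz: float) -> float:
    """Shear elastic modulus mu = rho lambda^2 nu^2 in Pa (lambda in mm)."""
    if rho_kg_m3 < 0 or lambda_mm < 0 or nu_hz < 0:
        raise DomainError("rho, lambda and nu must be non-negative")
    return rho_kg_m3 * (lambda_mm * 1e-3) ** 2 * nu_hz**2


def enumerate_conditions(base: WaveParams = WaveParams()) -> list[WaveParams]:
    """The 12 studied conditions: {0.29, 0.58, 1.45, increasing} x d_max."""
    profiles: list[float | str] = [*LAMBDAS_MM, INCREASING]
    return [
        replace(base, lambda_profile=p, d_max_mm=d)
        for p in profiles
        for d in D_MAX_MM
    ]


def lambda_at(r, params: WaveParams):
    """Local wavelength (mm) at distance r (mm) from the villous surface."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > params.d_max_mm + 1e-12):
        raise DomainError("r must lie in [0, d_max]")
    if params.lambda_profile != INCREASING:
        out = np.full_like(r, float(params.lambda_profile))
        return float(out) if out.ndim == 0 else out
    third = params.d_max_mm / 3.0
    band = np.minimum((r / third).astype(int), 2)
    out = np.take(np.asarray(LAMBDAS_MM), band)
    return float(out) if out.ndim == 0 else out


def phase_at(r, params: WaveParams):
    """Accumulated phase Phi(r) = int_0^r 2 pi / lambda(s) ds (rad).

    Continuous and non-decreasing also for the increasing profile (the
    phase, not 2 pi r / lambda(r), is accumulated across the thirds).
    """
    r = np.asarray(r, dtype=float)
    if params.lambda_profile != INCREASING:
        out = 2.0 * math.pi * r / float(params.lambda_profile)
        return float(out) if out.ndim == 0 else out
    third = params.d_max_mm / 3.0
    edges = np.array([0.0, third, 2.0 * third])
    phase_off = np.concatenate(
        [[0.0], np.cumsum(2.0 * math.pi * third / np.asarray(LAMBDAS_MM[:2]))]
    )
    band = np.clip((r / third).astype(int), 0, 2)
    lam = np.take(np.asarray(LAMBDAS_MM), band)
    out = phase_off[band] + 2.0 * math.pi * (r - edges[band]) / lam
    return float(out) if out.ndim == 0 else out


@dataclass
class DisplacementField:
    """Displacement vectors over the surroundings plus provenance volumes.

    ``vectors``: (nx, ny, nz, 3) float32, micrometres; zero inside the
    villi and beyond d_max.  ``distance``: float32 mm, +inf outside the
    propagation band.  ``source_map``: int32 surface-element id, -1 outside
    the band.  ``displaced``: |u| above a small threshold (1e-6 xi_0, the float32
    rounding scale of the stored distances), so voxels at the cosine zeros
    are excluded from the displaced area.
    """

    vectors: np.ndarray
    distance: np.ndarray
    source_map: np.ndarray
    displaced: np.ndarray
    params: WaveParams
    grid: VoxelGrid

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for a in (self.vectors, self.distance, self.source_map):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


def distance_transform(
    grid: VoxelGrid,
    d_max_mm: float,
    surface: ContractionSurface,
    slab_nz: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited Euclidean distance to the nearest surface element.

    Returns ``(distance, source_map)``: center-to-center distance in mm
    (float32, +inf where unoccupied voxels are farther than ``d_max_mm``
    or where voxels are occupied) and the nearest element id (int32, -1
    outside the band).  The KD-tree holds the surface voxel centers in
    element-id order and each voxel is queried independently, so the
    result does not depend on slab partitioning.
    """
    if d_max_mm < grid.pixel_mm:
        import warnings

        warnings.warn("d_max below one pixel: the propagation band is nearly empty")
    nx, ny, nz = grid.dims
    distance = np.full(grid.dims, np.inf, dtype=np.float32)
    source = np.full(grid.dims, -1, dtype=np.int32)
    tree = cKDTree(surface.pos)
    n_elem = len(surface)
    slab = nz if slab_nz is None else max(1, slab_nz)
    for k0 in range(0, nz, slab):
        k1 = min(k0 + slab, nz)
        free = ~grid.occupancy[:, :, k0:k1]
        ii, jj, kk = np.nonzero(free)
        if ii.size == 0:
            continue
        idx = np.column_stack([ii, jj, kk + k0])
        pts = grid.voxel_centers(idx)
        d, src = tree.query(
            pts, k=1, distance_upper_bound=d_max_mm * (1.0 + 1e-12)
        )
        hit = src < n_elem
        keep = hit & (d <= d_max_mm)
        distance[idx[keep, 0], idx[keep, 1], idx[keep, 2]] = d[keep]
        source[idx[keep, 0], idx[keep, 1], idx[keep, 2]] = src[keep]
    return distance, source


def displacement_field(
    distance: np.ndarray,
    source_map: np.ndarray,
    surface: ContractionSurface,
    params: WaveParams,
    grid: VoxelGrid,
    displaced_rtol: float = 1e-6,
) -> DisplacementField:
    """Evaluate u = xi_0 cos(Phi(r)) along each voxel's source direction."""
    if surface.directions is None:
        raise ValueError("surface has no contraction directions assigned")
    band = source_map >= 0
    band &= distance <= params.d_max_mm  # distance beyond cutoff stays zero
    vectors = np.zeros((*distance.shape, 3), dtype=np.float32)
    displaced = np.zeros(distance.shape, dtype=bool)
    r = distance[band].astype(np.float64)
    amp = params.xi0_um * np.cos(phase_at(r, params))
    dirs = surface.directions[source_map[band]]
    vectors[band] = (dirs * amp[:, None]).astype(np.float32)
    displaced[band] = np.abs(amp) > displaced_rtol * params.xi0_um
    dist_out = np.where(band, distance, np.float32(np.inf)).astype(np.float32)
    src_out = np.where(band, source_map, np.int32(-1)).astype(np.int32)
    return DisplacementField(
        vectors=vectors,
        distance=dist_out,
        source_map=src_out,
        displaced=displaced,
        params=params,
        grid=grid,
    )


def compute_displacement(
    grid: VoxelGrid,
    surface: ContractionSurface,
    params: WaveParams,
    slab_nz: int | None = None,
    distance: np.ndarray | None = None,
    source_map: np.ndarray | None = None,
) -> DisplacementField:
    """Distance transform plus wave evaluation in one call.

    A precomputed ``(distance, source_map)`` pair (e.g. shared across
    conditions at the largest d_max) may be passed in; distances beyond
    this condition's d_max are cut off regardless.
    """
    if distance is None or source_map is None:
        distance, source_map = distance_transform(
            grid, params.d_max_mm, surface, slab_nz=slab_nz
        )
    return displacement_field(distance, source_map, surface, params, grid)
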