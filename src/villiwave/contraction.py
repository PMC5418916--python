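"""Surface extraction and contraction-direction assignment.

Contractile cells run along the longitudinal axes of the stem villi, so
every point of the villous surface contracts tangentially, along the local
branch axis and toward the branch's proximal junction.  On the truncus the
axis is the z-axis and the surface slope matters: with the axis contraction
direction (0, 0, -1), the surface tangent makes the angle

    phi_o = pi + atan(dr/dz)

with the +z axis, giving the unit direction
(sin phi_o cos theta_o, sin phi_o sin theta_o, cos phi_o), where theta_o is
the azimuth of the surface point around the truncus axis.  On the rami and
ramuli the diameter change is small, so the contraction direction is the
axis tangent itself, oriented proximally (toward the junction with the
parent branch).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .tree_model import (
    TruncusProfile,
    VillousTree,
    VoxelGrid,
    truncus_radius_derivative,
)

log = logging.getLogger(__name__)


@dataclass
class ContractionSurface:
    """Surface voxels of the villous grid with unit contraction directions.

    Elements are ordered lexicographically by voxel index (i, j, k); the
    element id is the row index.  ``directions``/``branch_id``/``phi_o``/
    ``theta_o`` are filled by :func:`assign_directions`.
    """

    idx: np.ndarray  # (n, 3) int voxel indices
    pos: np.ndarray  # (n, 3) voxel centers, mm
    grid: VoxelGrid
    branch_id: np.ndarray | None = None
    directions: np.ndarray | None = None  # (n, 3) unit vectors
    phi_o: np.ndarray | None = None  # angle to +z axis, rad
    theta_o: np.ndarray | None = None  # azimuth about the local axis, rad

    def __len__(self) -> int:
        return len(self.idx)

    def to_dataframe(self):
        import pandas as pd

        data = {
            "i": self.idx[:, 0],
            "j": self.idx[:, 1],
            "k": self.idx[:, 2],
            "x": self.pos[:, 0],
            "y": self.pos[:, 1],
            "z": self.pos[:, 2],
        }
        if self.directions is not None:
            data.update(
                dir_x=self.directions[:, 0],
                dir_y=self.directions[:, 1],
                dir_z=self.directions[:, 2],
                branch_id=self.branch_id,
            )
        return pd.DataFrame(data)


def extract_surface(grid: VoxelGrid) -> ContractionSurface:
    """Occupied voxels with >= 1 of their 6 face-neighbors unoccupied.

    Voxels on the volume boundary count as surface.
    """
    occ = grid.occupancy
    if not occ.any():
        raise ValueError("cannot extract a surface from an empty grid")
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(occ, structure=structure, border_value=0)
    surface = occ & ~interior
    idx = np.argwhere(surface)  # lexicographic order defines element ids
    return ContractionSurface(idx=idx, pos=grid.voxel_centers(idx), grid=grid)


def truncus_direction(
    z, theta_o, profile: TruncusProfile = TruncusProfile()
) -> np.ndarray:
    """Unit contraction direction on the truncus surface at height z.

    phi_o = pi + atan(dr/dz); at z = z_tr the slope vanishes and the
    direction is (0, 0, -1); toward z = 0 the slope diverges and the
    direction flattens into the xy-plane.
    """
    z = np.asarray(z, dtype=float)
    theta_o = np.asarray(theta_o, dtype=float)
    drdz = truncus_radius_derivative(z, profile)
    phi = math.pi + np.arctan(drdz)
    out = np.stack(
        [
            np.sin(phi) * np.cos(theta_o),
            np.sin(phi) * np.sin(theta_o),
            np.cos(phi),
        ],
        axis=-1,
    )
    return out


def axial_direction(tangent_distal: np.ndarray) -> np.ndarray:
    """Unit contraction direction from a distally oriented axis tangent.

    Contraction points toward the proximal junction, i.e. opposite the
    root-to-tip tangent.
    """
    t = np.asarray(tangent_distal, dtype=float)
    t = t / np.linalg.norm(t, axis=-1, keepdims=True)
    return -t


def _axis_samples(tree: VillousTree):
    """All axis points with branch id and distal unit tangent, id-ordered."""
    pts, bids, tangents = [], [], []
    for bid in sorted(tree.branches):
        b = tree.branches[bid]
        pts.append(b.axis)
        bids.append(np.full(len(b.axis), bid))
        tangents.append(b.tangents())
    return np.vstack(pts), np.concatenate(bids), np.vstack(tangents)


def assign_directions(
    surface: ContractionSurface,
    tree: VillousTree,
    profile: TruncusProfile = TruncusProfile(),
    tie_tol: float = 1e-9,
) -> ContractionSurface:
    """Assign each surface element to its nearest branch and set directions.

    Truncus elements get the analytic surface-tangent direction; rami and
    ramuli elements get the proximally oriented axis tangent of the nearest
    axis point.  Near-ties between branches are logged; the KD-tree's
    deterministic choice (branch-id-ordered input) decides them.
    """
    pts, bids, tangents = _axis_samples(tree)
    tiers = np.array([tree.branches[b].tier for b in bids])
    tkd = cKDTree(pts)
    dist, nearest = tkd.query(surface.pos, k=1)
    branch_id = bids[nearest]
    surface.branch_id = branch_id

    # log near-ties between distinct branches
    d2, n2 = tkd.query(surface.pos, k=2)
    tie = (np.abs(d2[:, 1] - d2[:, 0]) <= tie_tol) & (
        bids[n2[:, 1]] != bids[n2[:, 0]]
    )
    if tie.any():
        log.info("nearest-branch ties at %d surface elements", int(tie.sum()))

    n = len(surface)
    directions = np.empty((n, 3))
    phi_o = np.empty(n)
    theta_o = np.empty(n)

    is_truncus = tiers[nearest] == "truncus"
    if is_truncus.any():
        root = tree.branches[tree.root_id]
        cx, cy = root.axis[0, 0], root.axis[0, 1]
        p = surface.pos[is_truncus]
        th = np.arctan2(p[:, 1] - cy, p[:, 0] - cx)
        zz = np.clip(p[:, 2], 0.0, profile.z_tr)
        directions[is_truncus] = truncus_direction(zz, th, profile)
        drdz = truncus_radius_derivative(zz, profile)
        phi_o[is_truncus] = math.pi + np.arctan(drdz)
        theta_o[is_truncus] = th
    if (~is_truncus).any():
        d = axial_direction(tangents[nearest[~is_truncus]])
        directions[~is_truncus] = d
        phi_o[~is_truncus] = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
        # azimuth of the surface point about the nearest axis point
        rel = surface.pos[~is_truncus] - pts[nearest[~is_truncus]]
        theta_o[~is_truncus] = np.arctan2(rel[:, 1], rel[:, 0])

    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    surface.directions = directions / norms
    surface.phi_o = phi_o
    surface.theta_o = theta_o
    return surface


def build_surface(
    grid: VoxelGrid, tree: VillousTree, profile: TruncusProfile = TruncusProfile()
) -> ContractionSurface:
    """Convenience: extract the surface and assign contraction directions."""
    return assign_directions(extract_surface(grid), tree, profile)
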