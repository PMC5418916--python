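"""2D diffusion-limited aggregation and skeleton extraction for the ramuli.

The ramuli chorii are unequally dichotomous: their branching topology is
drawn from lattice DLA aggregates (random walkers launched on a circle
around the cluster stick on first face contact).  The aggregate itself is
too ragged to serve as a branch axis, so it is thinned to a skeleton, the
skeleton is reduced to a tree of branching points and tips connected by
straight chords, and that chord tree is lifted into the ramuli z-slab:
radial distance from the cluster seed maps to depth (+z), so the deepest
tip of every model lands on the basal-plate side at z = 24.5 mm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize as _thin

from .tree_model import TIER_Z_BOUNDS


@dataclass
class DLAAggregate:
    """Connected set of lattice sites grown by DLA.

    ``positions`` holds the sites in attachment order, the seed first,
    as integer (n, 2) lattice coordinates relative to the seed.
    """

    positions: np.ndarray
    rng_seed: int

    @property
    def seed(self) -> np.ndarray:
        return self.positions[0]

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256(
            np.ascontiguousarray(self.positions.astype(np.int64)).tobytes()
        ).hexdigest()


@dataclass
class SkeletonTree:
    """Chord tree extracted from an aggregate: branching points and tips.

    ``nodes`` is (m, 2) float positions (lattice units, seed at index
    ``root``); ``edges`` is a list of (parent_node, child_node) index pairs.
    """

    nodes: np.ndarray
    edges: list[tuple[int, int]]
    root: int

    def n_edges(self) -> int:
        return len(self.edges)

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {i: [] for i in range(len(self.nodes))}
        for p, c in self.edges:
            out[p].append(c)
        return out


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

_STEPS = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=np.int64)


def grow_dla(
    n_particles: int,
    rng_seed: int,
    launch_margin: int = 5,
    kill_factor: float = 3.0,
    max_steps_per_walker: int = 2_000_000,
) -> DLAAggregate:
    """Grow a lattice DLA aggregate of ``n_particles`` + 1 sites.

    Walkers start uniformly on a circle of radius (cluster radius +
    ``launch_margin``), take unit lattice steps, are re-launched when they
    wander beyond ``kill_factor`` times the launch radius, and stick the
    first time they step onto a site face-adjacent to the cluster.
    Deterministic for a given ``rng_seed``.
    """
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    rng = np.random.default_rng(rng_seed)

    chunk = 256
    half = (
        int(math.ceil(kill_factor * (launch_margin + 4 * math.sqrt(n_particles + 1))))
        + chunk
        + 4
    )
    size = 2 * half + 1
    occupied = np.zeros((size, size), dtype=bool)
    sticky = np.zeros((size, size), dtype=bool)  # sites adjacent to the cluster

    def mark(p):
        occupied[p[0] + half, p[1] + half] = True
        for s in _STEPS:
            sticky[p[0] + s[0] + half, p[1] + s[1] + half] = True

    positions = [np.zeros(2, dtype=np.int64)]
    mark(positions[0])
    r_cluster = 0.0

    for _ in range(n_particles):
        r_launch = r_cluster + launch_margin
        r_kill = kill_factor * r_launch
        attached = False
        budget = max_steps_per_walker
        while not attached:
            if budget <= 0:
                raise RuntimeError(
                    f"walker budget exhausted after attaching {len(positions) - 1} particles"
                )
            phi = rng.uniform(0.0, 2.0 * math.pi)
            pos = np.array(
                [round(r_launch * math.cos(phi)), round(r_launch * math.sin(phi))],
                dtype=np.int64,
            )
            while True:
                steps = _STEPS[rng.integers(0, 4, size=chunk)]
                path = pos + np.cumsum(steps, axis=0)
                budget -= chunk
                dead = (path[:, 0] ** 2 + path[:, 1] ** 2) > r_kill * r_kill
                ii = np.clip(path[:, 0] + half, 0, size - 1)
                jj = np.clip(path[:, 1] + half, 0, size - 1)
                hits = sticky[ii, jj]
                stop = np.flatnonzero(dead | hits)
                if stop.size:
                    s = stop[0]
                    if hits[s] and not dead[s]:
                        p = path[s]
                        positions.append(p.copy())
                        mark(p)
                        r_cluster = max(r_cluster, float(np.hypot(p[0], p[1])))
                        attached = True
                    break  # dead walker: relaunch
                pos = path[-1]
                if budget <= 0:
                    break
    return DLAAggregate(positions=np.array(positions, dtype=np.int64), rng_seed=rng_seed)


def fractal_dimension(aggregate: DLAAggregate, method: str = "mass_radius") -> float:
    """Fractal dimension estimate of the aggregate.

    ``mass_radius`` (default) fits log N(r) vs log r, where N(r) is the
    number of particles within radius r of the seed, over r in
    [3, 0.6 R_max]; it is far less biased on small clusters than box
    counting, which underestimates markedly below ~10^4 particles.
    """
    pts = aggregate.positions.astype(float)
    if len(pts) < 50:
        raise ValueError("aggregate too small for a dimension estimate")
    if method == "mass_radius":
        r = np.hypot(pts[:, 0], pts[:, 1])
        radii = np.geomspace(3.0, max(r.max() * 0.6, 4.0), 10)
        n_within = np.array([(r <= x).sum() for x in radii], dtype=float)
        return float(np.polyfit(np.log(radii), np.log(n_within), 1)[0])
    if method == "box":
        span = int(max(pts.max() - pts.min(), 1)) + 1
        shifted = pts - pts.min(axis=0)
        sizes, counts = [], []
        s = 2
        while s <= max(span // 4, 2) and len(sizes) < 12:
            boxes = {(int(p[0] // s), int(p[1] // s)) for p in shifted}
            sizes.append(s)
            counts.append(len(boxes))
            s *= 2
        if len(sizes) < 2:
            raise ValueError("aggregate too small for box counting")
        return float(
            np.polyfit(-np.log(np.array(sizes, float)), np.log(np.array(counts, float)), 1)[0]
        )
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

def skeletonize(aggregate: DLAAggregate) -> SkeletonTree:
    """Reduce an aggregate to a chord tree of branching points and tips.

    The aggregate is thinned morphologically; the thinned pixels form an
    8-connected graph whose cycles (rare) are pruned to a minimum spanning
    tree; runs of degree-2 pixels are collapsed into straight chords
    between branching points (degree >= 3), tips (degree 1) and the root
    (the thinned pixel nearest the seed).
    """
    pts = aggregate.positions
    mins = pts.min(axis=0)
    img = np.zeros(tuple(pts.max(axis=0) - mins + 3), dtype=bool)
    img[pts[:, 0] - mins[0] + 1, pts[:, 1] - mins[1] + 1] = True
    skel = _thin(img)
    sk_pts = np.argwhere(skel)
    if len(sk_pts) == 0:  # thinning can erase a single-pixel aggregate
        sk_pts = np.argwhere(img)

    g = nx.Graph()
    index = {tuple(p): i for i, p in enumerate(sk_pts)}
    g.add_nodes_from(range(len(sk_pts)))
    for i, p in enumerate(sk_pts):
        for di, dj in ((1, 0), (0, 1)):
            j = index.get((p[0] + di, p[1] + dj))
            if j is not None:
                g.add_edge(i, j, weight=1.0)
    for i, p in enumerate(sk_pts):
        for di, dj in ((1, 1), (1, -1)):
            j = index.get((p[0] + di, p[1] + dj))
            if j is None:
                continue
            # skip a diagonal that merely shortcuts two orthogonal steps
            if (p[0] + di, p[1]) in index or (p[0], p[1] + dj) in index:
                continue
            g.add_edge(i, j, weight=math.sqrt(2.0))
    if g.number_of_edges() >= g.number_of_nodes():
        n_loops = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
        if n_loops > 0:
            warnings.warn(f"skeleton contained {n_loops} loop(s); pruned to a spanning tree")
        g = nx.minimum_spanning_tree(g)
    if not nx.is_connected(g):
        # keep the component containing the root pixel
        seed_px = aggregate.seed - mins + 1
        d2 = np.sum((sk_pts - seed_px) ** 2, axis=1)
        root_px = int(np.argmin(d2))
        comp = nx.node_connected_component(g, root_px)
        g = g.subgraph(comp).copy()
        keep = sorted(comp)
        relabel = {old: new for new, old in enumerate(keep)}
        g = nx.relabel_nodes(g, relabel)
        sk_pts = sk_pts[keep]

    seed_px = aggregate.seed - mins + 1
    d2 = np.sum((sk_pts - seed_px) ** 2, axis=1)
    root_px = int(np.argmin(d2))

    # keep root + branching points + tips; collapse degree-2 chains
    keep_px = {root_px} | {n for n in g.nodes if g.degree(n) != 2}
    node_ids: dict[int, int] = {}
    nodes: list[np.ndarray] = []
    for px in sorted(keep_px):
        node_ids[px] = len(nodes)
        nodes.append(sk_pts[px].astype(float))

    edges: list[tuple[int, int]] = []
    visited_px: set[int] = set()
    stack = [root_px]
    while stack:
        px = stack.pop()
        visited_px.add(px)
        for nb in sorted(g.neighbors(px)):
            if nb in visited_px:
                continue
            # walk the chain until the next kept pixel
            prev, cur = px, nb
            while cur not in keep_px:
                visited_px.add(cur)
                nxts = [q for q in g.neighbors(cur) if q != prev]
                if not nxts:
                    break
                prev, cur = cur, nxts[0]
            if cur in keep_px and cur != px:
                edges.append((node_ids[px], node_ids[cur]))
                visited_px.add(cur)
                stack.append(cur)

    # shift node coordinates back to seed-relative lattice units
    nodes_arr = np.array(nodes) - 1 + mins
    return SkeletonTree(nodes=nodes_arr, edges=edges, root=node_ids[root_px])


# ---------------------------------------------------------------------------
# lifting into the ramuli slab
# ---------------------------------------------------------------------------

def lift_to_3d(
    skeleton: SkeletonTree,
    z_range: tuple[float, float] = TIER_Z_BOUNDS["ramuli"],
    azimuth_deg: float = 0.0,
    lateral_scale_mm: float = 4.0,
) -> list[dict]:
    """Map a 2D chord tree into the ramuli z-slab, rooted at a rami tip.

    The skeleton's radial-distance-from-root coordinate maps linearly onto
    +z so the deepest node reaches ``z_range[1]`` exactly; the angular
    coordinate around the root becomes the lateral direction, scaled so
    lateral offsets stay within ``lateral_scale_mm`` of the attachment
    point.  Coordinates are returned relative to the attachment point as
    branch records ``{"start", "end", "parent_index"}``.
    """
    z_lo, z_hi = z_range
    rel = skeleton.nodes - skeleton.nodes[skeleton.root]
    radial = np.hypot(rel[:, 0], rel[:, 1])
    r_max = radial.max()
    if r_max == 0:
        raise ValueError("degenerate skeleton: all nodes at the root")
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    psi = math.radians(azimuth_deg)

    depth = (radial / r_max) * (z_hi - z_lo)
    lat = (radial / r_max) * lateral_scale_mm
    pts3 = np.column_stack(
        [lat * np.cos(ang + psi), lat * np.sin(ang + psi), depth]
    )
    pts3[skeleton.root] = 0.0

    records: list[dict] = []
    node_to_rec: dict[int, int] = {}
    children = skeleton.children()
    stack = [(skeleton.root, None)]
    while stack:
        node, parent_rec = stack.pop()
        for child in children[node]:
            rec = {
                "start": tuple(pts3[node]),
                "end": tuple(pts3[child]),
                "parent_index": parent_rec,
            }
            records.append(rec)
            node_to_rec[child] = len(records) - 1
            stack.append((child, len(records) - 1))
    return records
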