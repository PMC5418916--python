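"""Tree geometry: truncus profile, orders, bifurcation ratio, rasterization."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from villiwave import tree_model as tm


# ---------------------------------------------------------------------------
# truncus radius profile
# ---------------------------------------------------------------------------

class TestTruncusRadius:
    def test_endpoints(self):
        assert tm.truncus_radius(0.0) == pytest.approx(1.5)
        assert tm.truncus_radius(2.9) == pytest.approx(0.5)

    def test_midpoint_quarter_ellipse(self):
        # r(z_tr/2) = r_max - (r_max - r_min) * sqrt(3)/2
        assert tm.truncus_radius(1.45) == pytest.approx(1.5 - math.sqrt(3) / 2)

    def test_domain_error(self):
        with pytest.raises(tm.DomainError):
            tm.truncus_radius(-0.1)
        with pytest.raises(tm.DomainError):
            tm.truncus_radius(3.0)

    def test_monotone_nonincreasing(self):
        z = np.linspace(0.0, 2.9, 500)
        r = tm.truncus_radius(z)
        assert np.all(np.diff(r) <= 1e-12)
        assert np.all((r >= 0.5 - 1e-12) & (r <= 1.5 + 1e-12))

    def test_derivative_vanishes_at_boundary(self):
        # finite-difference slope at z_tr tends to 0 as the step shrinks
        slopes = [
            (tm.truncus_radius(2.9) - tm.truncus_radius(2.9 - h)) / h
            for h in (1e-2, 1e-4, 1e-6)
        ]
        assert abs(slopes[-1]) < 1e-2
        assert abs(slopes[-1]) < abs(slopes[0])
        assert tm.truncus_radius_derivative(2.9) == 0.0


# ---------------------------------------------------------------------------
# branch orders
# ---------------------------------------------------------------------------

def _brute_force_orders(children: dict[int, list[int]], root: int, convention: str):
    """Independent recursive labelling used as the ordering oracle."""
    centrifugal, centripetal = {}, {}

    def down(node, gen):
        centrifugal[node] = gen
        for c in children.get(node, []):
            down(c, gen + 1)

    def up(node):
        kids = children.get(node, [])
        if not kids:
            centripetal[node] = 1
            return 1
        orders = sorted(up(c) for c in kids)
        if convention == "horsfield":
            centripetal[node] = orders[-1] + 1
        elif len(orders) >= 2 and orders[-2] == orders[-1]:
            centripetal[node] = orders[-1] + 1
        else:
            centripetal[node] = orders[-1]
        return centripetal[node]

    down(root, 1)
    up(root)
    return centripetal, centrifugal


def _tree_from_children(children: dict[int, list[int]], root: int = 0) -> tm.VillousTree:
    axis = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    diam = np.array([0.4, 0.4])
    tree = tm.VillousTree()
    parent_of = {c: p for p, kids in children.items() for c in kids}
    order = [root]
    seen = {root}
    while order:
        nid = order.pop(0)
        tree.branches[nid] = tm.Branch(
            id=nid, tier="ramuli", axis=axis, diameters=diam,
            parent=parent_of.get(nid), children=list(children.get(nid, [])),
        )
        for c in children.get(nid, []):
            if c not in seen:
                seen.add(c)
                order.append(c)
    return tree


def _random_children(rng, n_nodes: int) -> dict[int, list[int]]:
    children: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for i in range(1, n_nodes):
        children[int(rng.integers(0, i))].append(i)
    return children


class TestAssignOrders:
    def test_complete_binary_four_generations(self, default_tree):
        """The rami tier is a complete binary tree: tips u=1, C_f = 4."""
        trunks = default_tree.branches[default_tree.root_id].children
        for trunk in trunks:
            sub = [
                b for b in default_tree.subtree_ids(trunk)
                if default_tree.branches[b].tier == "rami"
            ]
            orders = tm.assign_orders(default_tree, root=trunk, subtree=sub)
            tips = [b for b in sub if not any(
                c in sub for c in default_tree.branches[b].children)]
            assert all(orders.centripetal[t] == 1 for t in tips)
            assert orders.centripetal[trunk] == 4
            assert all(orders.centrifugal[t] == 4 for t in tips)

    def test_single_branch(self):
        tree = _tree_from_children({0: []})
        orders = tm.assign_orders(tree)
        assert orders.centripetal[0] == 1 and orders.centrifugal[0] == 1

    def test_caterpillar_hand_walked(self):
        # spine 0-1-2 with one side tip per spine node
        children = {0: [1, 3], 1: [2, 4], 2: [5], 3: [], 4: [], 5: []}
        tree = _tree_from_children(children)
        orders = tm.assign_orders(tree)  # strahler
        assert orders.centripetal == {5: 1, 4: 1, 3: 1, 2: 1, 1: 2, 0: 2}
        assert orders.centrifugal == {0: 1, 1: 2, 3: 2, 2: 3, 4: 3, 5: 4}
        horsfield = tm.assign_orders(tree, convention="horsfield")
        assert horsfield.centripetal == {5: 1, 4: 1, 3: 1, 2: 2, 1: 3, 0: 4}

    @pytest.mark.parametrize("convention", ["strahler", "horsfield"])
    def test_agrees_with_brute_force_on_random_trees(self, convention):
        rng = np.random.default_rng(7)
        for n_nodes in range(2, 11):
            for _ in range(20):
                children = _random_children(rng, n_nodes)
                tree = _tree_from_children(children)
                got = tm.assign_orders(tree, convention=convention)
                want_cp, want_cf = _brute_force_orders(children, 0, convention)
                assert got.centripetal == want_cp
                assert got.centrifugal == want_cf

    def test_cycle_raises(self):
        tree = _tree_from_children({0: [1], 1: []})
        tree.branches[1].children = [0]  # corrupt into a cycle
        with pytest.raises(tm.StructureError):
            tm.assign_orders(tree, root=0, subtree=[0, 1])


# ---------------------------------------------------------------------------
# bifurcation ratio
# ---------------------------------------------------------------------------

class TestBifurcationRatio:
    def test_equal_dichotomy(self):
        assert tm.estimate_bifurcation_ratio([8, 4, 2, 1]) == pytest.approx(2.0)

    def test_exact_geometric_series(self):
        assert tm.estimate_bifurcation_ratio([9, 3, 1]) == pytest.approx(3.0)

    def test_non_geometric_least_squares(self):
        # through-origin fit: slope = (2 ln10 + 1 ln4) / (4 + 1)
        want = math.exp((2 * math.log(10) + math.log(4)) / 5)
        assert tm.estimate_bifurcation_ratio([10, 4, 1]) == pytest.approx(want)

    def test_single_order_raises(self):
        with pytest.raises(ValueError):
            tm.estimate_bifurcation_ratio([5])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        ratio=st.floats(min_value=1.05, max_value=9.5),
        u_max=st.integers(min_value=2, max_value=8),
    )
    def test_recovers_any_geometric_series(self, ratio, u_max):
        counts = {u: ratio ** (u_max - u) for u in range(1, u_max + 1)}
        assert tm.estimate_bifurcation_ratio(counts) == pytest.approx(
            ratio, rel=1e-9
        )


# ---------------------------------------------------------------------------
# rami construction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def rami_tree():
    tree = tm.VillousTree()
    tree.add(tm.build_truncus())
    tm.build_rami_subtrees(tree)
    return tree


class TestRamiTier:
    def test_sixteen_tips_at_the_ramuli_boundary(self, rami_tree):
        tips = [b for b in rami_tree.branches.values()
                if b.tier == "rami" and not b.children]
        assert len(tips) == 16
        for b in tips:
            assert b.axis[-1, 2] == pytest.approx(13.5, abs=1e-9)

    def test_branch_points_at_z_stations(self, rami_tree):
        starts = sorted({round(float(b.axis[0, 2]), 6)
                         for b in rami_tree.branches.values() if b.tier == "rami"})
        assert starts == [2.9, 3.9, 4.7, 5.8]

    def test_bifurcation_ratio_is_two(self, rami_tree):
        trunk = rami_tree.branches[rami_tree.root_id].children[0]
        orders = tm.assign_orders(rami_tree, root=trunk)
        assert tm.estimate_bifurcation_ratio(orders.counts()) == pytest.approx(2.0)

    def test_junction_continuity(self, rami_tree):
        for b in rami_tree.branches.values():
            if b.parent is None:
                continue
            parent = rami_tree.branches[b.parent]
            assert np.allclose(b.axis[0], parent.axis[-1], atol=1e-9)
            assert b.diameters[0] == pytest.approx(parent.diameters[-1], abs=1e-9)

    def test_diameters_taper_within_range(self, rami_tree):
        for b in rami_tree.branches.values():
            if b.tier != "rami":
                continue
            lo, hi = tm.TIER_DIAMETERS["rami"]
            assert lo - 1e-9 <= b.diameters.min() <= b.diameters.max() <= hi + 1e-9
            assert np.all(np.diff(b.diameters) <= 1e-12)  # decreasing distally


class TestRamuliTier:
    def test_deepest_point_reaches_the_basal_plate(self, default_tree):
        assert default_tree.max_z() == pytest.approx(24.5, abs=1e-9)

    def test_tier_z_ranges(self, default_tree):
        for b in default_tree.branches.values():
            lo, hi = tm.TIER_Z_BOUNDS[b.tier]
            assert b.axis[:, 2].min() >= lo - 1e-9
            assert b.axis[:, 2].max() <= hi + 1e-9

    def test_tip_generations_within_reported_range(self, default_tree):
        gens = []
        for tid in _ramuli_roots(default_tree):
            orders = tm.assign_orders(default_tree, root=tid)
            gens.append(max(
                v - 1 for k, v in orders.centrifugal.items()
                if not default_tree.branches[k].children))
        assert all(4 <= g <= 20 for g in gens)

    def test_bifurcation_ratios_dispersed_above_two(self, default_tree):
        """Unequal dichotomy: per-subtree R_b spreads over the reported band."""
        rbs = []
        for tid in _ramuli_roots(default_tree):
            orders = tm.assign_orders(default_tree, root=tid)
            counts = orders.counts()
            u_root = orders.centripetal[tid]
            counts[u_root] -= 1  # drop the rami tip branch itself
            if counts[u_root] == 0:
                del counts[u_root]
            rbs.append(tm.estimate_bifurcation_ratio(counts))
        assert all(2.0 < rb < 8.0 for rb in rbs)
        assert max(rbs) - min(rbs) > 0.2  # genuinely dispersed

    def test_diameter_order_map_endpoints(self, default_tree):
        for tid in _ramuli_roots(default_tree):
            orders = tm.assign_orders(default_tree, root=tid)
            sub = default_tree.subtree_ids(tid)
            tips = [b for b in sub if not default_tree.branches[b].children]
            for t in tips:
                assert default_tree.branches[t].diameters[-1] == pytest.approx(0.3)
            ramuli_roots = [b for b in sub
                            if default_tree.branches[b].tier == "ramuli"
                            and default_tree.branches[default_tree.branches[b].parent].tier == "rami"]
            for r in ramuli_roots:
                assert default_tree.branches[r].diameters[0] == pytest.approx(0.5)

    def test_rebuild_is_bit_identical(self, default_tree, default_config):
        again = __import__("villiwave").pipeline.build_default_tree(default_config)
        assert again.to_json() == default_tree.to_json()

    def test_json_round_trip(self, default_tree):
        clone = tm.VillousTree.from_json(default_tree.to_json())
        assert set(clone.branches) == set(default_tree.branches)
        b0 = default_tree.branches[0]
        c0 = clone.branches[0]
        assert np.allclose(b0.axis, c0.axis, atol=1e-6)
        assert c0.tier == "truncus"


def _ramuli_roots(tree):
    """Rami tips that carry a ramuli subtree."""
    return sorted(
        b.id for b in tree.branches.values()
        if b.tier == "rami" and b.children
        and all(tree.branches[c].tier == "ramuli" for c in b.children)
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _capsule_tree(radius=0.5, length=2.9):
    """Single straight z-aligned branch (rasterized as a capsule)."""
    n = 30
    z = np.linspace(2.0, 2.0 + length, n)
    axis = np.column_stack([np.full(n, 4.0), np.full(n, 4.0), z])
    tree = tm.VillousTree()
    tree.branches[0] = tm.Branch(
        id=0, tier="ramuli", axis=axis, diameters=np.full(n, 2 * radius))
    return tree


class TestRasterize:
    def test_capsule_volume_oracle(self):
        """Occupied count matches the analytic capsule volume within 2%."""
        radius, length, pix = 0.5, 2.9, 29.0
        grid = tm.rasterize_tree(_capsule_tree(radius, length), pix)
        want = (math.pi * radius**2 * length + 4 / 3 * math.pi * radius**3) / (
            (pix / 1000.0) ** 3
        )
        assert grid.occupancy.sum() == pytest.approx(want, rel=0.02)

    def test_count_scales_with_pixel_size(self):
        tree = _capsule_tree()
        n1 = tm.rasterize_tree(tree, 58.0).occupancy.sum()
        n2 = tm.rasterize_tree(tree, 116.0).occupancy.sum()
        assert n1 / n2 == pytest.approx(8.0, rel=0.05)

    def test_empty_tree_gives_empty_grid(self):
        grid = tm.rasterize_tree(tm.VillousTree(), 290.0)
        assert not grid.occupancy.any()

    def test_reference_resolution_dims(self):
        assert tm.grid_dims(29.0) == (1200, 1200, 847)
        assert tm.model_extent_mm(1200, 29.0) == pytest.approx(34.8)

    def test_memory_budget_error(self):
        with pytest.raises(MemoryError):
            tm.rasterize_tree(tm.VillousTree(), 29.0, max_voxels=1e6)

    def test_default_tree_is_one_connected_component(self, default_grid):
        from scipy import ndimage

        _, n = ndimage.label(default_grid.occupancy)
        assert n == 1
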