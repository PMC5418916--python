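"""Shared fixtures: the default coarse model is built once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from villiwave import contraction, pipeline, tree_model, wavefield


@pytest.fixture(scope="session")
def default_config() -> pipeline.RunConfig:
    return pipeline.RunConfig(save_volumes=False)


@pytest.fixture(scope="session")
def default_tree(default_config):
    """Full three-tier tree with the 16 default-seeded DLA ramuli."""
    return pipeline.build_default_tree(default_config)


@pytest.fixture(scope="session")
def default_grid(default_tree, default_config):
    """Default tree rasterized at the 116 um/pixel working resolution."""
    return tree_model.rasterize_tree(default_tree, default_config.pixel_size_um)


@pytest.fixture(scope="session")
def default_surface(default_grid, default_tree, default_config):
    return contraction.build_surface(default_grid, default_tree, default_config.profile())


@pytest.fixture(scope="session")
def default_distance(default_grid, default_surface):
    """Distance/source volumes at the largest studied cutoff (shared)."""
    return wavefield.distance_transform(
        default_grid, max(wavefield.D_MAX_MM), default_surface, slab_nz=32
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def make_single_source_grid(n: int = 41, pixel_size_um: float = 72.5):
    """Grid with one occupied center voxel whose surface contracts along -z."""
    occ = np.zeros((n, n, n), dtype=bool)
    c = n // 2
    occ[c, c, c] = True
    grid = tree_model.VoxelGrid(occupancy=occ, pixel_size_um=pixel_size_um)
    surface = contraction.extract_surface(grid)
    surface.directions = np.array([[0.0, 0.0, -1.0]])
    surface.branch_id = np.array([0])
    return grid, surface


@pytest.fixture()
def single_source():
    return make_single_source_grid()
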