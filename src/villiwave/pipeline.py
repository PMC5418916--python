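"""Run configuration and the end-to-end pipeline driver.

``run_pipeline`` composes the stages: build the villous tree (geometry +
seeded DLA ramuli), rasterize it, extract the contracting surface, compute
the displacement field for the selected wave condition(s), and write the
per-slice statistics and characteristic positions.  Re-running with the
same configuration is bit-identical for volumes and JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, contraction, dla, io_utils, tree_model, wavefield
from .tree_model import TruncusProfile, VillousTree
from .wavefield import WaveParams

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    The defaults reproduce the reference parameterization at a coarse
    working resolution of 116 um/pixel (dims 300 x 300 x 212); the
    reference resolution of 29 um/pixel (1200 x 1200 x 847) is selected
    with ``pixel_size_um=29`` plus a raised ``max_voxels`` and slab
    streaming.
    """

    pixel_size_um: float = 116.0
    # truncus radius profile (mm)
    r_max: float = 1.5
    r_min: float = 0.5
    z_tr: float = 2.9
    # ramuli topology source
    master_seed: int = 0
    n_particles: int = 400
    lateral_scale_mm: float = 4.0
    # wave condition: a label like "lambda=1.45_dmax=4.35",
    # "lambda=increasing_dmax=2.9", or "all"
    condition: str = "lambda=1.45_dmax=4.35"
    xi0_um: float = 0.1
    nu_hz: float = 1.0
    rho_kg_m3: float = 1000.0
    # execution
    out_dir: str = "runs/default"
    save_volumes: bool = True
    slab_nz: int | None = 32
    max_voxels: float = 1.5e9

    # -- condition handling -------------------------------------------------
    def base_params(self) -> WaveParams:
        return WaveParams(
            xi0_um=self.xi0_um, nu_hz=self.nu_hz, rho_kg_m3=self.rho_kg_m3
        )

    def conditions(self) -> list[WaveParams]:
        if self.condition == "all":
            return wavefield.enumerate_conditions(self.base_params())
        return [parse_condition(self.condition, self.base_params())]

    def dla_seeds(self) -> list[int]:
        return [self.master_seed * 16 + i + 1 for i in range(16)]

    def profile(self) -> TruncusProfile:
        return TruncusProfile(r_max=self.r_max, r_min=self.r_min, z_tr=self.z_tr)

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text)
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def parse_condition(label: str, base: WaveParams = WaveParams()) -> WaveParams:
    """Parse 'lambda=<mm|increasing>_dmax=<mm>' into WaveParams."""
    try:
        lam_part, d_part = label.replace("mm", "").split("_")
        lam_s = lam_part.split("=")[1]
        lam: float | str = lam_s if lam_s == wavefield.INCREASING else float(lam_s)
        d_max = float(d_part.split("=")[1])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse condition label {label!r}") from exc
    return dataclasses.replace(base, lambda_profile=lam, d_max_mm=d_max)


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def build_default_tree(config: RunConfig = RunConfig()) -> VillousTree:
    """Build the full three-tier tree with seeded DLA ramuli.

    A DLA skeleton with fewer than 2 branches is regenerated with the
    seed advanced by 1000 (deterministic fallback).
    """
    tree = VillousTree()
    tree.add(tree_model.build_truncus(config.profile()))
    tree_model.build_rami_subtrees(tree)
    rami_tips = sorted(b for b in tree.tips() if tree.branches[b].tier == "rami")
    center = tree.branches[tree.root_id].axis[0][:2]
    lifted = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # routine skeleton-loop pruning
        for tid, seed in zip(rami_tips, config.dla_seeds()):
            while True:
                aggregate = dla.grow_dla(config.n_particles, seed)
                skeleton = dla.skeletonize(aggregate)
                if skeleton.n_edges() >= 2:
                    break
                seed += 1000
            tip = tree.branches[tid].axis[-1]
            azimuth = float(
                np.degrees(np.arctan2(tip[1] - center[1], tip[0] - center[0]))
            )
            lifted.append(
                dla.lift_to_3d(
                    skeleton,
                    azimuth_deg=azimuth,
                    lateral_scale_mm=config.lateral_scale_mm,
                )
            )
    tree_model.build_ramuli_subtrees(tree, lifted)
    return tree


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write artifacts under ``config.out_dir``.

    Returns a manifest dict (also written as JSON) with artifact paths,
    their hashes and the per-condition characteristic positions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sentinel = out / ".failed"
    if sentinel.exists():
        sentinel.unlink()
    try:
        manifest = _run_pipeline(config, out)
    except Exception as exc:
        sentinel.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return manifest


def _run_pipeline(config: RunConfig, out: Path) -> dict:
    t_start = time.perf_counter()
    config.to_yaml(out / "config.yaml")
    artifacts: dict[str, str] = {"config": "config.yaml"}

    log.info("building villous tree (master seed %d)", config.master_seed)
    tree = build_default_tree(config)
    tree.to_json(out / "tree.json")
    artifacts["tree"] = "tree.json"

    log.info("rasterizing at %.0f um/pixel", config.pixel_size_um)
    grid = tree_model.rasterize_tree(
        tree, config.pixel_size_um, max_voxels=config.max_voxels
    )
    log.info("grid %s, %d occupied voxels", grid.dims, int(grid.occupancy.sum()))
    if config.save_volumes:
        io_utils.write_tiff(grid.occupancy, out / "occupancy.tif", config.pixel_size_um)
        io_utils.write_nifti(grid.occupancy, out / "occupancy.nii.gz", config.pixel_size_um)
        artifacts["occupancy_tiff"] = "occupancy.tif"
        artifacts["occupancy_nifti"] = "occupancy.nii.gz"

    surface = contraction.build_surface(grid, tree, config.profile())
    surface.to_dataframe().to_csv(out / "surface.csv", index=False)
    artifacts["surface"] = "surface.csv"
    log.info("surface: %d elements", len(surface))

    conditions = config.conditions()
    d_max_all = max(p.d_max_mm for p in conditions)
    log.info("distance transform (d_max %.2f mm)", d_max_all)
    distance, source = wavefield.distance_transform(
        grid, d_max_all, surface, slab_nz=config.slab_nz
    )

    summary: dict = {
        "config_hash": config.content_hash(),
        "grid_dims": list(grid.dims),
        "pixel_size_um": config.pixel_size_um,
        "n_branches": len(tree.branches),
        "max_z_mm": tree.max_z(),
        "n_surface_elements": len(surface),
        "conditions": {},
    }
    for params in conditions:
        t0 = time.perf_counter()
        fld = wavefield.displacement_field(distance, source, surface, params, grid)
        polar = analysis.polar_of_field(fld)
        table = analysis.slice_stats(polar)
        positions = analysis.find_characteristic_positions(table)
        tag = params.label
        table.to_csv(out / f"stats_{tag}.csv", index=False)
        artifacts[f"stats_{tag}"] = f"stats_{tag}.csv"
        if config.save_volumes:
            io_utils.write_vector_nifti(
                fld.vectors, out / f"displacement_{tag}.nii.gz", config.pixel_size_um
            )
            artifacts[f"displacement_{tag}"] = f"displacement_{tag}.nii.gz"
        summary["conditions"][tag] = {
            "lambda_profile": params.lambda_profile,
            "d_max_mm": params.d_max_mm,
            "mu_pa": params.mu_pa,
            "displaced_voxels": int(fld.displaced.sum()),
            "positions": positions.as_dict(),
            "seconds": round(time.perf_counter() - t0, 2),
        }
        log.info("condition %s done in %.1fs", tag, time.perf_counter() - t0)

    io_utils.write_json(summary, out / "summary.json")
    artifacts["summary"] = "summary.json"
    manifest = {
        "config_hash": summary["config_hash"],
        "seconds_total": round(time.perf_counter() - t_start, 2),
        "artifacts": {
            name: {"path": rel, "sha256": io_utils.sha256_of(out / rel)}
            for name, rel in artifacts.items()
        },
    }
    io_utils.write_json(manifest, out / "manifest.json")
    return manifest
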