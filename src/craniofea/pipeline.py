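"""End-to-end suite orchestration.

Each suite builds its scenarios for every model, solves them, summarises
the fields with the trimmed statistics, and returns (and optionally
writes) a long-format comparison table.  These functions are what the CLI
commands, the numbered analysis scripts and the acceptance checks all
call, so a table produced anywhere is produced the same way everywhere.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .fem import solve
from .mesh import TetMesh, validate_mesh, volume
from .postprocess import comparison_table, export_contour, summarize
from .scenarios import (
    Scenario,
    apply_rhamphotheca,
    build_bending_scenario,
    build_bite_scenario,
    build_extrinsic_scenario,
    scaled_bending_forces,
)

__all__ = [
    "run_validate",
    "run_bending_suite",
    "run_bite_suite",
    "run_extrinsic_suite",
    "run_scenarios",
    "merge_reports",
    "write_outputs",
]


def _v_refs(cfg: RunConfig, meshes: dict[str, TetMesh]) -> dict[str, float]:
    vols = {name: volume(m) for name, m in meshes.items()}
    if cfg.v_ref_rule == "smallest":
        v = min(vols.values())
        return {name: v for name in vols}
    return vols


def run_validate(cfg: RunConfig) -> dict[str, object]:
    """Validate every configured model; returns name -> ValidationReport."""
    return {name: validate_mesh(m) for name, m in cfg.build_models().items()}


def run_scenarios(
    cfg: RunConfig,
    meshes: dict[str, TetMesh],
    scenarios: dict[str, list[Scenario]],
    out_dir: Path | None = None,
) -> pd.DataFrame:
    """Solve and summarise a prebuilt model -> scenarios mapping."""
    v_refs = _v_refs(cfg, meshes)
    runs = {}
    for name, scen_list in scenarios.items():
        mesh = meshes[name]
        for scen in scen_list:
            sol = solve(mesh, cfg.materials, scen.load_case)
            runs[(name, scen)] = summarize(
                sol, mesh, v_refs[name], cfg.trim_fraction
            )
            if out_dir is not None:
                export_contour(
                    mesh, sol, out_dir / f"{name}_{scen.name}.vtk", scenario=scen
                )
    return comparison_table(runs)


def run_bending_suite(
    cfg: RunConfig, out_dir: Path | None = None
) -> pd.DataFrame:
    """Scaled comparative bending over every model, position and laterality."""
    meshes = cfg.build_models()
    order = list(meshes)
    forces = scaled_bending_forces(
        [meshes[n] for n in order], base_force=cfg.base_force
    )
    scenarios = {
        name: [
            build_bending_scenario(meshes[name], pos, lat, float(forces[i]))
            for pos in cfg.positions
            for lat in cfg.lateralities
        ]
        for i, name in enumerate(order)
    }
    return run_scenarios(cfg, meshes, scenarios, out_dir)


def run_bite_suite(cfg: RunConfig, out_dir: Path | None = None) -> pd.DataFrame:
    """Muscle-driven biting over every model, position and laterality."""
    meshes = cfg.build_models()
    scenarios = {
        name: [
            build_bite_scenario(mesh, cfg.muscles, pos, lat)
            for pos in cfg.positions
            for lat in cfg.lateralities
        ]
        for name, mesh in meshes.items()
    }
    return run_scenarios(cfg, meshes, scenarios, out_dir)


def run_extrinsic_suite(
    cfg: RunConfig, out_dir: Path | None = None
) -> pd.DataFrame:
    """Head-pull / head-shake / head-twist, plus rhamphotheca variants.

    When the config declares a keratin material and a rhamphotheca region,
    every model is additionally run with the overlay applied, under the
    model name suffixed ``+rham``.
    """
    meshes = cfg.build_models()
    if cfg.keratin is not None and cfg.rhamphotheca_region is not None:
        for name in list(meshes):
            meshes[f"{name}+rham"] = apply_rhamphotheca(
                meshes[name], cfg.rhamphotheca_region, cfg.keratin
            )
    scenarios = {
        name: [
            build_extrinsic_scenario(mesh, kind, cfg.extrinsic_force)
            for kind in cfg.extrinsic_kinds
        ]
        for name, mesh in meshes.items()
    }
    return run_scenarios(cfg, meshes, scenarios, out_dir)


def write_outputs(
    df: pd.DataFrame, out_dir: Path, stem: str, cfg: RunConfig
) -> Path:
    """Write a suite table as CSV plus a reproducibility manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    df.to_csv(csv_path, index=False, float_format="%.12g")
    manifest = {
        "suite": stem,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "craniofea": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        "rows": int(len(df)),
    }
    with open(out_dir / f"{stem}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return csv_path


def merge_reports(run_dir: Path) -> pd.DataFrame:
    """Merge every suite CSV in a run directory into one comparison table."""
    frames = []
    for csv_path in sorted(Path(run_dir).glob("*.csv")):
        if csv_path.stem == "comparison_table":
            continue
        df = pd.read_csv(csv_path)
        if not {"model", "scenario"} <= set(df.columns):
            continue  # auxiliary table, not a suite report
        df.insert(0, "suite", csv_path.stem)
        frames.append(df)
    if not frames:
        raise FileNotFoundError(f"no suite CSVs found in {run_dir}")
    merged = pd.concat(frames, ignore_index=True)
    return merged.sort_values(
        ["suite", "model", "scenario"], kind="stable"
    ).reset_index(drop=True)
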