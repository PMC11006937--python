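"""Run configuration: the declarative description of a scenario suite.

A YAML file names the materials (moduli in GPa, converted to MPa on load),
the models (synthetic toy-skull specs and/or INP mesh paths, each with an
optional uniform scale), the muscle table, the protocol parameters
(baseline bending force, extrinsic force, trim fraction, reference-volume
rule) and the output directory.  Everything downstream is a pure function
of this object, which is what makes reruns byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as mesh_io
from .materials import Material
from .mesh import TetMesh, scale_mesh
from .scenarios import MuscleLoad
from .synthetic import ToySkullSpec, make_toy_skull

__all__ = ["RunConfig", "ModelSpec", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unresolvable run configuration."""


@dataclass(frozen=True)
class ModelSpec:
    """One model: either a mesh file path or a synthetic toy-skull spec."""

    name: str
    path: str | None = None
    synthetic: ToySkullSpec | None = None
    scale: float = 1.0

    def build(self, base_dir: Path) -> TetMesh:
        if (self.path is None) == (self.synthetic is None):
            raise ConfigError(
                f"model {self.name!r} must give exactly one of 'path' or 'synthetic'"
            )
        if self.path is not None:
            p = Path(self.path)
            if not p.is_absolute():
                p = base_dir / p
            if not p.exists():
                raise ConfigError(f"model {self.name!r}: file {p} does not exist")
            mesh = mesh_io.read_mesh(p)
        else:
            mesh = make_toy_skull(self.synthetic)
        return scale_mesh(mesh, self.scale) if self.scale != 1.0 else mesh


@dataclass
class RunConfig:
    """Validated run configuration."""

    materials: dict[str, Material]
    models: list[ModelSpec]
    muscles: list[MuscleLoad] = field(default_factory=list)
    positions: list[str] = field(default_factory=lambda: ["anterior", "mid", "posterior"])
    lateralities: list[str] = field(default_factory=lambda: ["bilateral", "unilateral_left"])
    extrinsic_kinds: list[str] = field(default_factory=lambda: ["pull", "shake", "twist"])
    base_force: float = 100.0  # N, bending baseline on the smallest model
    extrinsic_force: float = 100.0  # N
    trim_fraction: float = 0.05
    v_ref_rule: str = "smallest"  # smallest | own
    rhamphotheca_region: str | None = None
    keratin: Material | None = None
    seed: int = 0
    output: str = "results"
    base_dir: Path = field(default_factory=Path.cwd)
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.models:
            raise ConfigError("at least one model is required")
        if not (0.0 <= self.trim_fraction < 1.0):
            raise ConfigError("trim_fraction must lie in [0, 1)")
        if not self.base_force > 0:
            raise ConfigError("base_force must be positive")
        if self.v_ref_rule not in ("smallest", "own"):
            raise ConfigError("v_ref rule must be 'smallest' or 'own'")
        names = [m.name for m in self.models]
        if len(set(names)) != len(names):
            raise ConfigError("model names must be unique")

    def build_models(self) -> dict[str, TetMesh]:
        """Instantiate every model, preserving declaration order."""
        return {m.name: m.build(self.base_dir) for m in self.models}

    def config_hash(self) -> str:
        """Stable hash of the raw configuration (run manifests)."""
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _parse_material(name: str, entry: dict) -> Material:
    if "E_GPa" in entry:
        return Material.from_gpa(name, float(entry["E_GPa"]), float(entry["nu"]))
    if "E_MPa" in entry:
        return Material(name, float(entry["E_MPa"]), float(entry["nu"]))
    raise ConfigError(f"material {name!r} needs E_GPa or E_MPa")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        materials = {
            name: _parse_material(name, entry)
            for name, entry in raw.get("materials", {}).items()
        }
        models = []
        for m in raw.get("models", []):
            syn = None
            if "synthetic" in m:
                s = dict(m["synthetic"])
                if "resolution" in s:
                    s["resolution"] = tuple(int(v) for v in s["resolution"])
                syn = ToySkullSpec(**s)
            models.append(
                ModelSpec(
                    name=m["name"],
                    path=m.get("path"),
                    synthetic=syn,
                    scale=float(m.get("scale", 1.0)),
                )
            )
        muscles = [
            MuscleLoad(
                name=m["name"],
                side=m["side"],
                origin_set=m["origin_set"],
                insertion_point=tuple(float(v) for v in m["insertion"]),
                force=float(m["force_N"]),
            )
            for m in raw.get("muscles", [])
        ]
        keratin = None
        if "keratin" in raw:
            keratin = _parse_material("keratin", raw["keratin"])
        cfg = RunConfig(
            materials=materials,
            models=models,
            muscles=muscles,
            positions=list(raw.get("positions", ["anterior", "mid", "posterior"])),
            lateralities=list(
                raw.get("lateralities", ["bilateral", "unilateral_left"])
            ),
            extrinsic_kinds=list(raw.get("extrinsic_kinds", ["pull", "shake", "twist"])),
            base_force=float(raw.get("base_force_N", 100.0)),
            extrinsic_force=float(raw.get("extrinsic_force_N", 100.0)),
            trim_fraction=float(raw.get("trim_fraction", 0.05)),
            v_ref_rule=str(raw.get("v_ref", "smallest")),
            rhamphotheca_region=raw.get("rhamphotheca_region"),
            keratin=keratin,
            seed=int(raw.get("seed", 0)),
            output=str(raw.get("output", "results")),
            base_dir=path.parent.resolve(),
            raw=raw,
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"{path}: {exc}") from exc
    if keratin is not None:
        cfg.materials.setdefault("keratin", keratin)
    return cfg
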