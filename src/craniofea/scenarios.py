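"""Construction of the comparative load cases.

Three protocols are built here:

* **Scaled bending** — a non-physiological strength test: a dorsally
  directed load, perpendicular to the palate, applied at the anterior,
  mid, or posterior palate bite position (bilaterally, or unilaterally on
  the left).  Loads are scaled with cranial surface area from a baseline of
  100 N on the smallest model so every model carries the same relative
  load, making the comparison size-independent (stress scales with area).
* **Muscle-driven biting** — each jaw adductor muscle's contraction force
  divided across eight origin-site nodes, directed toward its insertion;
  the bite point is a vertical (Z) displacement constraint whose reaction
  is the bite force.
* **Extrinsic head movements** — pull (posterior), shake (lateral) and
  twist (a torsion couple) applied at the beak tip.

All protocols share the posterior constraint layout: four nodes on each
quadrate articular surface and three on the occipital condyle, fixed in
all axes.  Node selection within a set is deterministic: the k members
nearest the set centroid, ties broken by node index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import LoadCase, SolutionField
from .materials import Material
from .mesh import MeshError, TetMesh, surface_area

__all__ = [
    "Scenario",
    "MuscleLoad",
    "ScenarioError",
    "scaled_bending_forces",
    "build_bending_scenario",
    "muscle_nodal_loads",
    "build_bite_scenario",
    "bite_reaction",
    "build_extrinsic_scenario",
    "apply_rhamphotheca",
]

POSITIONS = ("anterior", "mid", "posterior")
LATERALITIES = ("bilateral", "unilateral_left")
QUADRATE_NODES = 4  # fully constrained nodes per quadrate articular patch
OCCIPITAL_NODES = 3  # fully constrained nodes on the occipital condyle
MUSCLE_NODES = 8  # loaded nodes per muscle per side


class ScenarioError(ValueError):
    """A scenario cannot be built from this mesh/configuration."""


@dataclass(eq=False)  # identity-hashable: scenarios key comparison tables
class Scenario:
    """A named load case with its comparative metadata."""

    name: str
    load_case: LoadCase
    kind: str  # bending | bite | pull | shake | twist
    position: str = "none"  # anterior | mid | posterior | none
    laterality: str = "bilateral"
    total_applied_force: float = 0.0  # N, magnitude sum of point loads
    bite_nodes: tuple[int, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class MuscleLoad:
    """One jaw adductor muscle on one side.

    The contraction force (N) acts from ``origin_set`` nodes toward a
    single ``insertion_point`` (mm) — the line of action is inherited from
    volumetric muscle reconstruction, so the insertion is an input, not
    computed.
    """

    name: str
    side: str  # "L" | "R"
    origin_set: str
    insertion_point: tuple[float, float, float]
    force: float  # N

    def __post_init__(self) -> None:
        if self.force < 0:
            raise ValueError("muscle force must be non-negative")
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")


def _get_set(mesh: TetMesh, name: str) -> np.ndarray:
    try:
        return mesh.node_sets[name]
    except KeyError:
        raise ScenarioError(f"mesh is missing required node set {name!r}") from None


def _nearest_centroid(mesh: TetMesh, indices: np.ndarray, k: int) -> np.ndarray:
    """The k set members nearest the set centroid, ties broken by index."""
    pts = mesh.nodes[indices]
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    order = np.lexsort((indices, d))
    return indices[order[:k]]


def _posterior_constraints(mesh: TetMesh) -> list[tuple[int, tuple[bool, bool, bool]]]:
    """4 + 4 quadrate nodes and 3 occipital-condyle nodes, fixed in all axes."""
    constraints = []
    for side in ("L", "R"):
        qset = _get_set(mesh, f"quadrate_{side}")
        if len(qset) < QUADRATE_NODES:
            raise ScenarioError(
                f"quadrate_{side} has {len(qset)} nodes; {QUADRATE_NODES} required"
            )
        for n in _nearest_centroid(mesh, qset, QUADRATE_NODES):
            constraints.append((int(n), (True, True, True)))
    occ = _get_set(mesh, "occipital")
    if len(occ) < OCCIPITAL_NODES:
        raise ScenarioError(
            f"occipital has {len(occ)} nodes; {OCCIPITAL_NODES} required"
        )
    for n in _nearest_centroid(mesh, occ, OCCIPITAL_NODES):
        constraints.append((int(n), (True, True, True)))
    return constraints


def _palate_sets(mesh: TetMesh, position: str, laterality: str) -> list[np.ndarray]:
    if position not in POSITIONS:
        raise ScenarioError(f"position must be one of {POSITIONS}, got {position!r}")
    if laterality not in LATERALITIES:
        raise ScenarioError(
            f"laterality must be one of {LATERALITIES}, got {laterality!r}"
        )
    sides = ("L",) if laterality == "unilateral_left" else ("L", "R")
    return [_get_set(mesh, f"palate_{position}_{s}") for s in sides]


def scaled_bending_forces(
    models: list[TetMesh], base_force: float = 100.0
) -> np.ndarray:
    """Per-model bending force scaled by cranial surface area.

    ``F_i = base_force * A_i / A_min``: the smallest cranium carries exactly
    ``base_force`` (100 N by default) and every model the same load per
    unit surface area, removing size from the comparison.
    """
    if not models:
        raise ScenarioError("at least one model is required")
    areas = np.array([surface_area(m) for m in models])
    if np.any(areas <= 0):
        raise ScenarioError("all models must have positive surface area")
    return base_force * areas / areas.min()


def build_bending_scenario(
    mesh: TetMesh,
    position: str,
    laterality: str,
    total_force: float,
) -> Scenario:
    """Palatal bending: +Z loads split equally over the position's palate nodes.

    Loads point dorsally (perpendicular to the palate, global +Z with the
    cranium in standard orientation) and sum to ``total_force``; the
    posterior constraint layout (4+4 quadrate, 3 occipital, all axes)
    anchors the model.
    """
    sets = _palate_sets(mesh, position, laterality)
    nodes = np.concatenate(sets)
    if len(nodes) == 0:
        raise ScenarioError(f"palate sets for {position!r} are empty")
    per_node = total_force / len(nodes)
    loads = [(int(n), np.array([0.0, 0.0, per_node])) for n in nodes]
    lc = LoadCase(point_loads=loads, constraints=_posterior_constraints(mesh))
    return Scenario(
        name=f"bending_{position}_{laterality}",
        load_case=lc,
        kind="bending",
        position=position,
        laterality=laterality,
        total_applied_force=float(total_force),
    )


def muscle_nodal_loads(
    muscle: MuscleLoad, mesh: TetMesh
) -> list[tuple[int, np.ndarray]]:
    """Divide a muscle's force across eight origin-site nodes.

    The eight set members nearest the origin-set centroid are selected
    (ties broken by node index); each carries ``force/8`` directed from the
    node toward the insertion point, so magnitudes sum exactly to the
    muscle force.
    """
    oset = _get_set(mesh, muscle.origin_set)
    if len(oset) < MUSCLE_NODES:
        raise ScenarioError(
            f"origin set {muscle.origin_set!r} has {len(oset)} nodes; "
            f"{MUSCLE_NODES} required"
        )
    chosen = _nearest_centroid(mesh, oset, MUSCLE_NODES)
    insertion = np.asarray(muscle.insertion_point, dtype=float)
    loads = []
    for n in chosen:
        d = insertion - mesh.nodes[n]
        norm = np.linalg.norm(d)
        if norm == 0.0:
            raise ScenarioError(
                f"origin node {n} of {muscle.name} coincides with the insertion "
                "point (zero-length line of action)"
            )
        loads.append((int(n), (muscle.force / MUSCLE_NODES) * d / norm))
    return loads


def build_bite_scenario(
    mesh: TetMesh,
    muscles: list[MuscleLoad],
    position: str,
    laterality: str,
) -> Scenario:
    """Muscle-driven bite at a palate position.

    Loads are the union of all muscles' nodal loads.  Constraints are the
    posterior layout plus the bite point(s): one node (unilateral) or two
    (bilateral, one per side) chosen nearest each palate set's centroid and
    constrained in the vertical (Z) axis only — the Z reaction there is the
    bite force.
    """
    if not muscles:
        loads: list[tuple[int, np.ndarray]] = []
    else:
        loads = []
        for m in muscles:
            loads.extend(muscle_nodal_loads(m, mesh))
    constraints = _posterior_constraints(mesh)
    bite_nodes = []
    for pset in _palate_sets(mesh, position, laterality):
        if len(pset) == 0:
            raise ScenarioError(f"palate set for {position!r} is empty")
        bite_nodes.append(int(_nearest_centroid(mesh, pset, 1)[0]))
    for n in bite_nodes:
        constraints.append((n, (False, False, True)))
    total = float(sum(np.linalg.norm(f) for _, f in loads))
    return Scenario(
        name=f"bite_{position}_{laterality}",
        load_case=LoadCase(point_loads=loads, constraints=constraints),
        kind="bite",
        position=position,
        laterality=laterality,
        total_applied_force=total,
        bite_nodes=tuple(bite_nodes),
    )


def bite_reaction(solution: SolutionField, scenario: Scenario) -> float:
    """Bite force: magnitude of the dorsal (Z) reaction at the bite node(s)."""
    if scenario.kind != "bite":
        raise ScenarioError(
            f"bite_reaction requires a bite scenario, got kind={scenario.kind!r}"
        )
    rz = sum(solution.reactions[n, 2] for n in scenario.bite_nodes)
    return float(abs(rz))


def build_extrinsic_scenario(
    mesh: TetMesh, kind: str, total_force: float
) -> Scenario:
    """Head-pull, head-shake or head-twist driven from the beak tip.

    * ``pull`` — posteriorly directed (-Y) loads at the beak-tip nodes;
    * ``shake`` — laterally directed (+X) loads at the beak-tip nodes;
    * ``twist`` — a torsion couple: +Z on the left beak-tip group, -Z on
      the right, each side carrying half of ``total_force`` so the load
      magnitudes sum to ``total_force`` and the net force vanishes.

    Constraints are the bending test's posterior layout.
    """
    if kind not in ("pull", "shake", "twist"):
        raise ScenarioError(f"extrinsic kind must be pull|shake|twist, got {kind!r}")
    tips = {s: _get_set(mesh, f"beak_tip_{s}") for s in ("L", "R")}
    loads: list[tuple[int, np.ndarray]] = []
    if kind == "twist":
        for side, sign in (("L", +1.0), ("R", -1.0)):
            nodes = tips[side]
            if len(nodes) == 0:
                raise ScenarioError(f"beak_tip_{side} is empty")
            per = 0.5 * total_force / len(nodes)
            loads.extend(
                (int(n), np.array([0.0, 0.0, sign * per])) for n in nodes
            )
    else:
        nodes = np.concatenate([tips["L"], tips["R"]])
        if len(nodes) == 0:
            raise ScenarioError("beak-tip sets are empty")
        direction = (
            np.array([0.0, -1.0, 0.0]) if kind == "pull" else np.array([1.0, 0.0, 0.0])
        )
        per = total_force / len(nodes)
        loads.extend((int(n), per * direction) for n in nodes)
    return Scenario(
        name=f"extrinsic_{kind}",
        load_case=LoadCase(point_loads=loads, constraints=_posterior_constraints(mesh)),
        kind=kind,
        position="none",
        laterality="bilateral",
        total_applied_force=float(total_force),
    )


def apply_rhamphotheca(
    mesh: TetMesh, region: str | np.ndarray, keratin: Material
) -> TetMesh:
    """Overlay a keratinous rhamphotheca: re-label beak elements to keratin.

    ``region`` is an element-set name or an array of element indices.
    Geometry and connectivity are untouched — only the material label of
    the region's elements changes, so solving the returned mesh against a
    materials table containing ``keratin`` models the softer beak sheath.
    """
    if isinstance(region, str):
        try:
            idx = mesh.element_sets[region]
        except KeyError:
            raise ScenarioError(f"mesh has no element set {region!r}") from None
    else:
        idx = np.unique(np.asarray(region, dtype=np.int64))
        if idx.size and (idx.min() < 0 or idx.max() >= mesh.n_elements):
            raise MeshError("rhamphotheca region references nonexistent elements")
    if len(idx) == 0:
        raise ScenarioError("rhamphotheca region covers no elements")
    out = mesh.copy()
    out.element_material[idx] = keratin.name
    return out
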