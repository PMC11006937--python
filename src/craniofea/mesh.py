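"""Tetrahedral mesh data model and geometry.

The mesh is the substrate of every load case: four-noded tetrahedra (tet4,
constant-strain elements), per-element material labels, and named node sets
that mark anatomical landmarks (palate bite points, quadrate articular
patches, the occipital condyle, muscle-origin patches).

Units are mm throughout, so areas are mm^2, volumes mm^3 and — with forces
in N and moduli in MPa — stresses come out directly in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TetMesh",
    "MeshError",
    "ValidationReport",
    "validate_mesh",
    "surface_area",
    "volume",
    "scale_mesh",
]


class MeshError(ValueError):
    """Raised for structurally invalid meshes or mesh operations."""


# Faces of a positively oriented tet (n0,n1,n2,n3); each triple is ordered so
# its normal points out of the element.
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


@dataclass
class TetMesh:
    """Tet4 volume mesh with material labels and named node/element sets.

    Parameters
    ----------
    nodes
        ``(n_nodes, 3)`` float array of coordinates, mm.
    elements
        ``(n_elements, 4)`` int array of 0-based node indices.
    element_material
        Length ``n_elements`` array of material labels (strings).
    node_sets
        Mapping of set name to sorted, unique 0-based node indices.
    element_sets
        Mapping of set name to sorted, unique 0-based element indices.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_material: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.float64).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=np.int64).reshape(-1, 4)
        self.element_material = np.asarray(self.element_material, dtype=object)
        if self.element_material.shape[0] != self.elements.shape[0]:
            raise MeshError(
                "element_material length does not match the number of elements"
            )
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise MeshError("element connectivity references nonexistent nodes")
        self.node_sets = {
            k: np.unique(np.asarray(v, dtype=np.int64)) for k, v in self.node_sets.items()
        }
        self.element_sets = {
            k: np.unique(np.asarray(v, dtype=np.int64))
            for k, v in self.element_sets.items()
        }
        for name, idx in self.node_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= len(self.nodes)):
                raise MeshError(f"node set {name!r} references nonexistent nodes")
        for name, idx in self.element_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= len(self.elements)):
                raise MeshError(f"element set {name!r} references nonexistent elements")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def copy(self) -> "TetMesh":
        return TetMesh(
            nodes=self.nodes.copy(),
            elements=self.elements.copy(),
            element_material=self.element_material.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            element_sets={k: v.copy() for k, v in self.element_sets.items()},
        )

    # -- geometry ----------------------------------------------------------

    def signed_volumes(self) -> np.ndarray:
        """Signed volume of every tet (positive for correct orientation)."""
        p = self.nodes[self.elements]  # (M, 4, 3)
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def normalize_orientation(self) -> int:
        """Flip negatively oriented tets in place; return the number flipped.

        Orientation is normalised by swapping the last two nodes, which
        negates the signed volume and leaves the element's faces intact.
        """
        sv = self.signed_volumes()
        bad = sv < 0
        if bad.any():
            self.elements[bad] = self.elements[bad][:, [0, 1, 3, 2]]
        return int(bad.sum())

    def boundary_triangles(self) -> np.ndarray:
        """Boundary triangles: faces owned by exactly one tet.

        Returned with the owner element's outward orientation, ``(F, 3)``.
        """
        if self.n_elements == 0:
            raise MeshError("empty mesh has no boundary")
        faces = self.elements[:, _TET_FACES].reshape(-1, 3)  # (4M, 3)
        key = np.sort(faces, axis=1)
        _, first, counts = np.unique(
            key, axis=0, return_index=True, return_counts=True
        )
        return faces[first[counts == 1]]


def surface_area(mesh: TetMesh) -> float:
    """Total boundary surface area, mm^2 (all boundary faces count)."""
    tri = mesh.boundary_triangles()
    p = mesh.nodes[tri]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def volume(mesh: TetMesh) -> float:
    """Total mesh volume, mm^3 (sum of |signed tet volumes|)."""
    if mesh.n_elements == 0:
        raise MeshError("empty mesh has no volume")
    return float(np.abs(mesh.signed_volumes()).sum())


def scale_mesh(mesh: TetMesh, s: float) -> TetMesh:
    """Uniformly scale coordinates by ``s`` about the node centroid.

    Connectivity, materials and all named sets are shared unchanged, which
    is what makes families of geometrically similar models directly
    comparable scenario for scenario.
    """
    if not s > 0:
        raise MeshError(f"scale factor must be positive, got {s}")
    out = mesh.copy()
    centroid = out.nodes.mean(axis=0)
    out.nodes = centroid + s * (out.nodes - centroid)
    return out


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_mesh`."""

    n_inverted: int
    n_degenerate: int
    unreferenced_nodes: np.ndarray
    n_nonmanifold_edges: int
    dangling_sets: dict[str, np.ndarray]
    passed: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"inverted elements: {self.n_inverted}",
            f"degenerate elements: {self.n_degenerate}",
            f"unreferenced nodes: {len(self.unreferenced_nodes)}",
            f"non-manifold boundary edges: {self.n_nonmanifold_edges}",
            f"dangling set indices: {sum(len(v) for v in self.dangling_sets.values())}",
            f"PASS: {self.passed}",
        ]
        return "\n".join(lines)


def validate_mesh(mesh: TetMesh, *, volume_tol: float = 1e-12) -> ValidationReport:
    """Structural checks a mesh must pass before any analysis.

    Flags inverted (negative-volume) elements, degenerate (near-zero
    volume) elements, nodes referenced by no element, boundary edges not
    shared by exactly two boundary triangles (non-manifold surface), and
    node-set entries pointing outside the node range.  Degenerate tets are
    a hard failure rather than being dropped: removing them silently would
    change the assembled stiffness.
    """
    sv = mesh.signed_volumes()
    scale = np.abs(sv).max() if len(sv) else 0.0
    n_inverted = int((sv < 0).sum())
    n_degenerate = int((np.abs(sv) <= volume_tol * max(scale, 1.0)).sum())

    referenced = np.zeros(mesh.n_nodes, dtype=bool)
    referenced[mesh.elements.ravel()] = True
    unreferenced = np.flatnonzero(~referenced)

    tri = mesh.boundary_triangles() if mesh.n_elements else np.empty((0, 3), int)
    edges = np.sort(tri[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
    if len(edges):
        _, counts = np.unique(edges, axis=0, return_counts=True)
        n_nonmanifold = int((counts != 2).sum())
    else:
        n_nonmanifold = 0

    dangling: dict[str, np.ndarray] = {}
    for name, idx in mesh.node_sets.items():
        bad = idx[(idx < 0) | (idx >= mesh.n_nodes)]
        if bad.size:
            dangling[name] = bad

    passed = (
        n_inverted == 0
        and n_degenerate == 0
        and n_nonmanifold == 0
        and not dangling
        and len(unreferenced) == 0
    )
    return ValidationReport(
        n_inverted=n_inverted,
        n_degenerate=n_degenerate,
        unreferenced_nodes=unreferenced,
        n_nonmanifold_edges=n_nonmanifold,
        dangling_sets=dangling,
        passed=passed,
    )
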