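"""Synthetic geometry: beams with analytic solutions and toy skulls.

The toy skull is deliberately not an anatomical model.  The pipeline's
contracts are geometric and statistical — named landmark sets, bilateral
symmetry, similarity families — so a tapered box carrying the full
complement of landmark node sets (palate bite points at three positions on
both sides, quadrate articular patches, an occipital-condyle patch,
muscle-origin patches, beak-tip sets) exercises every scenario builder
exactly as a segmented cranium would.

Axis convention: X lateral (midsagittal plane at x = 0, left = x < 0),
Y anteroposterior (rostral tip at y = length), Z dorsoventral (palate at
z = 0, skull roof at z = height).  All generation is deterministic given
the spec (and its seed, when jitter is enabled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import MeshError, TetMesh, scale_mesh

__all__ = ["ToySkullSpec", "make_beam", "make_toy_skull", "make_similar_family"]

# the six tetrahedra of the Kuhn subdivision of a cell: monotone lattice
# paths from corner (0,0,0) to (1,1,1); face-to-face compatible between
# neighbouring cells because every cell uses the same main diagonal.
_KUHN_PATHS = [
    [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)],
    [(0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 1)],
    [(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 1, 1)],
    [(0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)],
    [(0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)],
    [(0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)],
]


def _structured_tets(
    nx: int, ny: int, nz: int, mirror_below: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Node index grid ``(nx+1, ny+1, nz+1)`` and tet connectivity.

    Cells with lateral index ``i < mirror_below`` use the x-mirrored Kuhn
    subdivision.  Flipping the x-offsets of the lattice paths is still a
    face-compatible triangulation (the diagonal on shared yz faces does not
    involve x, and neighbours on the flipped side flip alike), and it makes
    the whole tessellation — not just the point set — mirror-symmetric
    about the plane between cell ``mirror_below - 1`` and ``mirror_below``.
    Stress fields of symmetric load cases then mirror element for element.
    """
    nid = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    tets = []
    for i in range(nx):
        flip = i < mirror_below
        for j in range(ny):
            for k in range(nz):
                for path in _KUHN_PATHS:
                    tets.append(
                        [
                            nid[i + (1 - di if flip else di), j + dj, k + dk]
                            for di, dj, dk in path
                        ]
                    )
    return nid, np.array(tets, dtype=np.int64)


def make_beam(
    L: float, W: float, H: float, nx: int, ny: int, nz: int, material: str = "bone"
) -> TetMesh:
    """Structured cantilever-validation beam along X.

    ``nx*ny*nz`` cells, six tets each; node sets ``fixed_end`` (the x = 0
    face) and ``free_end_tip`` (the x = L face).
    """
    if min(L, W, H) <= 0 or min(nx, ny, nz) < 1:
        raise MeshError("beam dimensions and cell counts must be positive")
    nid, tets = _structured_tets(nx, ny, nz)
    xs = np.linspace(0.0, L, nx + 1)
    ys = np.linspace(0.0, W, ny + 1)
    zs = np.linspace(0.0, H, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    mesh = TetMesh(
        nodes=nodes,
        elements=tets,
        element_material=np.full(len(tets), material, dtype=object),
        node_sets={
            "fixed_end": nid[0].ravel(),
            "free_end_tip": nid[-1].ravel(),
        },
    )
    mesh.normalize_orientation()
    return mesh


@dataclass(frozen=True)
class ToySkullSpec:
    """Parameters of the toy skull generator.

    ``resolution`` is cells per axis (lateral, anteroposterior,
    dorsoventral); the lateral count must be even so a midline node column
    exists for the occipital set, and the defaults are the coarsest grid
    that furnishes every landmark set at its required size.  ``taper`` is
    the fractional lateral narrowing at the rostral tip.  ``jitter``
    perturbs interior nodes by that fraction of the cell size using
    ``seed`` (0 keeps exact bilateral symmetry).
    """

    length: float = 60.0  # mm, anteroposterior
    width: float = 30.0  # mm, lateral (at the caudal end)
    height: float = 24.0  # mm, dorsoventral
    taper: float = 0.5
    resolution: tuple[int, int, int] = (6, 10, 4)
    seed: int = 0
    jitter: float = 0.0
    with_teeth: bool = True
    with_beak: bool = True

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("toy skull dimensions must be positive")
        if not (0.0 <= self.taper < 1.0):
            raise ValueError("taper must lie in [0, 1)")
        nx, ny, nz = self.resolution
        if min(nx, ny, nz) < 2:
            raise ValueError("resolution must be at least 2 cells per axis")
        if nx % 2 != 0:
            raise ValueError("lateral resolution must be even (midline node column)")
        if ny < 6 or nz < 3:
            raise ValueError(
                "resolution too coarse to furnish the required landmark sets "
                "(need >= 6 anteroposterior and >= 3 dorsoventral cells)"
            )


def make_toy_skull(spec: ToySkullSpec = ToySkullSpec()) -> TetMesh:
    """Generate the bilaterally symmetric toy skull with its landmark sets.

    Node sets provided (all mirror-symmetric about x = 0):

    * ``palate_{anterior,mid,posterior}_{L,R}`` — ventral-surface bite
      points: the rostral tip, the lateral palate margin at mid-length and
      the caudal palate;
    * ``quadrate_{L,R}`` — >= 4 posteroventral articular nodes per side;
    * ``occipital`` — >= 3 caudal midline nodes;
    * ``m_AME_origin_{L,R}`` (dorsotemporal) and ``m_AMP_origin_{L,R}``
      (lateral posterior) — >= 8 muscle-origin nodes per patch;
    * ``beak_tip_{L,R}`` — the rostral face, for extrinsic loading.

    Element sets ``beak`` and ``teeth`` mark the rostral region (for
    rhamphotheca overlays) and small anterior ventral tooth patches.
    """
    nx, ny, nz = spec.resolution
    nid, tets = _structured_tets(nx, ny, nz, mirror_below=nx // 2)
    # symmetric lateral stations (x = 0 column exists because nx is even)
    xi = np.linspace(-0.5, 0.5, nx + 1)
    ys = np.linspace(0.0, spec.length, ny + 1)
    zs = np.linspace(0.0, spec.height, nz + 1)
    half_width = spec.width * (1.0 - spec.taper * ys / spec.length)  # (ny+1,)
    nodes = np.empty(((nx + 1) * (ny + 1) * (nz + 1), 3))
    for j, y in enumerate(ys):
        X, Z = np.meshgrid(xi * half_width[j], zs, indexing="ij")
        block = np.stack([X.ravel(), np.full(X.size, y), Z.ravel()], axis=1)
        nodes[nid[:, j, :].ravel()] = block

    if spec.jitter > 0.0:
        rng = np.random.default_rng(spec.seed)
        cell = min(spec.width / nx, spec.length / ny, spec.height / nz)
        interior = np.ones(len(nodes), dtype=bool)
        boundary = np.concatenate(
            [
                nid[0].ravel(), nid[-1].ravel(),
                nid[:, 0, :].ravel(), nid[:, -1, :].ravel(),
                nid[:, :, 0].ravel(), nid[:, :, -1].ravel(),
            ]
        )
        interior[boundary] = False
        nodes[interior] += spec.jitter * cell * rng.uniform(
            -0.5, 0.5, size=(int(interior.sum()), 3)
        )

    xcol = np.arange(nx + 1)  # lateral station index; midline at nx//2
    mid_col = nx // 2
    left_cols = xcol[:mid_col]  # x < 0
    right_cols = xcol[mid_col + 1 :]  # x > 0

    sets: dict[str, np.ndarray] = {}

    # palate bite points, ventral surface z = 0
    sets["palate_anterior_L"] = nid[left_cols, ny, 0].ravel()
    sets["palate_anterior_R"] = nid[right_cols, ny, 0].ravel()
    jmid = ny // 2
    sets["palate_mid_L"] = nid[0, [jmid, jmid + 1], 0].ravel()
    sets["palate_mid_R"] = nid[nx, [jmid, jmid + 1], 0].ravel()
    sets["palate_posterior_L"] = nid[mid_col - 1, [2, 3], 0].ravel()
    sets["palate_posterior_R"] = nid[mid_col + 1, [2, 3], 0].ravel()

    # posterior constraint patches
    sets["quadrate_L"] = nid[[0, 1], 0, :2].ravel()
    sets["quadrate_R"] = nid[[nx - 1, nx], 0, :2].ravel()
    sets["occipital"] = nid[mid_col, 0, 1:4].ravel()

    # muscle-origin patches: dorsotemporal roof (AME) and lateral wall (AMP)
    sets["m_AME_origin_L"] = nid[[0, 1], 1:5, nz].ravel()
    sets["m_AME_origin_R"] = nid[[nx - 1, nx], 1:5, nz].ravel()
    sets["m_AMP_origin_L"] = nid[0, 1:5, nz - 2 : nz].ravel()
    sets["m_AMP_origin_R"] = nid[nx, 1:5, nz - 2 : nz].ravel()

    # beak tip: the rostral face, split by side
    sets["beak_tip_L"] = nid[left_cols, ny, :].ravel()
    sets["beak_tip_R"] = nid[right_cols, ny, :].ravel()

    element_sets: dict[str, np.ndarray] = {}
    material = np.full(len(tets), "bone", dtype=object)
    centroids_j = _cell_j_index(nx, ny, nz)
    centroids_k = _cell_k_index(nx, ny, nz)
    is_tooth = (centroids_j >= ny - 1) & (centroids_k == 0) if spec.with_teeth else np.zeros(len(tets), bool)
    if spec.with_beak:
        # the keratinous sheath overlays rostral bone, never the teeth
        element_sets["beak"] = np.flatnonzero(
            (centroids_j >= int(0.8 * ny)) & ~is_tooth
        )
    if spec.with_teeth:
        teeth = np.flatnonzero(is_tooth)
        element_sets["teeth"] = teeth
        material[teeth] = "teeth"

    mesh = TetMesh(
        nodes=nodes,
        elements=tets,
        element_material=material,
        node_sets=sets,
        element_sets=element_sets,
    )
    mesh.normalize_orientation()
    return mesh


def _cell_j_index(nx: int, ny: int, nz: int) -> np.ndarray:
    """Anteroposterior cell index of every tet (cells ordered i, j, k; 6 tets each)."""
    return np.repeat(np.tile(np.repeat(np.arange(ny), nz), nx), 6)


def _cell_k_index(nx: int, ny: int, nz: int) -> np.ndarray:
    """Dorsoventral cell index of every tet."""
    return np.repeat(np.tile(np.arange(nz), nx * ny), 6)


def make_similar_family(
    spec: ToySkullSpec, scales: list[float]
) -> list[TetMesh]:
    """Geometrically similar toy skulls sharing connectivity and sets.

    One base mesh is generated and uniformly scaled, so surface areas vary
    as s^2 and volumes as s^3 — the family the area-scaled loading protocol
    is designed to compare on equal footing.
    """
    if not scales:
        raise MeshError("at least one scale factor is required")
    base = make_toy_skull(spec)
    return [scale_mesh(base, float(s)) for s in scales]
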