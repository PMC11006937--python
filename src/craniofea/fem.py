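"""Linear-elastic finite-element solver for tet4 (constant-strain) meshes.

The element is the classic constant-strain tetrahedron: linear shape
functions, one constant strain/stress tensor per element, stiffness
``Ke = V * B^T D B``.  Dirichlet constraints are imposed by eliminating the
constrained degrees of freedom exactly (no penalty terms — a penalty would
leak spurious stress into the peak statistics this pipeline exists to
compare).  The reduced system is solved with a sparse direct factorisation
by default; a dense solve and a conjugate-gradient path are available for
cross-checking.

Stress recovery mirrors the element-nodal report of commercial solvers:
each element's (constant) von Mises value is replicated at its four
corners, so the exported multiset has ``4 * n_elements`` entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import Material, elasticity_matrix
from .mesh import TetMesh

__all__ = [
    "LoadCase",
    "SolutionField",
    "SingularSystemError",
    "element_stiffness",
    "assemble",
    "solve",
    "von_mises",
]


class SingularSystemError(RuntimeError):
    """Insufficiently constrained (rigid-body modes) or non-converged solve."""


@dataclass
class LoadCase:
    """Point loads plus per-axis zero-displacement constraints.

    ``point_loads`` is a list of ``(node, force_vector_N)``; ``constraints``
    a list of ``(node, (fix_x, fix_y, fix_z))``.  A node may not be both
    loaded and constrained on the same axis, and at least six degrees of
    freedom must be constrained for the system to be solvable.
    """

    point_loads: list[tuple[int, np.ndarray]] = field(default_factory=list)
    constraints: list[tuple[int, tuple[bool, bool, bool]]] = field(default_factory=list)

    def validate(self, n_nodes: int) -> None:
        constrained_axes: dict[int, set[int]] = {}
        n_fixed = 0
        for node, mask in self.constraints:
            if not (0 <= node < n_nodes):
                raise ValueError(f"constraint on nonexistent node {node}")
            axes = {a for a in range(3) if mask[a]}
            constrained_axes.setdefault(node, set()).update(axes)
            n_fixed += len(axes)
        for node, f in self.point_loads:
            if not (0 <= node < n_nodes):
                raise ValueError(f"load on nonexistent node {node}")
            f = np.asarray(f, dtype=float)
            loaded_axes = set(np.flatnonzero(f != 0.0))
            clash = loaded_axes & constrained_axes.get(node, set())
            if clash:
                raise ValueError(
                    f"node {node} is both loaded and constrained on axis {sorted(clash)}"
                )
        if n_fixed < 6:
            raise ValueError(
                f"only {n_fixed} constrained DOFs; at least 6 are required to "
                "remove rigid-body modes"
            )

    def force_vector(self, n_nodes: int) -> np.ndarray:
        f = np.zeros(3 * n_nodes)
        for node, vec in self.point_loads:
            f[3 * node : 3 * node + 3] += np.asarray(vec, dtype=float)
        return f

    def fixed_dofs(self, n_nodes: int) -> np.ndarray:
        mask = np.zeros(3 * n_nodes, dtype=bool)
        for node, axes in self.constraints:
            for a in range(3):
                if axes[a]:
                    mask[3 * node + a] = True
        return np.flatnonzero(mask)


@dataclass
class SolutionField:
    """Solved state: displacements, stresses, von Mises multiset, energy.

    ``element_nodal_vm`` holds one entry per (element, corner) pair — the
    element value replicated four times — matching the element-nodal stress
    reports the summary statistics are computed from.  ``reactions`` is a
    full ``(n_nodes, 3)`` array, nonzero only at constrained DOFs.
    """

    displacements: np.ndarray  # (n_nodes, 3), mm
    element_stress: np.ndarray  # (n_elements, 6) Voigt, MPa
    element_vm: np.ndarray  # (n_elements,), MPa
    element_nodal_vm: np.ndarray  # (4 * n_elements,), MPa
    strain_energy: float  # N*mm
    reactions: np.ndarray  # (n_nodes, 3), N

    def nodal_averaged_vm(self, mesh: TetMesh) -> np.ndarray:
        """Unique-node averaged von Mises field (for contour export only)."""
        sums = np.zeros(mesh.n_nodes)
        counts = np.zeros(mesh.n_nodes)
        np.add.at(sums, mesh.elements.ravel(), np.repeat(self.element_vm, 4))
        np.add.at(counts, mesh.elements.ravel(), 1.0)
        counts[counts == 0] = 1.0
        return sums / counts


def _shape_gradients(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients and volumes for a batch of tets.

    ``coords`` is ``(M, 4, 3)``.  Returns ``(grads, vols)`` with ``grads``
    of shape ``(M, 4, 3)`` (gradient of each linear shape function) and
    positive volumes ``(M,)``.  Raises on degenerate elements.
    """
    M = coords.shape[0]
    A = np.ones((M, 4, 4))
    A[:, :, 1:] = coords
    det = np.linalg.det(A)
    vols = det / 6.0
    if np.any(np.abs(vols) < 1e-300) or not np.all(np.isfinite(vols)):
        raise ValueError("degenerate (zero-volume) tetrahedron")
    inv = np.linalg.inv(A)  # (M, 4, 4); rows of inv are coefficient rows
    grads = inv[:, 1:, :].transpose(0, 2, 1)  # (M, 4, 3): node i, d/dx_j
    return grads, vols


def _strain_displacement(grads: np.ndarray) -> np.ndarray:
    """Constant 6x12 B matrices (engineering shear) for a batch of tets."""
    M = grads.shape[0]
    B = np.zeros((M, 6, 12))
    for i in range(4):
        bx, by, bz = grads[:, i, 0], grads[:, i, 1], grads[:, i, 2]
        c = 3 * i
        B[:, 0, c + 0] = bx
        B[:, 1, c + 1] = by
        B[:, 2, c + 2] = bz
        B[:, 3, c + 0] = by
        B[:, 3, c + 1] = bx
        B[:, 4, c + 1] = bz
        B[:, 4, c + 2] = by
        B[:, 5, c + 0] = bz
        B[:, 5, c + 2] = bx
    return B


def element_stiffness(coords: np.ndarray, material: Material) -> np.ndarray:
    """12x12 stiffness ``V * B^T D B`` of a single tet4 element.

    Symmetric with exactly six zero eigenvalues (rigid-body modes).  The
    element must have positive volume (orient the mesh first).
    """
    coords = np.asarray(coords, dtype=float).reshape(1, 4, 3)
    grads, vols = _shape_gradients(coords)
    if vols[0] <= 0:
        raise ValueError("element has non-positive volume; normalise orientation")
    B = _strain_displacement(grads)[0]
    D = elasticity_matrix(material)
    return vols[0] * B.T @ D @ B


def assemble(mesh: TetMesh, materials: dict[str, Material]) -> sp.csr_matrix:
    """Assemble the global 3N x 3N sparse stiffness matrix.

    Element matrices are computed in material-wise batches (one constitutive
    matrix per batch) and scattered with COO accumulation.
    """
    labels = np.asarray(mesh.element_material)
    missing = {str(l) for l in labels} - set(materials)
    if missing:
        raise KeyError(f"no Material supplied for label(s) {sorted(missing)}")

    coords = mesh.nodes[mesh.elements]  # (M, 4, 3)
    grads, vols = _shape_gradients(coords)
    if np.any(vols <= 0):
        raise ValueError("mesh contains non-positively oriented elements")
    B = _strain_displacement(grads)  # (M, 6, 12)

    Ke = np.empty((mesh.n_elements, 12, 12))
    for label in dict.fromkeys(labels):
        idx = np.flatnonzero(labels == label)
        D = elasticity_matrix(materials[str(label)])
        DB = np.einsum("ij,mjk->mik", D, B[idx])
        Ke[idx] = vols[idx, None, None] * np.einsum("mji,mjk->mik", B[idx], DB)

    edofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 12)  # (M, 12)
    rows = np.repeat(edofs, 12, axis=1).ravel()
    cols = np.tile(edofs, (1, 12)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)
    )
    return K.tocsr()


def solve(
    mesh: TetMesh,
    materials: dict[str, Material],
    load_case: LoadCase,
    *,
    method: str = "direct",
    cg_rtol: float = 1e-10,
) -> SolutionField:
    """Solve the constrained linear system and recover stresses and energy.

    Parameters
    ----------
    method
        ``"direct"`` (sparse LU), ``"dense"`` (dense direct solve of the
        reduced system; cross-check for small problems) or ``"cg"``
        (conjugate gradients with relative residual ``cg_rtol``).

    Constrained DOFs are eliminated exactly: the reduced system
    ``K_ff u_f = f_f`` is solved, reactions recovered as ``K u - f`` at the
    constrained DOFs.  Strain energy is ``U = 1/2 f . u`` over the applied
    loads (reaction work vanishes at homogeneous constraints).
    """
    load_case.validate(mesh.n_nodes)
    K = assemble(mesh, materials)
    n_dof = 3 * mesh.n_nodes
    f = load_case.force_vector(mesh.n_nodes)
    fixed = load_case.fixed_dofs(mesh.n_nodes)
    free = np.setdiff1d(np.arange(n_dof), fixed, assume_unique=False)

    K_ff = K[free][:, free].tocsc()
    f_f = f[free]
    u = np.zeros(n_dof)
    if np.any(f_f):
        if method == "direct":
            try:
                lu = spla.splu(K_ff)
                u_f = lu.solve(f_f)
            except RuntimeError as exc:  # singular factorisation
                raise SingularSystemError(str(exc)) from None
        elif method == "dense":
            u_f = np.linalg.solve(K_ff.toarray(), f_f)
        elif method == "cg":
            u_f, info = spla.cg(K_ff, f_f, rtol=cg_rtol, maxiter=20 * K_ff.shape[0])
            if info != 0:
                res = np.linalg.norm(K_ff @ u_f - f_f) / np.linalg.norm(f_f)
                raise SingularSystemError(
                    f"conjugate gradients did not converge (info={info}, "
                    f"relative residual {res:.3e})"
                )
        else:
            raise ValueError(f"unknown solve method {method!r}")
        if not np.all(np.isfinite(u_f)):
            raise SingularSystemError(
                "solution contains non-finite values: the system is singular "
                "(unconstrained rigid-body modes?)"
            )
        res = np.linalg.norm(K_ff @ u_f - f_f) / np.linalg.norm(f_f)
        if res > 1e-6:
            raise SingularSystemError(
                f"large residual after solve ({res:.3e}): system is ill-posed"
            )
        u[free] = u_f

    # stress recovery: sigma = D B u_e, constant per element
    coords = mesh.nodes[mesh.elements]
    grads, _ = _shape_gradients(coords)
    B = _strain_displacement(grads)
    ue = u.reshape(-1, 3)[mesh.elements].reshape(-1, 12)  # (M, 12)
    strains = np.einsum("mij,mj->mi", B, ue)  # Voigt, engineering shear
    labels = np.asarray(mesh.element_material)
    stress = np.empty_like(strains)
    for label in dict.fromkeys(labels):
        idx = np.flatnonzero(labels == label)
        D = elasticity_matrix(materials[str(label)])
        stress[idx] = strains[idx] @ D.T

    vm = von_mises(stress)
    reactions = (K @ u - f).reshape(-1, 3)
    # zero out roundoff at free DOFs; reactions live only at constraints
    rmask = np.zeros(n_dof, dtype=bool)
    rmask[fixed] = True
    reactions = np.where(rmask.reshape(-1, 3), reactions, 0.0)

    return SolutionField(
        displacements=u.reshape(-1, 3),
        element_stress=stress,
        element_vm=vm,
        element_nodal_vm=np.repeat(vm, 4),
        strain_energy=float(0.5 * f @ u),
        reactions=reactions,
    )


def von_mises(stress: np.ndarray) -> np.ndarray | float:
    """Von Mises equivalent stress from Voigt tensors (xx,yy,zz,xy,yz,zx).

    sigma_vm = sqrt( 1/2 [(sxx-syy)^2 + (syy-szz)^2 + (szz-sxx)^2]
                     + 3 (txy^2 + tyz^2 + tzx^2) )
    """
    s = np.asarray(stress, dtype=float)
    scalar = s.ndim == 1
    s = np.atleast_2d(s)
    sxx, syy, szz, txy, tyz, tzx = (s[:, i] for i in range(6))
    vm = np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )
    return float(vm[0]) if scalar else vm
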