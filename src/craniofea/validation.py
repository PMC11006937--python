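"""Solver-verification routines with independent analytic oracles.

Three classic checks back the solver:

* the **patch test** — a block under uniform uniaxial traction must
  reproduce the exact constant stress field in every element (constant-
  strain elements represent constant fields exactly);
* the **cantilever oracle** — tip deflection of a slender beam against
  Euler–Bernoulli theory ``PL^3 / 3EI``, converging monotonically under
  refinement (tet4 is stiff in bending, so convergence is from below);
* **dense-solver equivalence** — the sparse path against a dense direct
  solve of the same reduced system.
"""

from __future__ import annotations

import numpy as np

from .fem import LoadCase, solve
from .materials import Material
from .mesh import TetMesh
from .synthetic import make_beam

__all__ = [
    "uniform_traction_loads",
    "patch_test_error",
    "cantilever_tip_deflection",
    "beam_convergence",
    "dense_sparse_difference",
    "BEAM_REFINEMENTS",
]

#: Stated refinement levels (cells per axis) of the 10 x 1 x 1 mm cantilever
#: convergence study; the finest level is the one quoted against theory.
BEAM_REFINEMENTS: tuple[tuple[int, int, int], ...] = ((24, 3, 3), (48, 6, 6), (64, 8, 8))

#: Beam-oracle material: bone stiffness with nu = 0.  Euler-Bernoulli theory
#: carries no Poisson effect, and nu > 0 adds clamped-end stiffening that is
#: a modelling difference, not a solver error, so the oracle comparison uses
#: the Poisson-free material.
BEAM_MATERIAL = Material("beam_bone", 20490.0, 0.0)


def uniform_traction_loads(
    mesh: TetMesh, face_nodes: np.ndarray, traction: np.ndarray
) -> list[tuple[int, np.ndarray]]:
    """Consistent nodal loads for a uniform traction on a boundary patch.

    Boundary triangles whose three corners all lie in ``face_nodes``
    contribute ``t * A / 3`` to each corner — the work-equivalent load of a
    uniform traction on linear triangles.
    """
    face = set(int(n) for n in face_nodes)
    traction = np.asarray(traction, dtype=float)
    acc: dict[int, np.ndarray] = {}
    for tri in mesh.boundary_triangles():
        if all(int(n) in face for n in tri):
            p = mesh.nodes[tri]
            area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
            for n in tri:
                acc.setdefault(int(n), np.zeros(3))
                acc[int(n)] += traction * area / 3.0
    return [(n, f) for n, f in sorted(acc.items())]


def _node_at(mesh: TetMesh, xyz) -> int:
    idx = np.where(np.all(np.abs(mesh.nodes - np.asarray(xyz)) < 1e-9, axis=1))[0]
    if len(idx) != 1:
        raise ValueError(f"expected exactly one node at {xyz}, found {len(idx)}")
    return int(idx[0])


def patch_test_error(
    material: Material, sigma: float = 5.0, cells: tuple[int, int, int] = (2, 2, 2)
) -> float:
    """Max relative von Mises error of the uniaxial patch test.

    A 2 x 1 x 1 block is loaded with consistent nodal loads equivalent to a
    uniform traction ``sigma`` on the free end; the fixed end is roller-
    supported in X with three extra pins blocking the remaining rigid
    modes without constraining the Poisson contraction.  Exact answer:
    ``sigma_vm = sigma`` in every element.
    """
    L = 2.0
    mesh = make_beam(L, 1.0, 1.0, *cells, material=material.name)
    tip = mesh.node_sets["free_end_tip"]
    loads = uniform_traction_loads(mesh, tip, np.array([sigma, 0.0, 0.0]))
    pins = {
        _node_at(mesh, (0, 0, 0)): (True, True, True),
        _node_at(mesh, (0, 1, 0)): (True, False, True),
        _node_at(mesh, (0, 0, 1)): (True, True, False),
    }
    constraints = [
        (int(n), pins.get(int(n), (True, False, False)))
        for n in mesh.node_sets["fixed_end"]
    ]
    sol = solve(mesh, {material.name: material}, LoadCase(loads, constraints))
    return float(np.abs(sol.element_vm - sigma).max() / sigma)


def cantilever_tip_deflection(
    material: Material,
    cells: tuple[int, int, int],
    L: float = 10.0,
    W: float = 1.0,
    H: float = 1.0,
    P: float = 1.0,
    method: str = "direct",
) -> tuple[float, float]:
    """(computed, Euler–Bernoulli) tip deflection of an end-loaded cantilever.

    The tip load ``P`` (N, +Z) is split equally over the free-end face and
    the fixed end is fully clamped; the computed deflection is the mean Z
    displacement of the free-end face.  Theory: ``PL^3 / (3 E I)`` with
    ``I = W H^3 / 12``.
    """
    mesh = make_beam(L, W, H, *cells, material=material.name)
    tip = mesh.node_sets["free_end_tip"]
    loads = [(int(n), np.array([0.0, 0.0, P / len(tip)])) for n in tip]
    constraints = [(int(n), (True, True, True)) for n in mesh.node_sets["fixed_end"]]
    sol = solve(mesh, {material.name: material}, LoadCase(loads, constraints), method=method)
    computed = float(sol.displacements[tip, 2].mean())
    analytic = P * L**3 / (3.0 * material.E * (W * H**3 / 12.0))
    return computed, analytic


def beam_convergence(
    material: Material,
    refinements: tuple[tuple[int, int, int], ...] = BEAM_REFINEMENTS,
) -> list[dict[str, float]]:
    """Relative tip-deflection error at each refinement level."""
    rows = []
    for cells in refinements:
        d, ref = cantilever_tip_deflection(material, cells)
        rows.append(
            {
                "cells": "x".join(map(str, cells)),
                "deflection_mm": d,
                "analytic_mm": ref,
                "rel_error": abs(d - ref) / ref,
            }
        )
    return rows


def dense_sparse_difference(
    mesh: TetMesh, materials: dict[str, Material], load_case: LoadCase
) -> float:
    """Max relative displacement difference between sparse and dense solves."""
    sparse = solve(mesh, materials, load_case, method="direct")
    dense = solve(mesh, materials, load_case, method="dense")
    scale = np.abs(dense.displacements).max()
    if scale == 0.0:
        return 0.0
    return float(np.abs(sparse.displacements - dense.displacements).max() / scale)
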