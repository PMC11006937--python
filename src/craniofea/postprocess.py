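"""Comparative summary statistics and field export.

Point loads and point constraints on a tet4 mesh create artificially high
local stresses, so before models are compared the top 5% of the
element-nodal von Mises values are excluded; means, quartiles and the peak
are computed on the retained multiset.  Total strain energy from
area-scaled loading is made size-comparable by rescaling with a reference
volume: for geometrically similar models under area-scaled loads the
stress field is scale-invariant, so U grows with volume and
``U_corrected = U * (v_ref / V)`` brings all models to a common size.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .fem import SolutionField
from .mesh import TetMesh, volume as mesh_volume
from . import io as mesh_io
from .scenarios import Scenario

__all__ = [
    "SummaryStats",
    "trim_top",
    "summarize",
    "comparison_table",
    "export_contour",
    "DEFAULT_TRIM_FRACTION",
]

DEFAULT_TRIM_FRACTION = 0.05  # top 5% of element-nodal values excluded


@dataclass(frozen=True)
class SummaryStats:
    """Trimmed von Mises summary plus raw/corrected strain energy."""

    mean_vm: float  # MPa
    q1_vm: float
    median_vm: float
    q3_vm: float
    peak_vm: float  # max of the retained values, MPa
    strain_energy_raw: float  # N*mm
    strain_energy_corrected: float  # N*mm, rescaled to v_ref
    n_values_total: int
    n_values_retained: int


def trim_top(values: np.ndarray, trim_fraction: float = DEFAULT_TRIM_FRACTION) -> np.ndarray:
    """Drop the largest ``floor(trim_fraction * n)`` values.

    The retained multiset is returned sorted ascending; ties at the cut are
    resolved by removing exactly the computed count, so the result is
    independent of input order.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot trim an empty value multiset")
    if not (0.0 <= trim_fraction < 1.0):
        raise ValueError(f"trim_fraction must lie in [0, 1), got {trim_fraction}")
    n_drop = int(np.floor(trim_fraction * values.size))
    s = np.sort(values)
    return s[: values.size - n_drop] if n_drop else s


def summarize(
    solution: SolutionField,
    mesh: TetMesh,
    v_ref: float,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
) -> SummaryStats:
    """Summary statistics of a solved scenario.

    Statistics are computed on the trimmed element-nodal von Mises
    multiset; quartiles use linear interpolation between order statistics;
    the peak is the maximum retained value.  ``v_ref`` (mm^3) is the
    reference volume for the strain-energy size correction.
    """
    if not v_ref > 0:
        raise ValueError("v_ref must be positive")
    retained = trim_top(solution.element_nodal_vm, trim_fraction)
    q1, med, q3 = np.percentile(retained, [25, 50, 75], method="linear")
    v = mesh_volume(mesh)
    return SummaryStats(
        mean_vm=float(retained.mean()),
        q1_vm=float(q1),
        median_vm=float(med),
        q3_vm=float(q3),
        peak_vm=float(retained.max()),
        strain_energy_raw=float(solution.strain_energy),
        strain_energy_corrected=float(solution.strain_energy * (v_ref / v)),
        n_values_total=int(solution.element_nodal_vm.size),
        n_values_retained=int(retained.size),
    )


def comparison_table(
    runs: dict[tuple[str, Scenario], SummaryStats]
) -> pd.DataFrame:
    """Long-format comparison table over (model, scenario) runs.

    One row per run with the scenario metadata and every summary field;
    rows ordered deterministically by model then scenario name.
    """
    if not runs:
        raise ValueError("comparison_table needs at least one run")
    records = []
    for (model, scenario), stats in runs.items():
        rec = {
            "model": model,
            "scenario": scenario.name,
            "kind": scenario.kind,
            "position": scenario.position,
            "laterality": scenario.laterality,
            "total_applied_force_N": scenario.total_applied_force,
        }
        rec.update(asdict(stats))
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    return df.sort_values(["model", "scenario"], kind="stable").reset_index(drop=True)


def export_contour(
    mesh: TetMesh,
    solution: SolutionField,
    path,
    scenario: Scenario | None = None,
) -> None:
    """Export a VTK unstructured grid for contour plotting.

    Carries the per-element von Mises field, a unique-node averaged von
    Mises field, the displacement vectors, and (when a scenario is given)
    point flags marking loaded and constrained nodes.
    """
    point_data: dict[str, np.ndarray] = {
        "von_mises_nodal_avg": solution.nodal_averaged_vm(mesh),
        "displacement": solution.displacements,
    }
    if scenario is not None:
        load_flag = np.zeros(mesh.n_nodes)
        for n, _ in scenario.load_case.point_loads:
            load_flag[n] = 1.0
        con_flag = np.zeros(mesh.n_nodes)
        for n, _ in scenario.load_case.constraints:
            con_flag[n] = 1.0
        point_data["load_flag"] = load_flag
        point_data["constraint_flag"] = con_flag
    mesh_io.write_vtk(
        mesh,
        path,
        cell_data={"von_mises": solution.element_vm},
        point_data=point_data,
    )
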