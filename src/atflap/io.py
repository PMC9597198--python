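"""Plain-text readers and writers: curves, meshes, fields, configs.

Mesh and field output use the ASCII legacy-VTK and Gmsh MSH2 dialects, both
simple line-oriented text formats readable by ParaView/Gmsh.  Stress-stretch
curves and design tables are CSV; material parameters and simulation configs
are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .material import OgdenParameters, StressStretchCurve
from .mesh import SkinMesh

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "read_material",
    "write_material",
    "write_sweep_csv",
    "write_layout_csv",
    "write_vtk",
    "write_msh",
]


def read_curve_csv(path) -> StressStretchCurve:
    """Read a uniaxial curve CSV with columns ``stretch``, ``stress_mpa``."""
    df = pd.read_csv(path)
    if not {"stretch", "stress_mpa"} <= set(df.columns):
        raise ValueError("curve CSV needs 'stretch' and 'stress_mpa' columns")
    return StressStretchCurve(
        stretch=df["stretch"].to_numpy(), nominal_stress=df["stress_mpa"].to_numpy()
    )


def write_curve_csv(path, curve: StressStretchCurve) -> None:
    pd.DataFrame(
        {"stretch": curve.stretch, "stress_mpa": curve.nominal_stress}
    ).to_csv(path, index=False)


def write_material(path, params: OgdenParameters) -> None:
    data = {
        "model": "ogden",
        "mu_mpa": list(params.mu),
        "alpha": list(params.alpha),
    }
    if params.bulk_modulus is not None:
        data["bulk_modulus_mpa"] = float(params.bulk_modulus)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_material(path) -> OgdenParameters:
    data = yaml.safe_load(Path(path).read_text())
    if data.get("model", "ogden") != "ogden":
        raise ValueError(f"unsupported material model {data.get('model')!r}")
    return OgdenParameters(
        mu=tuple(data["mu_mpa"]),
        alpha=tuple(data["alpha"]),
        bulk_modulus=data.get("bulk_modulus_mpa"),
    )


def write_sweep_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, columns=["apex_deg", "ratio", "d_mm",
                                             "S_mm2", "h_mm"])


def write_layout_csv(path, design) -> None:
    rows = [{"point": k, "x_mm": v[0], "y_mm": v[1]}
            for k, v in design.incision_layout.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_vtk(path, mesh: SkinMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write an ASCII legacy-VTK unstructured grid (quads, z = 0)."""
    lines = [
        "# vtk DataFile Version 3.0",
        "atflap mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9g} {y:.9g} 0")
    e = mesh.n_elements
    lines.append(f"CELLS {e} {5 * e}")
    for q in mesh.quads:
        lines.append("4 " + " ".join(str(int(i)) for i in q))
    lines.append(f"CELL_TYPES {e}")
    lines.extend(["9"] * e)  # VTK_QUAD

    def _emit(data: dict, n: int) -> list:
        out = []
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out.extend(f"{v:.9g}" for v in arr)
            else:  # 2-D vectors, padded to 3 components
                out.append(f"VECTORS {name} double")
                out.extend(f"{v[0]:.9g} {v[1]:.9g} 0" for v in arr)
        return out

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.extend(_emit(point_data, mesh.n_nodes))
    if cell_data:
        lines.append(f"CELL_DATA {e}")
        lines.extend(_emit(cell_data, e))
    Path(path).write_text("\n".join(lines) + "\n")


def write_msh(path, mesh: SkinMesh) -> None:
    """Write a Gmsh MSH 2.2 ASCII file (1-based ids, element type 3 = quad)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat",
             "$Nodes", str(mesh.n_nodes)]
    for i, (x, y) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.9g} {y:.9g} 0")
    lines += ["$EndNodes", "$Elements", str(mesh.n_elements)]
    region = mesh.region if mesh.region is not None else np.zeros(
        mesh.n_elements, dtype=int)
    for e, q in enumerate(mesh.quads, start=1):
        tag = int(region[e - 1]) + 1
        ids = " ".join(str(int(i) + 1) for i in q)
        lines.append(f"{e} 3 2 {tag} {tag} {ids}")
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")
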