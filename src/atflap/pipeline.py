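"""End-to-end orchestration: design -> mesh -> suture -> release -> report.

Defaults reproduce the reference simulation setup: a 10 mm defect, a 60
degree apex angle, a 90 x 100 mm skin domain meshed with 3 mm quads (3 mm
sits inside the 2-5 mm clinical suture-bite-stitch-interval), and the
two-term incompressible Ogden facial-skin parameters.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from .geometry import design_flap
from .material import FACIAL_SKIN, OgdenParameters
from .mesh import build_domain, closure_plan, generate_mesh, quality_report
from .solver import SolverConfig, run_suture_then_release

__all__ = ["SimulationConfig", "RunReport", "run_pipeline",
           "mesh_sensitivity_study"]

log = logging.getLogger("atflap")


@dataclass
class SimulationConfig:
    """Configuration for one full A-T flap simulation (mm / MPa / deg)."""

    defect_radius: float = 10.0
    apex_angle_deg: float = 60.0
    domain_width: float = 90.0
    domain_height: float = 100.0
    element_size: float = 3.0
    base_extension_factor: float = 3.0
    material: OgdenParameters = field(default_factory=lambda: FACIAL_SKIN)
    solver: SolverConfig = field(default_factory=SolverConfig)
    output_dir: str | None = None

    def validate(self) -> None:
        for name in ("defect_radius", "domain_width", "domain_height",
                     "element_size"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if not (10.0 < self.apex_angle_deg < 170.0):
            raise ValueError("apex angle must lie in (10, 170) degrees")
        self.solver.validate()
        self.material.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["material"] = {"mu_mpa": list(self.material.mu),
                         "alpha": list(self.material.alpha),
                         "bulk_modulus_mpa": self.material.bulk_modulus}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        mat = d.pop("material", None)
        solver = d.pop("solver", None)
        cfg = cls(**d)
        if mat is not None:
            cfg.material = OgdenParameters(
                mu=tuple(mat["mu_mpa"]), alpha=tuple(mat["alpha"]),
                bulk_modulus=mat.get("bulk_modulus_mpa"))
        if solver is not None:
            cfg.solver = SolverConfig(**solver)
        return cfg

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def read(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    """Summary of one pipeline run (design, mesh, per-stage maxima)."""

    design: dict
    mesh: dict
    suture: dict
    release: dict
    convergence: dict
    manifest: list

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_summary(sol) -> dict:
    return {
        "max_von_mises_mpa": sol.max_von_mises,
        "max_von_mises_location_mm": [float(v) for v in
                                      sol.max_von_mises_location],
        "max_displacement_mm": sol.max_displacement,
        "max_displacement_location_mm": [float(v) for v in
                                         sol.max_displacement_location],
        "converged": bool(sol.converged),
    }


def run_pipeline(config: SimulationConfig) -> RunReport:
    """Execute all stages and (optionally) write artifacts.

    Deterministic: rerunning with the same config reproduces the report.
    """
    config.validate()
    t0 = time.perf_counter()
    design = design_flap(config.defect_radius, config.apex_angle_deg,
                         config.base_extension_factor)
    domain = build_domain(design, config.domain_width, config.domain_height)
    mesh = generate_mesh(domain, config.element_size)
    quality = quality_report(mesh)
    plan = closure_plan(mesh)
    log.info("meshed %d elements / %d nodes at %.2f mm",
             mesh.n_elements, mesh.n_nodes, config.element_size)
    suture, release = run_suture_then_release(mesh, config.material,
                                              config.solver)
    log.info("suture: max vM %.3f MPa, max |u| %.3f mm (%d Newton iters)",
             suture.max_von_mises, suture.max_displacement,
             suture.newton_iterations)
    log.info("release: max vM %.3f MPa, max |u| %.3f mm (%d Newton iters)",
             release.max_von_mises, release.max_displacement,
             release.newton_iterations)

    manifest = []
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.write(out / "config.yaml")
        manifest.append("config.yaml")
        _io.write_vtk(out / "mesh.vtk", mesh,
                      cell_data={"region": mesh.region})
        manifest.append("mesh.vtk")
        for tag, sol in (("suture", suture), ("release", release)):
            _io.write_vtk(
                out / f"{tag}.vtk", mesh,
                point_data={"displacement": sol.u,
                            "von_mises": sol.nodal_von_mises},
                cell_data={"von_mises_cell": sol.element_von_mises},
            )
            manifest.append(f"{tag}.vtk")
            pd.DataFrame({
                "node": range(mesh.n_nodes),
                "x_mm": mesh.nodes[:, 0], "y_mm": mesh.nodes[:, 1],
                "ux_mm": sol.u[:, 0], "uy_mm": sol.u[:, 1],
                "von_mises_mpa": sol.nodal_von_mises,
            }).to_csv(out / f"{tag}_nodal.csv", index=False)
            manifest.append(f"{tag}_nodal.csv")

    report = RunReport(
        design={
            "defect_radius_mm": design.defect_radius,
            "apex_angle_deg": design.apex_angle_deg,
            "flap_length_mm": design.flap_length,
            "flap_width_mm": design.flap_width,
            "ratio": design.ratio,
            "suture_area_mm2": design.suture_area,
            "joint_height_mm": plan.joint_height,
        },
        mesh={
            "n_elements": mesh.n_elements,
            "n_nodes": mesh.n_nodes,
            "element_size_mm": config.element_size,
            "n_inverted": quality.n_inverted,
            "n_distorted": quality.n_distorted,
            "n_bad_aspect": quality.n_bad_aspect,
        },
        suture=_stage_summary(suture),
        release=_stage_summary(release),
        convergence={
            "suture_newton_iterations": suture.newton_iterations,
            "release_newton_iterations": release.newton_iterations,
            "runtime_s": time.perf_counter() - t0,
        },
        manifest=manifest,
    )
    if config.output_dir is not None:
        d = report.to_dict()
        d["convergence"] = {k: v for k, v in d["convergence"].items()
                            if k != "runtime_s"}  # keep reports reproducible
        (Path(config.output_dir) / "report.json").write_text(
            json.dumps(d, indent=2))
        report.manifest.append("report.json")
    report._solutions = (suture, release)  # for callers needing full fields
    return report


def mesh_sensitivity_study(config: SimulationConfig, sizes) -> pd.DataFrame:
    """Element-size sensitivity: quality and release-state maxima per size.

    One row per element size with element/node counts, the quality triple
    (inverted / distorted / bad aspect) and the release-stage maximum nodal
    von Mises stress and displacement.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("need at least one element size")
    rows = []
    for size in sizes:
        cfg = SimulationConfig.from_dict(
            {**config.to_dict(), "element_size": float(size),
             "output_dir": None})
        report = run_pipeline(cfg)
        rows.append({
            "element_size_mm": float(size),
            "n_elements": report.mesh["n_elements"],
            "n_nodes": report.mesh["n_nodes"],
            "release_max_von_mises_mpa": report.release["max_von_mises_mpa"],
            "release_max_displacement_mm":
                report.release["max_displacement_mm"],
            "n_inverted": report.mesh["n_inverted"],
            "n_distorted": report.mesh["n_distorted"],
            "n_bad_aspect": report.mesh["n_bad_aspect"],
        })
    return pd.DataFrame(rows)
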