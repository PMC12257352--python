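"""End-to-end validation workflow over scenarios and multi-fraction courses.

Each scenario plays one treatment fraction: author a known deformation on the
phantom, synthesise the modified CT and the fraction dose on it, accumulate
that dose back to the planning anatomy twice — once through the inverse of
the authored (true) field and once through the registration under test — and
compare the two accumulated doses with gamma analysis, clinical-goal
evaluation and contour/displacement metrics.  A course sums the per-fraction
accumulations and repeats the comparison on the summed dose.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .deform import DeformationSpec, author_field, scenario_presets
from .dvh import (GoalResult, eval_goal, goal_discrepancy, scale_to_course, worst_per_goal)
from .gamma import GammaConfig, multi_criteria
from .grid import ScalarVolume, StructureSet, VectorField
from .metrics import dice, dvf_stats_per_structure, hausdorff
from .phantom import PhantomConfig, PrescriptionContext, build_phantom, synth_fraction_dose
from .register import RegistrationParams, estimate_field, register_with_oracle
from .warp import accumulate_dose_ddm, invert_field, sum_doses, warp_image, warp_structures

__all__ = [
    "ScenarioConfig",
    "CourseConfig",
    "ScenarioResult",
    "ValidationReport",
    "run_scenario",
    "run_course",
    "emit_report",
    "load_course_config",
]

_DEFAULT_CRITERIA = [(1.0, 1.0), (3.0, 2.0), (5.0, 3.0)]
_CONTOUR_STRUCTURES = ("bladder", "rectum", "prostate", "uterus", "CTV", "PTV")


@dataclass
class ScenarioConfig:
    name: str
    deformations: list[DeformationSpec] = dc_field(default_factory=list)


@dataclass
class CourseConfig:
    phantom: PhantomConfig
    scenarios: list[ScenarioConfig]
    registration: RegistrationParams | str = "oracle"
    technique: str = "imrt9"
    gamma_criteria: list = dc_field(default_factory=lambda: list(_DEFAULT_CRITERIA))
    inversion_tol_mm: float = 0.05
    seed: int = 0

    @property
    def use_oracle(self) -> bool:
        return isinstance(self.registration, str)


@dataclass
class ScenarioResult:
    name: str
    dose_true: ScalarVolume
    dose_est: ScalarVolume
    gamma_table: pd.DataFrame
    goals_true: list[GoalResult]
    goals_est: list[GoalResult]
    dvf_stats_true: pd.DataFrame
    dvf_stats_est: pd.DataFrame
    contour_table: pd.DataFrame
    inversion_residual_mm: float
    field_true: VectorField
    field_est: VectorField


@dataclass
class ValidationReport:
    site: str
    scenario_results: list[ScenarioResult]
    course_gamma: pd.DataFrame
    course_goals_true: list[GoalResult]
    course_goals_est: list[GoalResult]
    discrepancy: object
    rx: PrescriptionContext


def _stage(name: str):
    """Tag exceptions with the pipeline stage that raised them."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[stage: {name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_scenario(
    cfg: ScenarioConfig,
    ct_plan: ScalarVolume,
    structures: StructureSet,
    rx: PrescriptionContext,
    course: CourseConfig,
) -> ScenarioResult:
    """Execute one fraction scenario against the shared phantom."""
    grid = ct_plan.grid
    body = structures["body"]

    with _stage("author_true_field"):
        u_true = author_field(structures, cfg.deformations)
    with _stage("synthesize_ct_mod"):
        ct_mod = warp_image(ct_plan, u_true)
        structures_mod = warp_structures(structures, u_true)
    with _stage("fraction_dose"):
        # scheduled-plan analogue: apertures frozen on the planning PTV, body
        # taken from the modified anatomy
        dose_structs = StructureSet(grid, {"PTV": structures["PTV"],
                                           "body": structures_mod["body"]})
        d_fx = synth_fraction_dose(dose_structs, rx, technique=course.technique,
                                   seed=course.seed)
    with _stage("invert_true_field"):
        phi_true = invert_field(u_true, tol_mm=course.inversion_tol_mm, mask=body)
    with _stage("accumulate_true"):
        d_true = accumulate_dose_ddm(d_fx, phi_true, target=grid)
    with _stage("registration_under_test"):
        if course.use_oracle:
            phi_est = register_with_oracle(u_true, tol_mm=course.inversion_tol_mm, mask=body)
        else:
            phi_est = estimate_field(ct_plan, ct_mod, course.registration)
    with _stage("accumulate_estimated"):
        d_est = accumulate_dose_ddm(d_fx, phi_est, target=grid)
    with _stage("gamma_analysis"):
        gamma_table = multi_criteria(d_true, d_est, course.gamma_criteria)
        gamma_table.insert(0, "scenario", cfg.name)
    with _stage("clinical_goals"):
        d_true_course = scale_to_course(d_true, rx.n_fractions)
        d_est_course = scale_to_course(d_est, rx.n_fractions)
        goals_true = [eval_goal(g, d_true_course, structures, rx) for g in rx.goal_set]
        goals_est = [eval_goal(g, d_est_course, structures, rx) for g in rx.goal_set]
    with _stage("dvf_statistics"):
        stats_true = dvf_stats_per_structure(phi_true, structures)
        stats_true.insert(0, "scenario", cfg.name)
        stats_est = dvf_stats_per_structure(phi_est, structures)
        stats_est.insert(0, "scenario", cfg.name)
    with _stage("contour_metrics"):
        structures_back = warp_structures(structures_mod, phi_est, target=grid)
        rows = []
        for name in _CONTOUR_STRUCTURES:
            if name not in structures:
                continue
            rows.append({
                "scenario": cfg.name,
                "structure": name,
                "dice": dice(structures[name], structures_back[name]),
                "hausdorff_mm": hausdorff(structures[name], structures_back[name],
                                          grid.spacing),
            })
        contour_table = pd.DataFrame(rows, columns=["scenario", "structure", "dice",
                                                    "hausdorff_mm"])

    return ScenarioResult(
        name=cfg.name,
        dose_true=d_true,
        dose_est=d_est,
        gamma_table=gamma_table,
        goals_true=goals_true,
        goals_est=goals_est,
        dvf_stats_true=stats_true,
        dvf_stats_est=stats_est,
        contour_table=contour_table,
        inversion_residual_mm=getattr(phi_true, "residual_mm", float("nan")),
        field_true=phi_true,
        field_est=phi_est,
    )


def run_course(course: CourseConfig) -> ValidationReport:
    """Run every scenario as a fraction of one course and analyse the summed dose."""
    ct_plan, structures, rx = build_phantom(course.phantom)
    results = [run_scenario(sc, ct_plan, structures, rx, course) for sc in course.scenarios]

    n_fx = len(results)
    with _stage("course_summation"):
        # sum the accumulated fractions, then scale to the prescribed fractionation
        scale = rx.n_fractions / n_fx
        sum_true = sum_doses([r.dose_true for r in results])
        sum_est = sum_doses([r.dose_est for r in results])
        sum_true = ScalarVolume(sum_true.grid, sum_true.values * scale, "Gy")
        sum_est = ScalarVolume(sum_est.grid, sum_est.values * scale, "Gy")
        course_gamma = multi_criteria(sum_true, sum_est, course.gamma_criteria)
        course_gamma.insert(0, "scenario", "course_sum")
        course_goals_true = [eval_goal(g, sum_true, structures, rx) for g in rx.goal_set]
        course_goals_est = [eval_goal(g, sum_est, structures, rx) for g in rx.goal_set]
    discrepancy = goal_discrepancy([r.goals_est for r in results],
                                   [r.goals_true for r in results])
    return ValidationReport(
        site=course.phantom.site,
        scenario_results=results,
        course_gamma=course_gamma,
        course_goals_true=course_goals_true,
        course_goals_est=course_goals_est,
        discrepancy=discrepancy,
        rx=rx,
    )


def _goal_frame(report: ValidationReport) -> pd.DataFrame:
    """Course goal table with worst-across-fractions bracket columns."""
    worst_true = worst_per_goal([r.goals_true for r in report.scenario_results])
    worst_est = worst_per_goal([r.goals_est for r in report.scenario_results])
    rows = []
    for i, goal in enumerate(report.rx.goal_set):
        rt = report.course_goals_true[i]
        re_ = report.course_goals_est[i]
        rows.append({
            "structure": goal.structure,
            "goal": goal.text,
            "unit": goal.report_unit,
            "value_true": rt.value,
            "worst_fraction_true": worst_true[i],
            "met_true": rt.met,
            "within_variation_true": rt.within_variation,
            "value_est": re_.value,
            "worst_fraction_est": worst_est[i],
            "met_est": re_.met,
            "within_variation_est": re_.within_variation,
        })
    return pd.DataFrame(rows)


def _fraction_goal_frame(report: ValidationReport) -> pd.DataFrame:
    rows = []
    for r in report.scenario_results:
        for gt, ge in zip(r.goals_true, r.goals_est):
            rows.append({
                "scenario": r.name,
                "structure": gt.goal.structure,
                "goal": gt.goal.text,
                "unit": gt.goal.report_unit,
                "value_true": gt.value,
                "met_true": gt.met,
                "value_est": ge.value,
                "met_est": ge.met,
            })
    return pd.DataFrame(rows)


def emit_report(report: ValidationReport, outdir: str | Path,
                write_volumes: bool = False, plots: bool = False) -> dict[str, Path]:
    """Write CSV tables + JSON summary (and optionally volumes / PNG overlays)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.6f"

    gamma = pd.concat([r.gamma_table for r in report.scenario_results]
                      + [report.course_gamma], ignore_index=True)
    dvf = pd.concat(
        [r.dvf_stats_true.assign(field="true_inverse") for r in report.scenario_results]
        + [r.dvf_stats_est.assign(field="estimated") for r in report.scenario_results],
        ignore_index=True,
    )
    contours = pd.concat([r.contour_table for r in report.scenario_results],
                         ignore_index=True)
    paths = {}
    for name, frame in [("gamma_results", gamma), ("dvf_magnitudes", dvf),
                        ("contour_metrics", contours),
                        ("goals_per_fraction", _fraction_goal_frame(report)),
                        ("goals_course", _goal_frame(report))]:
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format=float_fmt)
        paths[name] = p

    summary = {
        "site": report.site,
        "n_fractions": len(report.scenario_results),
        "prescription_Gy": report.rx.total_dose_Gy,
        "prescribed_fractions": report.rx.n_fractions,
        "goal_discrepancy": {
            "passed_sys_failed_true": report.discrepancy.passed_sys_failed_true,
            "failed_sys_passed_true": report.discrepancy.failed_sys_passed_true,
            "n_goals": report.discrepancy.n_goals,
            "n_fractions": report.discrepancy.n_fractions,
            "percentage": report.discrepancy.percentage,
        },
        "inversion_residual_max_mm": max(r.inversion_residual_mm
                                         for r in report.scenario_results),
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=1, sort_keys=True))
    paths["summary"] = p

    if write_volumes:
        for r in report.scenario_results:
            dio.write_volume(r.dose_true, outdir / f"dose_true_{r.name}.nii.gz")
            dio.write_volume(r.dose_est, outdir / f"dose_est_{r.name}.nii.gz")
    if plots:
        _sagittal_overlays(report, outdir)
    return paths


def _sagittal_overlays(report: ValidationReport, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for r in report.scenario_results:
        mid = r.dose_true.grid.size[0] // 2
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, vol, title in [(axes[0], r.dose_true, "accumulated (true field)"),
                               (axes[1], r.dose_est, "accumulated (system)")]:
            im = ax.imshow(np.asarray(vol.values)[mid].T, origin="lower", cmap="jet")
            ax.set_title(f"{r.name}: {title}")
            fig.colorbar(im, ax=ax, label="Gy")
        fig.tight_layout()
        fig.savefig(outdir / f"overlay_{r.name}.png", dpi=100)
        plt.close(fig)


def load_course_config(path_or_dict) -> CourseConfig:
    """Build a CourseConfig from a YAML file or an equivalent mapping."""
    if isinstance(path_or_dict, (str, Path)):
        cfg = yaml.safe_load(Path(path_or_dict).read_text())
    else:
        cfg = dict(path_or_dict)

    phantom_kwargs = dict(cfg.get("phantom", {}))
    phantom_kwargs.setdefault("site", cfg.get("site", "prostate_like"))
    if "grid" in cfg:
        phantom_kwargs.setdefault("size", tuple(cfg["grid"]["size"]))
        phantom_kwargs.setdefault("spacing", tuple(cfg["grid"]["spacing"]))
    phantom_kwargs.setdefault("seed", cfg.get("seed", 0))
    if "size" in phantom_kwargs:
        phantom_kwargs["size"] = tuple(phantom_kwargs["size"])
    if "spacing" in phantom_kwargs:
        phantom_kwargs["spacing"] = tuple(phantom_kwargs["spacing"])
    phantom = PhantomConfig(**phantom_kwargs)

    scen_cfg = cfg.get("scenarios", "preset")
    scenarios: list[ScenarioConfig] = []
    if scen_cfg == "preset":
        for name, specs in scenario_presets(phantom.site).items():
            scenarios.append(ScenarioConfig(name, specs))
    else:
        for entry in scen_cfg:
            specs = []
            for d in entry.get("deformations", []):
                d = dict(d)
                if "shift_mm" in d:
                    d["shift_mm"] = tuple(d["shift_mm"])
                specs.append(DeformationSpec(**d))
            scenarios.append(ScenarioConfig(entry["name"], specs))

    reg_cfg = cfg.get("registration", "oracle")
    registration: RegistrationParams | str
    if isinstance(reg_cfg, str):
        registration = "oracle"
    else:
        reg_cfg = dict(reg_cfg)
        if "iterations" in reg_cfg:
            reg_cfg["iterations"] = tuple(reg_cfg["iterations"])
        reg_cfg.setdefault("seed", cfg.get("seed", 0))
        registration = RegistrationParams(**reg_cfg)

    criteria = [tuple(c) for c in cfg.get("gamma", _DEFAULT_CRITERIA)]
    return CourseConfig(
        phantom=phantom,
        scenarios=scenarios,
        registration=registration,
        technique=cfg.get("technique", "imrt9"),
        gamma_criteria=criteria,
        inversion_tol_mm=float(cfg.get("inversion_tol_mm", 0.05)),
        seed=int(cfg.get("seed", 0)),
    )


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
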