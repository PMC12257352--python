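"""DVH metrics, clinical-goal evaluation and the goal-discrepancy statistic.

Clinical goals are written in the compact grammar used on planning systems,
e.g. ``"D0.03cc < 105% (109%)"`` — the minimum dose to the hottest 0.03 cc
must stay below 105 % of the prescription, with an allowed variation up to
109 % — or ``"V60Gy < 3% (10%)"`` and ``"V45Gy < 50cc"``.  Relative-dose
thresholds (%) resolve against the prescription total dose.  Inequalities are
strict: a value exactly at the threshold fails.

The discrepancy statistic counts goals whose pass/fail flag differs between a
system-accumulated and a ground-truth dose across all fractions of a course,
reported as an integer percentage of all goal evaluations.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .grid import ScalarVolume, StructureSet

__all__ = [
    "Metric",
    "ClinicalGoal",
    "GoalResult",
    "DiscrepancySummary",
    "parse_goal",
    "load_goal_set",
    "eval_metric",
    "eval_goal",
    "scale_to_course",
    "goal_discrepancy",
    "worst_per_goal",
]


@dataclass(frozen=True)
class Metric:
    """A DVH metric: ``D_pct(v %)``, ``D_cc(v cc)`` or ``V_Gy(d Gy)``."""

    kind: str  # "D_pct" | "D_cc" | "V_Gy"
    param: float

    def __post_init__(self) -> None:
        if self.kind not in ("D_pct", "D_cc", "V_Gy"):
            raise ValueError(f"unknown metric kind {self.kind!r}")

    def label(self) -> str:
        if self.kind == "D_pct":
            return f"D{self.param:g}%"
        if self.kind == "D_cc":
            return f"D{self.param:g}cc"
        return f"V{self.param:g}Gy"


@dataclass(frozen=True)
class ClinicalGoal:
    """A DVH constraint with direction, threshold and optional allowed variation.

    ``threshold_unit`` is ``"%"``, ``"Gy"`` or ``"cc"``.  For D metrics a
    ``%`` threshold is relative to the prescription; for V metrics the
    threshold unit is the report unit (% of structure volume or absolute cc).
    """

    structure: str
    metric: Metric
    direction: str  # "less_than" | "greater_than"
    threshold: float
    threshold_unit: str
    variation: float | None = None
    text: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("less_than", "greater_than"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    @property
    def report_unit(self) -> str:
        if self.metric.kind in ("D_pct", "D_cc"):
            return "Gy"
        return self.threshold_unit  # "%" or "cc" for V metrics

    def label(self) -> str:
        return f"{self.structure} {self.text or self.metric.label()}"


@dataclass
class GoalResult:
    goal: ClinicalGoal
    value: float  # in goal.report_unit
    met: bool
    within_variation: bool


@dataclass
class DiscrepancySummary:
    """Counts of goal-adherence flips between system and truth over a course."""

    passed_sys_failed_true: int
    failed_sys_passed_true: int
    n_goals: int
    n_fractions: int

    @property
    def percentage(self) -> int:
        total = self.n_goals * self.n_fractions
        flips = self.passed_sys_failed_true + self.failed_sys_passed_true
        return int(round(100.0 * flips / total))


_GOAL_RE = re.compile(
    r"^\s*([DV])\s*([\d.]+)\s*(%|cc|Gy)\s*([<>])\s*([\d.]+)\s*(%|cc|Gy)\s*(?:\(\s*([\d.]+)\s*(%|cc|Gy)?\s*\))?\s*$"
)


def parse_goal(structure: str, text: str) -> ClinicalGoal:
    """Parse a goal string like ``"D0.03cc < 105% (109%)"`` or ``"V45Gy < 50cc"``."""
    m = _GOAL_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse clinical goal {text!r}")
    letter, param, param_unit, op, thr, thr_unit, var, var_unit = m.groups()
    param = float(param)
    if letter == "D":
        if param_unit == "%":
            metric = Metric("D_pct", param)
        elif param_unit == "cc":
            metric = Metric("D_cc", param)
        else:
            raise ValueError(f"D metric parameter must be % or cc in {text!r}")
        if thr_unit == "cc":
            raise ValueError(f"D metric threshold cannot be in cc: {text!r}")
    else:
        if param_unit != "Gy":
            raise ValueError(f"V metric parameter must be in Gy: {text!r}")
        if thr_unit == "Gy":
            raise ValueError(f"V metric threshold must be % or cc: {text!r}")
        metric = Metric("V_Gy", param)
    variation = float(var) if var is not None else None
    if var is not None and var_unit is not None and var_unit != thr_unit:
        raise ValueError(f"variation unit must match threshold unit in {text!r}")
    return ClinicalGoal(
        structure=structure,
        metric=metric,
        direction="less_than" if op == "<" else "greater_than",
        threshold=float(thr),
        threshold_unit=thr_unit,
        variation=variation,
        text=text,
    )


def load_goal_set(site: str) -> list[ClinicalGoal]:
    """Load the built-in goal set for ``prostate_like`` or ``cervix_like``."""
    fname = {"prostate_like": "goals_prostate.json", "cervix_like": "goals_cervix.json"}[site]
    data = json.loads(resources.files("dosewarp").joinpath("data", fname).read_text())
    return [parse_goal(entry["structure"], entry["goal"]) for entry in data]


def eval_metric(dose: ScalarVolume, mask: np.ndarray, metric: Metric,
                report_unit: str | None = None) -> float:
    """Evaluate one DVH metric over a structure mask.

    D metrics use partial-voxel linear interpolation on the sorted
    dose-coverage curve (voxel k of the descending sort is placed at
    cumulative volume (k - 1/2) voxels), so sub-voxel volumes such as
    0.03 cc are grid-independent.  V metrics count voxels with dose >= d.
    """
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty structure mask")
    d = np.asarray(dose.values)[mask].astype(float)
    w_cc = dose.grid.voxel_volume_cc
    total_cc = n * w_cc
    if metric.kind == "V_Gy":
        frac = float(np.count_nonzero(d >= metric.param)) / n
        if report_unit == "cc":
            return frac * total_cc
        return 100.0 * frac
    if metric.kind == "D_pct":
        target_cc = metric.param / 100.0 * total_cc
    else:
        target_cc = metric.param
        if target_cc > total_cc:
            raise ValueError(
                f"requested volume {target_cc} cc exceeds structure volume {total_cc:.3f} cc"
            )
    d_desc = np.sort(d)[::-1]
    vol_mid = (np.arange(1, n + 1) - 0.5) * w_cc
    return float(np.interp(target_cc, vol_mid, d_desc))


def scale_to_course(per_fraction_dose: ScalarVolume, n_fractions: int) -> ScalarVolume:
    """Scale a single-fraction dose to the full course (voxel-wise * n)."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    return ScalarVolume(per_fraction_dose.grid,
                        np.asarray(per_fraction_dose.values) * float(n_fractions), "Gy")


def _resolve_threshold(goal: ClinicalGoal, value_thr: float, rx) -> float:
    """Absolute threshold in the goal's report unit."""
    if goal.metric.kind in ("D_pct", "D_cc") and goal.threshold_unit == "%":
        return value_thr / 100.0 * rx.total_dose_Gy
    return value_thr


def eval_goal(goal: ClinicalGoal, dose: ScalarVolume, structures: StructureSet, rx) -> GoalResult:
    """Evaluate one clinical goal; strict inequalities, no rounding before comparison."""
    mask = structures[goal.structure]
    value = eval_metric(dose, mask, goal.metric, report_unit=goal.report_unit)
    thr = _resolve_threshold(goal, goal.threshold, rx)
    if goal.direction == "less_than":
        met = value < thr
    else:
        met = value > thr
    if goal.variation is None:
        within = met
    else:
        var_thr = _resolve_threshold(goal, goal.variation, rx)
        within = (value < var_thr) if goal.direction == "less_than" else (value > var_thr)
        within = within or met
    return GoalResult(goal, float(value), bool(met), bool(within))


def goal_discrepancy(
    results_sys: Sequence[Sequence],
    results_true: Sequence[Sequence],
    use_variation: bool = False,
) -> DiscrepancySummary:
    """Count pass/fail flips between system and true dose over matched fractions.

    Inputs are per-fraction sequences of :class:`GoalResult` (or booleans) in
    matched order.  ``use_variation`` switches the flip criterion to the
    allowed-variation flag instead of the primary goal flag.
    """
    if len(results_sys) != len(results_true):
        raise ValueError("fraction counts differ between system and true results")
    a = b = 0
    n_goals = None
    for fx_sys, fx_true in zip(results_sys, results_true):
        if len(fx_sys) != len(fx_true):
            raise ValueError("goal counts differ between system and true results")
        if n_goals is None:
            n_goals = len(fx_sys)
        elif len(fx_sys) != n_goals:
            raise ValueError("goal counts differ across fractions")
        for rs, rt in zip(fx_sys, fx_true):
            ps = _pass_flag(rs, use_variation)
            pt = _pass_flag(rt, use_variation)
            if ps and not pt:
                a += 1
            elif pt and not ps:
                b += 1
    if n_goals is None or n_goals == 0:
        raise ValueError("no goals to compare")
    return DiscrepancySummary(a, b, n_goals, len(results_sys))


def _pass_flag(r, use_variation: bool) -> bool:
    if isinstance(r, (bool, np.bool_)):
        return bool(r)
    return bool(r.within_variation if use_variation else r.met)


def worst_per_goal(per_fraction_results: Sequence[Sequence[GoalResult]]) -> list[float]:
    """Per goal, the value farthest in the failing direction across fractions.

    Maximum for ``less_than`` goals, minimum for ``greater_than`` goals.
    """
    if len(per_fraction_results) < 1:
        raise ValueError("need at least one fraction")
    n_goals = len(per_fraction_results[0])
    worst: list[float] = []
    for g in range(n_goals):
        vals = [fx[g].value for fx in per_fraction_results]
        goal = per_fraction_results[0][g].goal
        worst.append(max(vals) if goal.direction == "less_than" else min(vals))
    return worst
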