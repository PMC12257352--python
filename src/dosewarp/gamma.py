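"""3-D gamma-index comparison of dose distributions.

For every reference voxel above the low-dose threshold, the gamma index is
the minimum over candidate points p of

    sqrt( |p - r|^2 / dta^2  +  (D_eval(p) - D_ref(r))^2 / dd^2 )

with the dose criterion ``dd`` taken as a percentage of the reference's
global maximum (global normalisation) and candidates on a subvoxel lattice of
pitch ``interp_step_mm`` within ``search_cap_mm`` of r, evaluated trilinearly.
A voxel passes when gamma <= 1; the pass rate is reported over evaluated
voxels only (the threshold applies to the reference dose alone).

The search processes candidate offsets in order of increasing distance and
abandons a voxel as soon as the pure-distance term exceeds its running
minimum, which makes near-agreeing distributions cheap while remaining an
exact minimisation over the candidate lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ScalarVolume, resample_to_grid

__all__ = ["GammaConfig", "GammaResult", "gamma_map", "multi_criteria"]


@dataclass(frozen=True)
class GammaConfig:
    """Gamma criterion: dose difference (% of global max) / distance to agreement (mm)."""

    dose_criterion_pct: float
    distance_criterion_mm: float
    threshold_fraction: float = 0.10
    normalization: str = "global_max"
    search_cap_mm: float | None = None  # default 2 * dta
    interp_step_mm: float | None = None  # default dta / 10

    def __post_init__(self) -> None:
        if self.dose_criterion_pct <= 0 or self.distance_criterion_mm <= 0:
            raise ValueError("gamma criteria must be > 0")
        if not 0.0 <= self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in [0, 1)")
        if self.normalization != "global_max":
            raise ValueError("only global_max normalization is supported")

    @property
    def cap_mm(self) -> float:
        return self.search_cap_mm if self.search_cap_mm is not None else 2.0 * self.distance_criterion_mm

    @property
    def step_mm(self) -> float:
        return self.interp_step_mm if self.interp_step_mm is not None else self.distance_criterion_mm / 10.0

    def label(self) -> str:
        return f"{self.dose_criterion_pct:g}%/{self.distance_criterion_mm:g}mm"


@dataclass
class GammaResult:
    pass_rate_pct: float
    gamma_map: ScalarVolume
    n_evaluated: int
    config: GammaConfig


def _candidate_offsets(cap_mm: float, step_mm: float) -> np.ndarray:
    """Offsets on the subvoxel lattice within the search cap, sorted by distance."""
    n = int(np.floor(cap_mm / step_mm))
    ax = np.arange(-n, n + 1) * step_mm
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d2 = (offs ** 2).sum(axis=1)
    keep = d2 <= cap_mm ** 2 + 1e-12
    offs, d2 = offs[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return offs[order]


def gamma_map(reference: ScalarVolume, evaluated: ScalarVolume, config: GammaConfig) -> GammaResult:
    """Compute the gamma map and pass rate of ``evaluated`` against ``reference``."""
    if reference.quantity != "Gy" or evaluated.quantity != "Gy":
        raise ValueError("gamma analysis expects Gy volumes")
    if evaluated.grid != reference.grid:
        evaluated = resample_to_grid(evaluated, reference.grid, mode="linear")

    ref = np.asarray(reference.values, float)
    ev = np.asarray(evaluated.values, float)
    grid = reference.grid
    global_max = float(ref.max())
    if global_max <= 0:
        raise ValueError("reference dose is all zero; nothing above threshold")
    thr = config.threshold_fraction * global_max
    eval_mask = ref >= thr
    if not eval_mask.any():
        raise ValueError("no reference voxels above the threshold dose")

    dd = config.dose_criterion_pct / 100.0 * global_max
    dta = config.distance_criterion_mm
    spacing = np.asarray(grid.spacing)

    idx = np.argwhere(eval_mask).astype(float)  # index coords of evaluated voxels
    ref_vals = ref[eval_mask]
    flat_ids = np.flatnonzero(eval_mask.ravel())

    offsets = _candidate_offsets(config.cap_mm, config.step_mm)
    d2 = (offsets ** 2).sum(axis=1)

    # start from the zero-offset candidate (pure dose difference)
    ev_here = ev[eval_mask]
    best = ((ev_here - ref_vals) / dd) ** 2

    active = np.arange(idx.shape[0])
    act_idx = idx
    act_ref = ref_vals
    k = 1  # offset 0 already done (offsets[0] is the zero vector)
    chunk = 48
    while k < offsets.shape[0] and active.size:
        k_end = min(k + chunk, offsets.shape[0])
        for j in range(k, k_end):
            t = d2[j] / dta ** 2
            if t >= best[active].max():
                k_end = offsets.shape[0]  # sorted by distance: nothing can improve
                active = np.empty(0, dtype=int)
                break
            coords = (act_idx + offsets[j] / spacing).T
            vals = ndimage.map_coordinates(ev, coords, order=1, mode="constant", cval=np.nan)
            g2 = t + ((vals - act_ref) / dd) ** 2
            improved = g2 < best[active]
            improved &= ~np.isnan(g2)
            if improved.any():
                upd = active[improved]
                best[upd] = g2[improved]
        k = k_end
        if active.size and k < offsets.shape[0]:
            t_next = d2[k] / dta ** 2
            keep = best[active] > t_next
            active = active[keep]
            act_idx = idx[active]
            act_ref = ref_vals[active]

    gam = np.sqrt(best)
    gmap = np.zeros(grid.size)
    gmap.ravel()[flat_ids] = gam
    pass_rate = 100.0 * float(np.count_nonzero(gam <= 1.0)) / gam.size
    return GammaResult(pass_rate, ScalarVolume(grid, gmap, "mask"), int(gam.size), config)


def multi_criteria(
    reference: ScalarVolume,
    evaluated: ScalarVolume,
    criteria: list,
) -> pd.DataFrame:
    """One gamma analysis per criterion; returns a tidy table.

    Each criterion is a :class:`GammaConfig` or a ``(dose_pct, dist_mm)``
    pair.  Pass rates are non-increasing as criteria tighten.
    """
    rows = []
    for crit in criteria:
        cfg = crit if isinstance(crit, GammaConfig) else GammaConfig(*crit)
        res = gamma_map(reference, evaluated, cfg)
        rows.append(
            {
                "dose_criterion_pct": cfg.dose_criterion_pct,
                "distance_criterion_mm": cfg.distance_criterion_mm,
                "criterion": cfg.label(),
                "pass_rate_pct": res.pass_rate_pct,
                "n_evaluated": res.n_evaluated,
            }
        )
    return pd.DataFrame(rows, columns=["dose_criterion_pct", "distance_criterion_mm",
                                       "criterion", "pass_rate_pct", "n_evaluated"])
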