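"""Authoring of known, invertible organ deformation fields.

Fields are authored directly in the ``mod_to_plan`` pull-back convention —
``CT_mod(x) = CT_plan(x + u(x))`` — so synthesising the modified image needs
no inversion, and the accumulation ground truth is exactly the numerically
inverted authored field.  Each organ deformation is a radial map about the
organ centroid: linear inside the (expanded/shrunken) organ so the Jacobian
stays positive, with a Gaussian falloff of length ``decay_mm`` outside.
Displacement is forced to zero inside the femoral heads and outside the body,
and the field is screened with a central-difference Jacobian determinant
before being accepted.

Deformation magnitudes follow the conventional classes: peak displacement
below 5 mm is *small*, 5–10 mm *medium*, above 10 mm *large*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import StructureSet, VectorField

__all__ = [
    "DeformationSpec",
    "author_field",
    "verify_invertibility",
    "classify_magnitude",
    "scenario_presets",
    "MAGNITUDE_MEDIUM_MM",
    "MAGNITUDE_LARGE_MM",
    "MAGNITUDE_BLADDER_LARGE_EXPANSION_MM",
]

# preset authoring magnitudes: mid-class for medium and large; the bladder
# "large expansion" scenario is authored much larger to emulate extreme filling
MAGNITUDE_MEDIUM_MM = 7.5
MAGNITUDE_LARGE_MM = 15.0
MAGNITUDE_BLADDER_LARGE_EXPANSION_MM = 30.0

_MIN_JACOBIAN = 0.05


@dataclass(frozen=True)
class DeformationSpec:
    """One organ deformation: expand/shrink by a target peak surface displacement,
    or shift by a 3-vector (mm)."""

    organ: str
    mode: str  # "expand" | "shrink" | "shift"
    magnitude_mm: float | None = None
    shift_mm: tuple[float, float, float] | None = None
    decay_mm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("expand", "shrink", "shift"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "shift":
            if self.shift_mm is None:
                raise ValueError("shift mode requires shift_mm")
        elif self.magnitude_mm is None or self.magnitude_mm <= 0:
            raise ValueError("expand/shrink require magnitude_mm > 0")
        if self.decay_mm <= 0:
            raise ValueError("decay_mm must be > 0")

    @property
    def peak_mm(self) -> float:
        if self.mode == "shift":
            return float(np.linalg.norm(self.shift_mm))
        return float(self.magnitude_mm)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _bc(axis: int):
    """Broadcast slicer putting a 1-D array along ``axis`` of a 3-D volume."""
    sl = [None, None, None]
    sl[axis] = slice(None)
    return tuple(sl)


def _organ_windows(structures: StructureSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(taper_distance_mm, femur_window, hard_zero).

    ``taper_distance_mm`` is the distance to the nearest of the body surface
    and the grid faces (a target-centred FOV carries no deformation at its
    border, and a field that is zero at the boundary inverts cleanly); the
    per-spec window smoothsteps it over a magnitude-scaled taper length.
    Bone gets a fixed 6 mm smoothstep and a hard zero.
    """
    grid = structures.grid
    body = structures["body"]
    d_in_body = ndimage.distance_transform_edt(body, sampling=grid.spacing)
    edges = [np.minimum(ax - ax[0], ax[-1] - ax)[_bc(a)]
             for a, ax in enumerate(grid.axes_mm())]
    edge = np.minimum(np.minimum(edges[0], edges[1]), edges[2])
    taper_dist = np.minimum(d_in_body, np.broadcast_to(edge, grid.size))
    femur_window = np.ones(grid.size)
    hard_zero = ~body
    for name in ("femur_L", "femur_R"):
        if name in structures:
            fem = structures[name]
            d_out_fem = ndimage.distance_transform_edt(~fem, sampling=grid.spacing)
            femur_window = femur_window * _smoothstep(d_out_fem / 6.0)
            hard_zero = hard_zero | fem
    return taper_dist, femur_window, hard_zero


def _max_stretch(disp: np.ndarray, spacing) -> float:
    """Largest singular value of the displacement gradient (checked only where
    the gradient is appreciable); bounds the Lipschitz constant of the field."""
    g = np.empty(disp.shape[:3] + (3, 3))
    for i in range(3):
        grads = np.gradient(disp[..., i], *spacing, axis=(0, 1, 2))
        for j in range(3):
            g[..., i, j] = grads[j]
    fro = np.sqrt((g ** 2).sum(axis=(-2, -1)))
    hot = fro > 1.0
    if not hot.any():
        return float(fro.max())
    sv = np.linalg.svd(g[hot], compute_uv=False)
    return float(sv[..., 0].max())


def _single_field(structures: StructureSet, spec: DeformationSpec,
                  taper_dist: np.ndarray, femur_window: np.ndarray,
                  hard_zero: np.ndarray) -> np.ndarray:
    grid = structures.grid
    taper_mm = max(12.0, 0.9 * spec.peak_mm)
    window = _smoothstep(taper_dist / taper_mm) * femur_window
    organ = structures[spec.organ]
    if not organ.any():
        raise ValueError(f"structure {spec.organ!r} is empty")
    spacing = np.asarray(grid.spacing)
    idx = np.argwhere(organ)
    centroid = idx.mean(axis=0) * spacing + np.asarray(grid.origin)
    vol_mm3 = idx.shape[0] * grid.voxel_volume_mm3
    r_mean = (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)

    x, y, z = grid.meshgrid_mm()
    dx, dy, dz = x - centroid[0], y - centroid[1], z - centroid[2]
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    r_safe = np.where(r > 1e-9, r, 1.0)

    if spec.mode == "shift":
        d_out = ndimage.distance_transform_edt(~organ, sampling=grid.spacing)
        decay = max(spec.decay_mm, 0.8 * spec.peak_mm)
        w = np.exp(-(d_out**2) / (2.0 * decay**2))
        disp = -np.asarray(spec.shift_mm)[None, None, None, :] * w[..., None]
    else:
        m = float(spec.magnitude_mm)
        decay = max(spec.decay_mm, 0.8 * m)
        if spec.mode == "expand":
            # forward surface motion +m; pull-back is a radial contraction
            r_edge = r_mean + m
            amp = np.where(r <= r_edge, m * r / r_edge,
                           m * np.exp(-((r - r_edge) ** 2) / (2.0 * decay**2)))
            sign = -1.0
        else:
            if m >= 0.6 * r_mean:
                raise ValueError(
                    f"shrink magnitude {m} mm too large for organ radius {r_mean:.1f} mm"
                )
            r_edge = r_mean - m
            amp = np.where(r <= r_edge, m * r / r_edge,
                           m * np.exp(-((r - r_edge) ** 2) / (2.0 * decay**2)))
            sign = +1.0
        unit = np.stack([dx / r_safe, dy / r_safe, dz / r_safe], axis=-1)
        disp = sign * amp[..., None] * unit

    disp = disp * window[..., None]
    sig_vox = [1.0 * min(grid.spacing) / s for s in grid.spacing]  # ~1 fine-voxel blur
    for c in range(3):
        disp[..., c] = ndimage.gaussian_filter(disp[..., c], sigma=sig_vox)
    disp[hard_zero] = 0.0

    # restore the target peak lost to windowing/smoothing, backing off
    # deterministically if the Jacobian screen would fail
    peak = np.linalg.norm(disp, axis=-1).max()
    if peak <= 0:
        return disp
    # restore the target peak, backing off deterministically while either the
    # Jacobian screen fails or the field is too steep for fixed-point inversion
    scale = spec.peak_mm / peak
    for _ in range(8):
        candidate = disp * scale
        ok, _minj = verify_invertibility(VectorField(grid, candidate, "mod_to_plan"))
        if ok and _max_stretch(candidate, grid.spacing) < 2.5:
            return candidate
        scale *= 0.85
    raise ValueError(
        f"cannot author an invertible field for {spec.organ} {spec.mode} "
        f"{spec.peak_mm} mm on this anatomy"
    )


def _compose_disp(outer: np.ndarray, inner: np.ndarray, structures: StructureSet) -> np.ndarray:
    from .warp import compose  # local import to avoid a cycle

    grid = structures.grid
    f_out = VectorField(grid, outer, "mod_to_plan")
    f_in = VectorField(grid, inner, "mod_to_plan")
    return compose(f_out, f_in).displacements


def author_field(structures: StructureSet, specs: list[DeformationSpec]) -> VectorField:
    """Author the combined pull-back field for a scenario.

    Multiple specs combine by map composition (not addition): the first spec
    is applied to the planning image first, later specs deform the result.
    An empty spec list returns the zero field.
    """
    grid = structures.grid
    if not specs:
        return VectorField(grid, np.zeros(grid.size + (3,)), "mod_to_plan")
    for spec in specs:
        if spec.organ not in structures:
            raise ValueError(f"unknown organ {spec.organ!r}; have {structures.names()}")
    taper_dist, femur_window, hard_zero = _organ_windows(structures)
    combined: np.ndarray | None = None
    for spec in specs:
        disp = _single_field(structures, spec, taper_dist, femur_window, hard_zero)
        if combined is None:
            combined = disp
        else:
            # first-applied field is the outer map of the composed pull-back
            combined = _compose_disp(combined, disp, structures)
    field = VectorField(grid, combined, "mod_to_plan")
    ok, minj = verify_invertibility(field)
    if not ok:
        raise ValueError(f"authored scenario field fails the Jacobian screen (min det {minj:.3f})")
    return field


def verify_invertibility(field: VectorField) -> tuple[bool, float]:
    """Central-difference Jacobian determinant of (identity + u) at every voxel.

    Returns ``(ok, min_det)`` with ``ok`` iff the minimum determinant exceeds
    0.05 — a conservative screen for a well-defined fixed-point inverse.
    """
    u = field.displacements
    sp = field.grid.spacing
    J = np.empty(u.shape[:3] + (3, 3))
    for i in range(3):
        grads = np.gradient(u[..., i], *sp, axis=(0, 1, 2))
        for j in range(3):
            J[..., i, j] = grads[j] + (1.0 if i == j else 0.0)
    det = np.linalg.det(J)
    min_det = float(det.min())
    return min_det > _MIN_JACOBIAN, min_det


def classify_magnitude(field: VectorField, mask: np.ndarray) -> str:
    """Magnitude class from the peak displacement over ``mask``:
    < 5 mm small, 5–10 mm medium (boundaries inclusive), > 10 mm large."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    peak = float(field.magnitude[mask].max())
    if peak < 5.0:
        return "small"
    if peak <= 10.0:
        return "medium"
    return "large"


def scenario_presets(site: str) -> dict[str, list[DeformationSpec]]:
    """Named per-fraction deformation scenarios for a treatment course.

    Nine prostate fractions (a no-change fraction plus eight organ-motion
    scenarios) and eleven cervix fractions, covering bladder/rectum filling
    changes in the medium and large classes and their combinations.
    """
    med, lrg = MAGNITUDE_MEDIUM_MM, MAGNITUDE_LARGE_MM
    blg = MAGNITUDE_BLADDER_LARGE_EXPANSION_MM
    if site == "prostate_like":
        return {
            "no_change": [],
            "bladder_med_shrink": [DeformationSpec("bladder", "shrink", med)],
            "bladder_med_expansion": [DeformationSpec("bladder", "expand", med)],
            "bladder_large_expansion": [DeformationSpec("bladder", "expand", blg)],
            "rectum_med_shrink": [DeformationSpec("rectum", "shrink", med)],
            "rectum_med_expansion": [DeformationSpec("rectum", "expand", med)],
            "rectum_large_expansion": [DeformationSpec("rectum", "expand", lrg)],
            "bladder_med_shrink_rectum_med_expansion": [
                DeformationSpec("bladder", "shrink", med),
                DeformationSpec("rectum", "expand", med),
            ],
            "bladder_med_expansion_rectum_med_expansion": [
                DeformationSpec("bladder", "expand", med),
                DeformationSpec("rectum", "expand", med),
            ],
        }
    if site == "cervix_like":
        return {
            "no_change": [],
            "bladder_med_shrink": [DeformationSpec("bladder", "shrink", med)],
            "bladder_med_expansion": [DeformationSpec("bladder", "expand", med)],
            "bladder_large_expansion": [DeformationSpec("bladder", "expand", blg)],
            "rectum_large_shrink": [DeformationSpec("rectum", "shrink", 12.0)],
            "rectum_med_shrink": [DeformationSpec("rectum", "shrink", med)],
            "rectum_large_expansion": [DeformationSpec("rectum", "expand", lrg)],
            "bladder_med_expansion_rectum_med_shrink": [
                DeformationSpec("bladder", "expand", med),
                DeformationSpec("rectum", "shrink", med),
            ],
            "bladder_med_expansion_rectum_med_expansion": [
                DeformationSpec("bladder", "expand", med),
                DeformationSpec("rectum", "expand", med),
            ],
            "uterus_med_expansion": [DeformationSpec("uterus", "expand", med)],
            "uterus_med_shrink": [DeformationSpec("uterus", "shrink", med)],
        }
    raise ValueError(f"unknown site {site!r}")
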