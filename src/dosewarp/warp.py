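"""Apply, invert and compose displacement fields; direct dose mapping.

All maps are pull-backs: a field ``u`` warps a moving volume by sampling it at
``x + u(x)`` on the output grid.  Dose accumulation is direct dose mapping
(DDM): the fraction dose is trilinearly sampled at the mapped positions, with
no energy or mass rescaling.  Field inversion is derivative-free fixed-point
iteration, adequate for Jacobian-screened fields.
"""

from __future__ import annotations

import numpy as np

from .grid import (
    ScalarVolume,
    StructureSet,
    VectorField,
    VolumeGrid,
    resample_field,
    sample_scalar_at_index,
    sample_vector,
)

__all__ = [
    "warp_image",
    "warp_mask",
    "warp_structures",
    "invert_field",
    "compose",
    "accumulate_dose_ddm",
    "sum_doses",
]

_FILL = {"HU": -1000.0, "Gy": 0.0, "mask": 0.0}


def _mapped_points(field: VectorField, target: VolumeGrid) -> np.ndarray:
    """Physical sample positions x + u(x) on the target grid, shape (n, 3)."""
    fld = resample_field(field, target) if field.grid != target else field
    pts = target.points_mm()
    return pts + fld.displacements.reshape(-1, 3)


def warp_image(
    moving: ScalarVolume,
    field: VectorField,
    target: VolumeGrid | None = None,
    mode: str = "linear",
    fill: float | None = None,
) -> ScalarVolume:
    """out(x) = moving(x + u(x)) on ``target`` (default: the field's grid).

    Fields on coarser grids than the target are upsampled trilinearly at
    evaluation time.  Out-of-extent samples take the quantity's physical fill
    (air HU, 0 Gy, 0 mask fraction) unless overridden.
    """
    target = target or field.grid
    if fill is None:
        fill = _FILL[moving.quantity]
    pts = _mapped_points(field, target)
    idx = moving.grid.mm_to_index(pts)
    vals = sample_scalar_at_index(moving.values, idx, mode=mode, fill=fill)
    return ScalarVolume(target, vals.reshape(target.size), moving.quantity)


def warp_mask(mask: np.ndarray, grid: VolumeGrid, field: VectorField,
              target: VolumeGrid | None = None) -> np.ndarray:
    """Warp a binary mask as a real-valued fraction, threshold at >= 0.5."""
    vol = ScalarVolume(grid, np.asarray(mask, float), "mask")
    out = warp_image(vol, field, target=target, mode="linear", fill=0.0)
    return np.asarray(out.values) >= 0.5


def warp_structures(structures: StructureSet, field: VectorField,
                    target: VolumeGrid | None = None) -> StructureSet:
    target = target or field.grid
    masks = {name: warp_mask(structures[name], structures.grid, field, target)
             for name in structures.names()}
    return StructureSet(target, masks)


def invert_field(
    field: VectorField,
    tol_mm: float = 0.05,
    max_iter: int = 80,
    mask: np.ndarray | None = None,
    damping: float = 0.5,
) -> VectorField:
    """Damped fixed-point inverse: v <- v - damping * (v + u(x + v(x))) from v0 = -u.

    The damped update converges wherever the plain iteration
    ``v <- -u(x + v)`` does, and additionally tolerates displacement
    gradients up to ~2/damping - 1 in magnitude, which the authored fields
    reach near their taper bands.  Stops when the max composition residual
    |u(x + v(x)) + v(x)| falls below ``tol_mm``.  The returned field carries
    the opposite direction tag and a ``residual_mm`` attribute (residual over
    ``mask``, or the whole grid).  Raises if the residual exceeds 5 * tol_mm.
    """
    grid = field.grid
    pts = grid.points_mm()
    u = field.displacements
    v = -u.copy()
    for _ in range(max_iter):
        u_at = sample_vector(field, pts + v.reshape(-1, 3)).reshape(v.shape)
        res = v + u_at
        if np.linalg.norm(res, axis=-1).max() < tol_mm:
            break
        v = v - damping * res
    u_at = sample_vector(field, pts + v.reshape(-1, 3)).reshape(v.shape)
    residual = np.linalg.norm(u_at + v, axis=-1)
    if mask is not None:
        residual = residual[np.asarray(mask, bool)]
    res_max = float(residual.max()) if residual.size else 0.0
    if res_max > 5.0 * tol_mm:
        raise RuntimeError(
            f"field inversion did not converge: residual {res_max:.3f} mm > {5 * tol_mm:.3f} mm"
        )
    inv = VectorField(grid, v, field.opposite_tag())
    inv.residual_mm = res_max  # type: ignore[attr-defined]
    return inv


def compose(outer: VectorField, inner: VectorField) -> VectorField:
    """w(x) = u_inner(x) + u_outer(x + u_inner(x)); the composed pull-back map."""
    grid = inner.grid
    pts = grid.points_mm() + inner.displacements.reshape(-1, 3)
    outer_at = sample_vector(outer, pts).reshape(inner.displacements.shape)
    return VectorField(grid, inner.displacements + outer_at, inner.direction_tag)


def accumulate_dose_ddm(fraction_dose: ScalarVolume, plan_to_mod: VectorField,
                        target: VolumeGrid | None = None) -> ScalarVolume:
    """Direct dose mapping: D_acc(y) = D_fx(y + v(y)) on the planning grid.

    ``plan_to_mod`` must carry the matching direction tag; out-of-extent
    samples contribute 0 Gy; no energy/mass rescaling.
    """
    if fraction_dose.quantity != "Gy":
        raise ValueError("fraction_dose must be a Gy volume")
    if plan_to_mod.direction_tag != "plan_to_mod":
        raise ValueError(
            f"accumulation requires a plan_to_mod field, got {plan_to_mod.direction_tag!r}"
        )
    out = warp_image(fraction_dose, plan_to_mod, target=target, mode="linear", fill=0.0)
    out.values = np.clip(out.values, 0.0, None)
    return out


def sum_doses(doses: list[ScalarVolume]) -> ScalarVolume:
    """Voxel-wise sum of doses on one shared grid."""
    if not doses:
        raise ValueError("need at least one dose")
    grid = doses[0].grid
    total = np.zeros(grid.size)
    for d in doses:
        if d.grid != grid:
            raise ValueError("all doses must share one grid")
        total = total + np.asarray(d.values)
    return ScalarVolume(grid, total, "Gy")
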