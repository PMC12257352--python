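"""Pluggable deformable-registration stand-in (the "system under test").

The reference implementation is a Gaussian-regularised, multi-resolution,
demons-style intensity registration (SimpleITK's fast symmetric-forces demons
inside a hand-rolled pyramid).  It estimates the plan-to-mod pull-back field
from the image pair alone — mono-modal synthetic CT pairs make an intensity
metric sufficient; the validation pipeline evaluates *any* plug-in honouring
this interface.

``degrade_factor`` deliberately blends the estimate toward a smooth random
field so the pipeline can demonstrate that its metrics discriminate a poor
registration from a good one.  ``field_grid_factor`` coarsens the returned
field relative to the CT grid (default 4x), reproducing the resolution
asymmetry between an authored truth field at CT resolution and a clinical
system's coarser estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .grid import ScalarVolume, VectorField, VolumeGrid
from .warp import invert_field

__all__ = ["RegistrationParams", "estimate_field", "register_with_oracle"]


@dataclass
class RegistrationParams:
    levels: int = 3
    iterations: tuple[int, ...] = (60, 30, 15)  # coarsest -> finest
    update_smoothing_sigma_mm: float = 1.0
    field_smoothing_sigma_mm: float = 3.0
    degrade_factor: float = 0.0
    field_grid_factor: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.update_smoothing_sigma_mm < 0 or self.field_smoothing_sigma_mm < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if not 0.0 <= self.degrade_factor <= 1.0:
            raise ValueError("degrade_factor must be in [0, 1]")
        if self.field_grid_factor < 1:
            raise ValueError("field_grid_factor must be >= 1")


def _to_sitk(vol: ScalarVolume) -> sitk.Image:
    arr = np.ascontiguousarray(np.transpose(np.asarray(vol.values, np.float64), (2, 1, 0)))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(vol.grid.spacing)
    img.SetOrigin(vol.grid.origin)
    return img


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    smoothed = sitk.SmoothingRecursiveGaussian(
        img, [0.5 * factor * s for s in img.GetSpacing()]
    )
    return sitk.Shrink(smoothed, [factor] * 3)


def _coarse_grid(grid: VolumeGrid, factor: int) -> VolumeGrid:
    if factor == 1:
        return grid
    size = tuple(max(2, int(np.ceil(n / factor))) for n in grid.size)
    spacing = tuple(s * factor for s in grid.spacing)
    return VolumeGrid(size, spacing, grid.origin)


def estimate_field(fixed: ScalarVolume, moving: ScalarVolume,
                   params: RegistrationParams | None = None) -> VectorField:
    """Estimate the plan->mod pull-back field registering ``moving`` to ``fixed``.

    ``fixed`` is the planning CT, ``moving`` the modified (treatment) CT; the
    returned field samples the moving image at ``x + u(x)`` to reproduce the
    fixed image.  Deterministic for fixed inputs and seed.
    """
    params = params or RegistrationParams()
    if fixed.grid != moving.grid:
        raise ValueError("fixed and moving must share one grid (same physical extent)")
    fixed_img, moving_img = _to_sitk(fixed), _to_sitk(moving)

    iters = list(params.iterations)
    while len(iters) < params.levels:
        iters.append(iters[-1])
    factors = [2 ** (params.levels - 1 - lv) for lv in range(params.levels)]

    field_img: sitk.Image | None = None
    for factor, n_iter in zip(factors, iters):
        fx = _shrink(fixed_img, factor)
        mv = _shrink(moving_img, factor)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(n_iter))
        demons.SetSmoothDisplacementField(params.field_smoothing_sigma_mm > 0)
        if params.field_smoothing_sigma_mm > 0:
            demons.SetStandardDeviations(
                [params.field_smoothing_sigma_mm / s for s in fx.GetSpacing()]
            )
        demons.SetSmoothUpdateField(params.update_smoothing_sigma_mm > 0)
        if params.update_smoothing_sigma_mm > 0:
            demons.SetUpdateFieldStandardDeviations(
                [params.update_smoothing_sigma_mm / s for s in fx.GetSpacing()]
            )
        if field_img is None:
            field_img = demons.Execute(fx, mv)
        else:
            init = sitk.Resample(field_img, fx, sitk.Transform(), sitk.sitkLinear, 0.0,
                                 sitk.sitkVectorFloat64)
            field_img = demons.Execute(fx, mv, init)

    assert field_img is not None
    if field_img.GetSize() != fixed_img.GetSize():
        field_img = sitk.Resample(field_img, fixed_img, sitk.Transform(), sitk.sitkLinear,
                                  0.0, sitk.sitkVectorFloat64)
    disp = np.transpose(sitk.GetArrayFromImage(field_img), (2, 1, 0, 3)).astype(float)
    full = VectorField(fixed.grid, disp, "plan_to_mod")

    coarse = _coarse_grid(fixed.grid, params.field_grid_factor)
    from .grid import resample_field

    out = resample_field(full, coarse)

    if params.degrade_factor > 0:
        out = VectorField(coarse, _degrade(out.displacements, coarse, params), "plan_to_mod")
    return out


def _degrade(disp: np.ndarray, grid: VolumeGrid, params: RegistrationParams) -> np.ndarray:
    """Blend the estimate toward a smooth seeded random field (poor-DIR emulation)."""
    g = params.degrade_factor
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal(disp.shape)
    sig_vox = [10.0 / s for s in grid.spacing]  # ~10 mm spatial correlation
    for c in range(3):
        noise[..., c] = ndimage.gaussian_filter(noise[..., c], sigma=sig_vox)
    mag_rms = float(np.sqrt((disp ** 2).sum(axis=-1).mean()))
    target_rms = max(mag_rms, 2.0)  # at least a clinically meaningful error scale
    noise_rms = float(np.sqrt((noise ** 2).sum(axis=-1).mean()))
    if noise_rms > 0:
        noise *= target_rms / noise_rms
    return (1.0 - g) * disp + g * noise


def register_with_oracle(true_field: VectorField, tol_mm: float = 0.05,
                         mask: np.ndarray | None = None) -> VectorField:
    """Perfect-DIR control arm: the numerically inverted true mod->plan field."""
    if true_field.direction_tag != "mod_to_plan":
        raise ValueError("oracle registration expects the true mod_to_plan field")
    return invert_field(true_field, tol_mm=tol_mm, mask=mask)
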