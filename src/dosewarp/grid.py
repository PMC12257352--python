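"""Axis-aligned volume geometry, scalar volumes, displacement fields and structure sets.

All geometry is physical: distances and displacements in millimetres, the voxel
at index ``(i, j, k)`` centred at ``origin + (i, j, k) * spacing``.  Arrays are
indexed ``[i, j, k]`` in (x, y, z) order.  Only identity-orientation grids are
supported; the readers in :mod:`dosewarp.io` reject oblique volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "VectorField",
    "StructureSet",
    "sample_scalar",
    "resample_to_grid",
    "sample_vector",
    "resample_field",
]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D axis-aligned lattice with physical geometry.

    Parameters
    ----------
    size : tuple of int
        Number of voxels per axis.
    spacing : tuple of float
        Voxel pitch per axis in mm; strictly positive.
    origin : tuple of float
        Physical position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    size: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "size", tuple(int(s) for s in self.size))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.size) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("size, spacing and origin must be length-3")
        if any(s <= 0 for s in self.size):
            raise ValueError(f"size must be positive, got {self.size}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.size

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def center_mm(self) -> np.ndarray:
        """Physical geometric centre of the grid."""
        return np.asarray(self.origin) + (np.asarray(self.size) - 1) / 2.0 * np.asarray(self.spacing)

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical voxel-centre coordinates."""
        return tuple(
            self.origin[a] + np.arange(self.size[a]) * self.spacing[a] for a in range(3)
        )

    def meshgrid_mm(self) -> tuple[np.ndarray, ...]:
        """Broadcastable physical coordinate arrays (sparse meshgrid)."""
        ax = self.axes_mm()
        return np.meshgrid(*ax, indexing="ij", sparse=True)

    def points_mm(self) -> np.ndarray:
        """All voxel-centre coordinates, shape ``(nvox, 3)`` in C order."""
        ax = self.axes_mm()
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([c.ravel() for c in g], axis=1)

    def mm_to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert physical points (n, 3) to fractional index coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return (
            self.size == other.size
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def __hash__(self) -> int:
        return hash((self.size, self.spacing, self.origin))


def _check_shape(grid: VolumeGrid, arr: np.ndarray, expect_vector: bool = False) -> None:
    want = grid.size + ((3,) if expect_vector else ())
    if tuple(arr.shape) != want:
        raise ValueError(f"array shape {arr.shape} does not match grid {want}")


@dataclass
class ScalarVolume:
    """A scalar lattice (HU, Gy or mask fraction) on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray
    quantity: str = "HU"  # one of {"HU", "Gy", "mask"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_shape(self.grid, self.values)
        if self.quantity not in ("HU", "Gy", "mask"):
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.quantity == "Gy" and np.any(self.values < 0):
            raise ValueError("dose volumes must be non-negative")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy(), self.quantity)


@dataclass
class VectorField:
    """A displacement field (mm, physical space), pull-back convention.

    ``direction_tag`` records which way the pull-back map reads:
    ``mod_to_plan`` fields synthesise the modified image from the planning
    image (``CT_mod(x) = CT_plan(x + u(x))``); ``plan_to_mod`` fields pull a
    fraction quantity back onto the planning grid.  A field and its inverse
    carry opposite tags.
    """

    grid: VolumeGrid
    displacements: np.ndarray  # (nx, ny, nz, 3) mm
    direction_tag: str = "mod_to_plan"

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        _check_shape(self.grid, self.displacements, expect_vector=True)
        if self.direction_tag not in ("mod_to_plan", "plan_to_mod"):
            raise ValueError(f"unknown direction_tag {self.direction_tag!r}")

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=-1)

    def opposite_tag(self) -> str:
        return "plan_to_mod" if self.direction_tag == "mod_to_plan" else "mod_to_plan"

    def copy(self) -> "VectorField":
        return VectorField(self.grid, self.displacements.copy(), self.direction_tag)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid (case-sensitive, unique names)."""

    grid: VolumeGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, m in self.masks.items():
            m = np.asarray(m)
            _check_shape(self.grid, m)
            clean[str(name)] = m.astype(bool)
        self.masks = clean

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"unknown structure {name!r}; have {sorted(self.masks)}")
        return self.masks[name]

    def names(self) -> list[str]:
        return list(self.masks)

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask)
        _check_shape(self.grid, mask)
        self.masks[str(name)] = mask.astype(bool)

    def volume_cc(self, name: str) -> float:
        return float(self[name].sum()) * self.grid.voxel_volume_cc


_MODE_ORDER = {"linear": 1, "nearest": 0}


def sample_scalar(
    vol: ScalarVolume,
    points: Iterable,
    mode: str = "linear",
    fill: float = 0.0,
) -> np.ndarray:
    """Interpolate ``vol`` at physical points (mm).

    Points outside the grid's physical extent return ``fill``.  ``mode`` is
    ``linear`` (trilinear) or ``nearest``.
    """
    if mode not in _MODE_ORDER:
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    idx = vol.grid.mm_to_index(np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float))
    out = ndimage.map_coordinates(
        np.asarray(vol.values, dtype=float),
        idx.T,
        order=_MODE_ORDER[mode],
        mode="grid-constant",
        cval=fill,
    )
    return out


def sample_scalar_at_index(
    values: np.ndarray, index_coords: np.ndarray, mode: str = "linear", fill: float = 0.0
) -> np.ndarray:
    """Interpolate a raw lattice at fractional index coordinates ``(3, n)`` or ``(n, 3)``."""
    ic = np.asarray(index_coords, dtype=float)
    if ic.ndim == 2 and ic.shape[-1] == 3 and ic.shape[0] != 3:
        ic = ic.T
    return ndimage.map_coordinates(
        np.asarray(values, dtype=float), ic, order=_MODE_ORDER[mode], mode="grid-constant", cval=fill
    )


def resample_to_grid(vol: ScalarVolume, target: VolumeGrid, mode: str = "linear", fill: float | None = None) -> ScalarVolume:
    """Resample a scalar volume onto ``target``.

    Out-of-extent fill defaults by quantity: HU -> -1000 (air), Gy -> 0,
    mask -> 0.
    """
    if fill is None:
        fill = {"HU": -1000.0, "Gy": 0.0, "mask": 0.0}[vol.quantity]
    if target == vol.grid:
        return ScalarVolume(target, vol.values.copy(), vol.quantity)
    pts = target.points_mm()
    vals = sample_scalar(vol, pts, mode=mode, fill=fill)
    return ScalarVolume(target, vals.reshape(target.size), vol.quantity)


def sample_vector(fld: VectorField, points: np.ndarray, mode: str = "linear") -> np.ndarray:
    """Interpolate a displacement field at physical points; outside -> 0 mm."""
    idx = fld.grid.mm_to_index(points).T
    comps = [
        ndimage.map_coordinates(fld.displacements[..., c], idx, order=_MODE_ORDER[mode], mode="grid-constant", cval=0.0)
        for c in range(3)
    ]
    return np.stack(comps, axis=-1)


def resample_field(fld: VectorField, target: VolumeGrid, mode: str = "linear") -> VectorField:
    """Resample a displacement field (component-wise trilinear) onto ``target``."""
    if target == fld.grid:
        return fld.copy()
    pts = target.points_mm()
    disp = sample_vector(fld, pts, mode=mode).reshape(target.size + (3,))
    return VectorField(target, disp, fld.direction_tag)
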