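"""NIfTI / NRRD reading and writing for volumes, fields and structure sets.

SimpleITK does the byte work.  A JSON sidecar (``<path>.json``) carries the
metadata the image formats cannot: the scalar ``quantity`` and the vector
``direction_tag``.  Only identity-orientation (axis-aligned) images are
accepted; oblique volumes are rejected with an explicit message rather than
silently resampled.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .grid import ScalarVolume, StructureSet, VectorField, VolumeGrid

__all__ = ["read_volume", "write_volume", "read_structure_set", "write_structure_set"]

_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUFFIXES):
        raise ValueError(f"unsupported volume format for {path} (use .nii, .nii.gz or .nrrd)")


def _grid_from_image(img: sitk.Image) -> VolumeGrid:
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3-D image, got {img.GetDimension()}-D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            "non-axis-aligned orientation is not supported; "
            f"direction matrix was {direction.tolist()}"
        )
    return VolumeGrid(size=tuple(img.GetSize()), spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_volume(path: str | Path) -> ScalarVolume | VectorField:
    """Read a NIfTI/NRRD volume; 3-component images return a :class:`VectorField`."""
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    grid = _grid_from_image(img)
    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    ncomp = img.GetNumberOfComponentsPerPixel()
    arr = sitk.GetArrayFromImage(img)  # (z, y, x[, c])
    if ncomp == 3:
        disp = np.transpose(arr, (2, 1, 0, 3)).astype(float)
        return VectorField(grid, disp, meta.get("direction_tag", "mod_to_plan"))
    if ncomp != 1:
        raise ValueError(f"expected 1 or 3 components per voxel, got {ncomp}")
    vals = np.transpose(arr, (2, 1, 0))
    return ScalarVolume(grid, vals, meta.get("quantity", "HU"))


def write_volume(obj: ScalarVolume | VectorField, path: str | Path) -> Path:
    """Write a volume or field; geometry and values round-trip bit-exactly for float32/64."""
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, VectorField):
        arr = np.transpose(obj.displacements, (2, 1, 0, 3))
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=True)
        meta = {"direction_tag": obj.direction_tag}
    elif isinstance(obj, ScalarVolume):
        arr = np.transpose(np.asarray(obj.values, dtype=np.float64), (2, 1, 0))
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
        meta = {"quantity": obj.quantity}
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")
    img.SetSpacing(obj.grid.spacing)
    img.SetOrigin(obj.grid.origin)
    sitk.WriteImage(img, str(path))
    _sidecar(path).write_text(json.dumps(meta))
    return path


def write_structure_set(structures: StructureSet, directory: str | Path, fmt: str = ".nii.gz") -> Path:
    """Write one volume per structure + a JSON name map under ``directory``.

    One file per mask (rather than a multi-label volume) so nested structures
    such as CTV within PTV round-trip without overlap loss.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name_map: dict[str, str] = {}
    for name in structures.names():
        fname = f"mask_{name}{fmt}"
        vol = ScalarVolume(structures.grid, structures[name].astype(np.float64), "mask")
        write_volume(vol, directory / fname)
        name_map[name] = fname
    (directory / "structures.names.json").write_text(json.dumps(name_map, indent=1))
    return directory / "structures.names.json"


def read_structure_set(directory: str | Path) -> StructureSet:
    directory = Path(directory)
    name_map = json.loads((directory / "structures.names.json").read_text())
    masks: dict[str, np.ndarray] = {}
    grid = None
    for name, fname in name_map.items():
        vol = read_volume(directory / fname)
        grid = vol.grid
        masks[name] = np.asarray(vol.values) >= 0.5
    if grid is None:
        raise ValueError(f"empty structure set in {directory}")
    return StructureSet(grid, masks)
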