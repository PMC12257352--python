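"""Per-structure displacement statistics, Dice coefficient and Hausdorff distance.

Displacement statistics are reported over the voxels of the *planning*
structure set (maximum indicates the range of motion; a similar maximum
between two fields does not imply voxel-wise agreement, which is what
:func:`dvf_error` measures directly).  The Hausdorff distance is the maximum
(100th-percentile) symmetric surface distance in physical mm, computed from
single-voxel-erosion surfaces and anisotropic Euclidean distance transforms;
a percentile variant is available for robust comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import StructureSet, VectorField, VolumeGrid, resample_field

__all__ = ["StructureStats", "dvf_stats_per_structure", "dvf_error", "dice", "hausdorff"]


@dataclass
class StructureStats:
    structure: str
    max_dvf_mm: float
    mean_dvf_mm: float


def dvf_stats_per_structure(field: VectorField, structures: StructureSet) -> pd.DataFrame:
    """Max and mean displacement magnitude per structure of the planning set."""
    fld = field if field.grid == structures.grid else resample_field(field, structures.grid)
    mag = fld.magnitude
    rows = []
    for name in structures.names():
        mask = structures[name]
        if not mask.any():
            raise ValueError(f"structure {name!r} is empty")
        vals = mag[mask]
        rows.append({"structure": name,
                     "max_dvf_mm": float(vals.max()),
                     "mean_dvf_mm": float(vals.mean())})
    return pd.DataFrame(rows, columns=["structure", "max_dvf_mm", "mean_dvf_mm"])


def dvf_error(estimated: VectorField, truth: VectorField, mask: np.ndarray) -> tuple[float, float]:
    """(max, mean) of |u_est - u_true| over ``mask``; fields must share a direction."""
    if estimated.direction_tag != truth.direction_tag:
        raise ValueError(
            f"direction mismatch: {estimated.direction_tag} vs {truth.direction_tag}"
        )
    est = estimated if estimated.grid == truth.grid else resample_field(estimated, truth.grid)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    diff = np.linalg.norm(est.displacements - truth.displacements, axis=-1)[mask]
    return float(diff.max()), float(diff.mean())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); two empty masks -> 1.0."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _surface(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return mask & ~eroded


def hausdorff(a: np.ndarray, b: np.ndarray, spacing, percentile: float = 100.0) -> float:
    """Symmetric surface distance (mm) between two masks at ``percentile``.

    The default (100) is the classic maximum Hausdorff distance; 95 gives the
    common robust variant.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("hausdorff distance requires two non-empty masks")
    sa, sb = _surface(a), _surface(b)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = dist_to_b[sa]
    d_ba = dist_to_a[sb]
    if percentile >= 100.0:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))
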