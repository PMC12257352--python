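"""Independent brute-force oracles used to pin expected values in the tests.

Each oracle is deliberately dumb — exhaustive search, full sorts, explicit
distance checks — and shares no code path with the implementation it checks.
"""

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def brute_force_gamma(reference, evaluated, config):
    """Exhaustive gamma search over the full candidate lattice, no pruning.

    Returns (pass_rate_pct, gamma values over evaluated voxels in C order).
    """
    grid = reference.grid
    ref = np.asarray(reference.values, float)
    ev = np.asarray(evaluated.values, float)
    global_max = ref.max()
    thr = config.threshold_fraction * global_max
    dd = config.dose_criterion_pct / 100.0 * global_max
    dta = config.distance_criterion_mm

    n = int(np.floor(config.cap_mm / config.step_mm))
    ax = np.arange(-n, n + 1) * config.step_mm
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    offs = offs[(offs ** 2).sum(axis=1) <= config.cap_mm ** 2 + 1e-12]
    d2 = (offs ** 2).sum(axis=1)

    interp = RegularGridInterpolator(grid.axes_mm(), ev, bounds_error=False,
                                     fill_value=np.nan)
    pts_idx = np.argwhere(ref >= thr)
    pts = pts_idx * np.asarray(grid.spacing) + np.asarray(grid.origin)
    gammas = np.empty(len(pts))
    chunk = 256
    for s in range(0, len(pts), chunk):
        block = pts[s:s + chunk]
        cand = block[:, None, :] + offs[None, :, :]
        vals = interp(cand.reshape(-1, 3)).reshape(len(block), -1)
        rv = ref[tuple(pts_idx[s:s + chunk].T)][:, None]
        g2 = d2[None, :] / dta ** 2 + ((vals - rv) / dd) ** 2
        gammas[s:s + chunk] = np.sqrt(np.nanmin(g2, axis=1))
    pass_rate = 100.0 * float(np.count_nonzero(gammas <= 1.0)) / len(gammas)
    return pass_rate, gammas


def sort_dvh_dose_at_volume(dose_values, target_volume_cc, voxel_cc):
    """Dose covering the hottest ``target_volume_cc`` by an explicit full sort
    with midpoint placement of each voxel on the cumulative-volume axis."""
    d = np.sort(np.asarray(dose_values, float))[::-1]
    cum_mid = (np.arange(1, d.size + 1) - 0.5) * voxel_cc
    if target_volume_cc <= cum_mid[0]:
        return float(d[0])
    if target_volume_cc >= cum_mid[-1]:
        return float(d[-1])
    j = np.searchsorted(cum_mid, target_volume_cc)
    x0, x1 = cum_mid[j - 1], cum_mid[j]
    w = (target_volume_cc - x0) / (x1 - x0)
    return float(d[j - 1] * (1 - w) + d[j] * w)


def brute_force_volume_fraction(dose_values, dose_Gy):
    d = np.asarray(dose_values, float)
    return 100.0 * float(np.count_nonzero(d >= dose_Gy)) / d.size


def brute_force_expand(mask, margin_mm, spacing):
    """Set every voxel whose centre lies within margin of a set voxel centre."""
    mask = np.asarray(mask, bool)
    src = np.argwhere(mask) * np.asarray(spacing, float)
    out = np.zeros_like(mask)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * np.asarray(spacing, float)
        if np.min(np.linalg.norm(src - p, axis=1)) <= margin_mm:
            out[idx] = True
    return out


def brute_force_hausdorff(a, b, spacing):
    """Max symmetric surface distance by explicit pairwise distances."""
    import scipy.ndimage as ndi

    def surf(m):
        return np.argwhere(m & ~ndi.binary_erosion(m)) * np.asarray(spacing, float)

    pa, pb = surf(np.asarray(a, bool)), surf(np.asarray(b, bool))
    d_ab = np.array([np.min(np.linalg.norm(pb - p, axis=1)) for p in pa])
    d_ba = np.array([np.min(np.linalg.norm(pa - p, axis=1)) for p in pb])
    return max(d_ab.max(), d_ba.max())
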