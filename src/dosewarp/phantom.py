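"""Synthetic pelvic phantom: CT, structure set, prescription and plan-like dose.

The phantom stands in for patient planning CTs in the dose-accumulation
validation workflow.  It provides the anatomy the workflow needs — a body with
bladder, rectum, a target organ (prostate or uterus), femoral heads, CTV/PTV —
and an analytic plan-like fraction dose (PTV plateau, Gaussian penumbra,
superposed entrance fluence from discrete or continuous gantry angles).  The
dose is shaped like a treatment plan, with the gradients and beam edges that
drive accumulation error, not computed by radiation transport.

Two sites are modelled after common pelvic prescriptions: ``prostate_like``
(60 Gy in 20 fractions) and ``cervix_like`` (45 Gy in 25 fractions).  The
target-organ centroid sits at the grid's geometric centre, emulating CBCT
acquisition centred on the isocentre.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid import ScalarVolume, StructureSet, VolumeGrid

__all__ = [
    "PhantomConfig",
    "PrescriptionContext",
    "build_phantom",
    "expand_margin",
    "synth_fraction_dose",
]

# mm geometry per site; all centres relative to the grid's geometric centre
_DEFAULT_GEOMETRY = {
    "prostate_like": {
        "body_radii": (110.0, 85.0),
        "fat_thickness": 8.0,
        "prostate": {"center": (0.0, 0.0, 0.0), "radii": (22.0, 20.0, 20.0)},
        "bladder": {"center": (0.0, 52.0, 10.0), "radii": (38.0, 28.0, 25.0)},
        "rectum": {"center_xy": (0.0, -48.0), "radius": 15.0, "half_length": 70.0,
                   "gas_radius": 7.0, "gas_half_length": 20.0},
        "femur": {"centers": ((72.0, -8.0, 0.0), (-72.0, -8.0, 0.0)), "radius": 21.0},
    },
    "cervix_like": {
        "body_radii": (110.0, 90.0),
        "fat_thickness": 8.0,
        "uterus": {"center": (0.0, 0.0, 0.0), "radii": (26.0, 22.0, 38.0)},
        "bladder": {"center": (0.0, 50.0, -5.0), "radii": (36.0, 26.0, 24.0)},
        "rectum": {"center_xy": (0.0, -48.0), "radius": 15.0, "half_length": 70.0,
                   "gas_radius": 7.0, "gas_half_length": 20.0},
        "femur": {"centers": ((72.0, -8.0, 0.0), (-72.0, -8.0, 0.0)), "radius": 21.0},
        "bowel": {"center": (0.0, 30.0, 48.0), "radii": (48.0, 32.0, 26.0)},
    },
}

_HU = {
    "air": -1000.0,
    "soft": 40.0,
    "fat": -80.0,
    "bladder": 5.0,
    "target": 45.0,
    "rectum": 30.0,
    "gas": -1000.0,
    "bone": 700.0,
    "bowel": 25.0,
}

_PRESCRIPTIONS = {
    "prostate_like": (60.0, 20),
    "cervix_like": (45.0, 25),
}


@dataclass
class PhantomConfig:
    """Phantom generation parameters.

    ``geometry`` and ``hu`` default to the site's built-in values; individual
    entries can be overridden.  ``seed`` controls the correlated soft-tissue
    texture only — geometry is deterministic.
    """

    site: str = "prostate_like"
    size: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)
    ptv_margin_mm: float = 7.0
    geometry: dict = dc_field(default_factory=dict)
    hu: dict = dc_field(default_factory=dict)
    texture_hu: float = 12.0
    texture_corr_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site not in _DEFAULT_GEOMETRY:
            raise ValueError(f"site must be one of {sorted(_DEFAULT_GEOMETRY)}, got {self.site!r}")
        if self.ptv_margin_mm < 0:
            raise ValueError("ptv_margin_mm must be >= 0")
        geo = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _DEFAULT_GEOMETRY[self.site].items()}
        for k, v in self.geometry.items():
            if isinstance(v, dict) and k in geo:
                geo[k].update(v)
            else:
                geo[k] = v
        self.geometry = geo
        hu = dict(_HU)
        hu.update(self.hu)
        self.hu = hu

    def grid(self) -> VolumeGrid:
        size = tuple(int(s) for s in self.size)
        spacing = tuple(float(s) for s in self.spacing)
        # origin chosen so the grid's geometric centre (= target centroid) is at 0 mm
        origin = tuple(-(n - 1) / 2.0 * sp for n, sp in zip(size, spacing))
        return VolumeGrid(size, spacing, origin)

    @property
    def target_organ(self) -> str:
        return "prostate" if self.site == "prostate_like" else "uterus"


@dataclass
class PrescriptionContext:
    """Prescription total dose, fractionation and the clinical-goal set."""

    total_dose_Gy: float
    n_fractions: int
    goal_set: list = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_dose_Gy <= 0:
            raise ValueError("total_dose_Gy must be > 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def fraction_dose_Gy(self) -> float:
        return self.total_dose_Gy / self.n_fractions


def _ellipsoid(grid: VolumeGrid, center: Sequence[float], radii: Sequence[float]) -> np.ndarray:
    x, y, z = grid.meshgrid_mm()
    c, r = np.asarray(center, float), np.asarray(radii, float)
    return ((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2 + ((z - c[2]) / r[2]) ** 2 <= 1.0


def _cylinder_z(grid: VolumeGrid, center_xy: Sequence[float], radius: float,
                z_center: float = 0.0, half_length: float | None = None) -> np.ndarray:
    x, y, z = grid.meshgrid_mm()
    inside = (x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2 <= radius ** 2
    if half_length is not None:
        inside = inside & (np.abs(z - z_center) <= half_length)
    else:
        inside = inside & np.ones_like(z, dtype=bool)
    return np.broadcast_to(inside, grid.size).copy()


def expand_margin(mask: np.ndarray, margin_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Isotropic physical-distance dilation via Euclidean distance transform."""
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    mask = np.asarray(mask, bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm


def build_phantom(config: PhantomConfig) -> tuple[ScalarVolume, StructureSet, PrescriptionContext]:
    """Generate the CT volume, structure set and prescription for ``config``.

    Guarantees CTV ⊆ PTV ⊆ body, the target centroid at the grid centre, and
    bit-identical output for a fixed config and seed.
    """
    grid = config.grid()
    geo = config.geometry
    hu = config.hu
    x, y, z = grid.meshgrid_mm()

    a, b = geo["body_radii"]
    body = np.broadcast_to((x / a) ** 2 + (y / b) ** 2 <= 1.0, grid.size).copy()
    ft = geo["fat_thickness"]
    inner = np.broadcast_to((x / (a - ft)) ** 2 + (y / (b - ft)) ** 2 <= 1.0, grid.size)

    target_name = config.target_organ
    target = _ellipsoid(grid, geo[target_name]["center"], geo[target_name]["radii"])
    bladder = _ellipsoid(grid, geo["bladder"]["center"], geo["bladder"]["radii"])
    rect = geo["rectum"]
    rectum = _cylinder_z(grid, rect["center_xy"], rect["radius"], half_length=rect["half_length"])
    gas = _cylinder_z(grid, rect["center_xy"], rect["gas_radius"], half_length=rect["gas_half_length"])
    femur_r = _ellipsoid(grid, geo["femur"]["centers"][0], (geo["femur"]["radius"],) * 3)
    femur_l = _ellipsoid(grid, geo["femur"]["centers"][1], (geo["femur"]["radius"],) * 3)

    for name, organ in [("target", target), ("bladder", bladder), ("rectum", rectum),
                        ("femur_R", femur_r), ("femur_L", femur_l)]:
        if (organ & ~body).any():
            raise ValueError(f"organ {name!r} overlaps the body boundary")

    bladder &= ~target
    rectum &= ~target & ~bladder
    gas &= rectum

    ct = np.full(grid.size, hu["air"])
    ct[body] = hu["fat"]
    ct[body & inner] = hu["soft"]
    ct[bladder] = hu["bladder"]
    ct[rectum] = hu["rectum"]
    ct[gas] = hu["gas"]
    ct[target] = hu["target"]

    masks: dict[str, np.ndarray] = {
        "body": body,
        "bladder": bladder,
        "rectum": rectum,
        target_name: target,
        "femur_L": femur_l,
        "femur_R": femur_r,
    }

    if config.site == "cervix_like":
        bowel = _ellipsoid(grid, geo["bowel"]["center"], geo["bowel"]["radii"])
        bowel &= ~target & ~bladder & ~rectum & body
        ct[bowel] = hu["bowel"]
        masks["bowel"] = bowel

    ct[femur_r | femur_l] = hu["bone"]

    ctv = target.copy()
    ptv = expand_margin(ctv, config.ptv_margin_mm, grid.spacing) & body
    masks["CTV"] = ctv
    masks["PTV"] = ptv

    if config.site == "cervix_like":
        masks["bowel_bag"] = expand_margin(masks["bowel"], 5.0, grid.spacing) & body & ~(femur_l | femur_r)
        masks["bowel_minus_ctv"] = masks["bowel"] & ~ctv

    # correlated soft-tissue texture so intensity registration has features
    # away from organ boundaries; deterministic under the seed
    rng = np.random.default_rng(config.seed)
    noise = rng.standard_normal(grid.size)
    sigma_vox = [config.texture_corr_mm / s for s in grid.spacing]
    noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = noise.std()
    if sd > 0:
        noise *= config.texture_hu / sd
    textured = body & ~gas & ~(femur_l | femur_r)
    ct = np.where(textured, ct + noise, ct)

    structures = StructureSet(grid, masks)
    total, n_fx = _PRESCRIPTIONS[config.site]
    from .dvh import load_goal_set  # deferred: dvh does not import phantom

    rx = PrescriptionContext(total, n_fx, goal_set=load_goal_set(config.site))
    return ScalarVolume(grid, ct, "HU"), structures, rx


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(t, -40, 40)))


def _body_depth_2d(body2d: np.ndarray, grid: VolumeGrid, theta: float,
                   step_mm: float = 4.0, max_mm: float = 360.0) -> np.ndarray:
    """Radiological path length (mm) from the body surface along gantry angle theta.

    The beam travels in -d from a source at angle theta in the x-y plane;
    depth(x) integrates the 2-D body mask from x toward the source.
    """
    nx, ny = body2d.shape
    ax_x = grid.origin[0] + np.arange(nx) * grid.spacing[0]
    ax_y = grid.origin[1] + np.arange(ny) * grid.spacing[1]
    X, Y = np.meshgrid(ax_x, ax_y, indexing="ij")
    d = np.array([np.cos(theta), np.sin(theta)])
    steps = np.arange(0.0, max_mm, step_mm)
    depth = np.zeros_like(X)
    body_f = body2d.astype(float)
    for s in steps:
        px = (X + s * d[0] - grid.origin[0]) / grid.spacing[0]
        py = (Y + s * d[1] - grid.origin[1]) / grid.spacing[1]
        vals = ndimage.map_coordinates(body_f, [px.ravel(), py.ravel()], order=1,
                                       mode="constant", cval=0.0)
        depth += vals.reshape(X.shape) * step_mm
    return depth


def synth_fraction_dose(
    structures: StructureSet,
    rx: PrescriptionContext,
    technique: str = "imrt9",
    seed: int = 0,
    penumbra_sigma_mm: float = 4.0,
    mu_per_mm: float = 0.004,
    aperture_margin_mm: float = 3.0,
    edge_softness_mm: float = 2.0,
    plateau_weight: float = 0.65,
) -> ScalarVolume:
    """Analytic per-fraction dose: PTV plateau + penumbra, entrance-fluence bath.

    ``imrt9`` superposes nine discrete gantry angles (visible beam-edge steps
    near the surface); ``vmat`` integrates a continuous arc (72 angles, no
    discrete edges).  The dose is normalised to the per-fraction prescription
    at the PTV centroid and is zero outside the body.
    """
    if technique not in ("imrt9", "vmat"):
        raise ValueError(f"technique must be 'imrt9' or 'vmat', got {technique!r}")
    if "PTV" not in structures or not structures["PTV"].any():
        raise ValueError("structure set must contain a non-empty PTV")
    grid = structures.grid
    ptv = structures["PTV"]
    body = structures["body"]
    spacing = np.asarray(grid.spacing)

    # plateau with Gaussian penumbra from physical distance outside the PTV
    dist_out = ndimage.distance_transform_edt(~ptv, sampling=grid.spacing)
    plateau = np.exp(-(dist_out ** 2) / (2.0 * penumbra_sigma_mm ** 2))

    # entrance fluence from gantry angles in the transverse plane
    if technique == "imrt9":
        n_beams = 9
        rng = np.random.default_rng(seed)
        weights = 1.0 + 0.05 * rng.uniform(-1.0, 1.0, n_beams)
        weights /= weights.mean()
    else:
        n_beams = 72
        weights = np.ones(n_beams)
    angles = np.arange(n_beams) * 2.0 * np.pi / n_beams

    mid_z = grid.size[2] // 2
    body2d = body[:, :, mid_z]
    ax = grid.axes_mm()
    X2, Y2 = np.meshgrid(ax[0], ax[1], indexing="ij")
    zc = ax[2][None, None, :]

    ptv_idx = np.argwhere(ptv)
    ptv_pts = ptv_idx * spacing + np.asarray(grid.origin)
    z_lo, z_hi = ptv_pts[:, 2].min() - aperture_margin_mm, ptv_pts[:, 2].max() + aperture_margin_mm

    fluence = np.zeros(grid.size)
    for theta, w in zip(angles, weights):
        depth = _body_depth_2d(body2d, grid, theta)
        lat = -X2 * np.sin(theta) + Y2 * np.cos(theta)
        lat_ptv = -ptv_pts[:, 0] * np.sin(theta) + ptv_pts[:, 1] * np.cos(theta)
        l_lo = lat_ptv.min() - aperture_margin_mm
        l_hi = lat_ptv.max() + aperture_margin_mm
        ap_xy = _sigmoid((lat - l_lo) / edge_softness_mm) * _sigmoid((l_hi - lat) / edge_softness_mm)
        beam2d = ap_xy * np.exp(-mu_per_mm * depth)
        ap_z = _sigmoid((zc - z_lo) / edge_softness_mm) * _sigmoid((z_hi - zc) / edge_softness_mm)
        fluence += w * beam2d[:, :, None] * ap_z
    fluence /= n_beams

    mean_ptv = fluence[ptv].mean()
    if mean_ptv <= 0:
        raise ValueError("degenerate fluence over the PTV")
    fluence /= mean_ptv

    fx_dose = rx.fraction_dose_Gy
    dose = fx_dose * (plateau_weight * plateau + (1.0 - plateau_weight) * fluence)

    # pin the PTV-centroid dose to the per-fraction prescription
    centroid = ptv_pts.mean(axis=0)
    ci = np.clip(np.rint((centroid - np.asarray(grid.origin)) / spacing).astype(int),
                 0, np.asarray(grid.size) - 1)
    dose *= fx_dose / dose[tuple(ci)]
    dose = np.where(body, dose, 0.0)
    return ScalarVolume(grid, np.clip(dose, 0.0, None), "Gy")
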