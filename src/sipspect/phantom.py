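"""Synthetic abdominal phantoms with ^177^Lu-DOTATATE-like kinetics.

A phantom is a set of co-registered voxel grids: an activity concentration
map (Bq/ml), a linear-attenuation map at 208 keV (1/cm), and boolean organ
masks.  Anatomy is deliberately simple — an elliptic-cylinder body, two
ellipsoidal kidneys, a vertebral column built from stacked cylinders with a
marrow cavity, optional spherical lesions — but it is co-registered,
segmentable and attenuating, which is what the downstream projection,
reconstruction and dosimetry stages need.

Axis convention: arrays are indexed ``(x, y, z)`` with 0-based voxel
indices; z is the scanner axis.  +y is "posterior" (the side where the
spine sits).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: paint regions that carry their own kinetics (disjoint by construction);
#: ``marrow_spheres`` is a measurement VOI inside ``vertebrae``, not a region.
KINETIC_REGIONS = ("body", "kidney_L", "kidney_R", "vertebrae", "lesions")

MASK_NAMES = ("kidney_L", "kidney_R", "vertebrae", "marrow_spheres", "lesions", "body")

#: soft tissue linear attenuation at 208 keV, 1/cm
MU_SOFT_TISSUE = 0.137
#: cortical/trabecular bone modelled as 1.4x soft tissue
MU_BONE_FACTOR = 1.4


@dataclass(frozen=True)
class KineticsModel:
    """Biexponential concentration kinetics C(t) = A1 e^(-l1 t) + A2 e^(-l2 t).

    Amplitudes in Bq/ml, decay constants in 1/h (effective, i.e. biological
    washout combined with physical decay).
    """

    A1: float
    lambda1: float
    A2: float
    lambda2: float

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("decay constants must be strictly positive")


def organ_concentration(k: KineticsModel, t: float) -> float:
    """Concentration (Bq/ml) of a biexponential organ curve at time t (hours)."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    return k.A1 * np.exp(-k.lambda1 * t) + k.A2 * np.exp(-k.lambda2 * t)


#: default kinetics: kidney uptake dominates, marrow/vertebra uptake is low,
#: and whole-body count level falls monotonically over days 0/1/2/7.
DEFAULT_KINETICS: dict[str, KineticsModel] = {
    "kidney_L": KineticsModel(2.0e5, 0.06, 4.0e4, 0.008),
    "kidney_R": KineticsModel(2.0e5, 0.06, 4.0e4, 0.008),
    "body": KineticsModel(3.0e4, 0.08, 4.0e3, 0.010),
    "vertebrae": KineticsModel(1.2e4, 0.07, 2.5e3, 0.009),
    "lesions": KineticsModel(4.0e5, 0.03, 8.0e4, 0.006),
}

#: imaging time points (hours post administration): ~2 h, 1 d, 2 d, 7 d
DEFAULT_TIME_POINTS_H = (2.0, 24.0, 48.0, 168.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometric description of the phantom (everything except the seed).

    Organ positions are specified as fractions of the grid extent so the
    same config scales from desk-size grids up to the clinical 128x128
    matrix.  ``background_texture_cv`` is the coefficient of variation of
    the multiplicative lognormal texture applied to background activity.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: float = 4.42
    body_semiaxes_frac: tuple[float, float] = (0.44, 0.38)
    kidney_volume_ml: float = 150.0
    kidney_offset_frac: tuple[float, float] = (0.22, 0.12)
    kidney_aspect: float = 1.8
    vertebra_radius_mm: float = 14.0
    vertebra_offset_frac: float = 0.26
    vertebra_height_mm: float = 28.0
    vertebra_gap_mm: float = 4.0
    marrow_cavity_radius_mm: float = 8.0
    marrow_sphere_volume_ml: float = 4.0
    lesion_centers_frac: tuple[tuple[float, float, float], ...] = ()
    lesion_radius_mm: float = 12.0
    background_texture_cv: float = 0.1
    mu_soft: float = MU_SOFT_TISSUE
    mu_bone: float = MU_BONE_FACTOR * MU_SOFT_TISSUE


@dataclass
class PhantomVolume:
    """Co-registered activity, attenuation and organ masks on one grid."""

    activity: np.ndarray  # Bq/ml
    mu_map: np.ndarray  # 1/cm at 208 keV
    voxel_size_mm: float
    masks: dict[str, np.ndarray]
    #: per-region unit-concentration pattern (1 in organs, normalised
    #: texture in background); used by phantom_at_time
    texture: np.ndarray | None = None
    config: PhantomConfig | None = None
    seed: int | None = None

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3

    def region_masks(self) -> dict[str, np.ndarray]:
        """Disjoint kinetic paint regions (background = body minus organs)."""
        m = self.masks
        organs = m["kidney_L"] | m["kidney_R"] | m["vertebrae"] | m["lesions"]
        return {
            "body": m["body"] & ~organs,
            "kidney_L": m["kidney_L"],
            "kidney_R": m["kidney_R"],
            "vertebrae": m["vertebrae"],
            "lesions": m["lesions"],
        }


def _centered_coords_mm(shape, voxel_size_mm):
    axes = [(np.arange(n) - (n - 1) / 2.0) * voxel_size_mm for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(shape, voxel_size_mm, center_mm, semiaxes_mm):
    X, Y, Z = _centered_coords_mm(shape, voxel_size_mm)
    cx, cy, cz = center_mm
    ax, ay, az = semiaxes_mm
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _kidney_mask(shape, voxel_size_mm, center_mm, volume_ml, aspect):
    # semiaxes a = b, c = aspect * a chosen for the requested volume, with one
    # corrective re-voxelisation step so the discrete volume tracks the target
    a = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi * aspect)) ** (1.0 / 3.0)
    vox_ml = (voxel_size_mm / 10.0) ** 3
    mask = _ellipsoid_mask(shape, voxel_size_mm, center_mm, (a, a, aspect * a))
    got = mask.sum() * vox_ml
    if got > 0:
        a *= (volume_ml / got) ** (1.0 / 3.0)
        mask = _ellipsoid_mask(shape, voxel_size_mm, center_mm, (a, a, aspect * a))
    return mask


def sphere_mask(shape, voxel_size_mm, center_vox, volume_ml):
    """Boolean sphere of the requested volume centred on a voxel coordinate.

    Voxel centres within radius (3V/4pi)^(1/3) are included; a volume
    smaller than one voxel degenerates to the single centre voxel.
    """
    vox_ml = (voxel_size_mm / 10.0) ** 3
    r_mm = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    idx = [np.arange(n) for n in shape]
    X, Y, Z = np.meshgrid(*idx, indexing="ij")
    cx, cy, cz = center_vox
    d2 = ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) * voxel_size_mm**2
    mask = d2 <= r_mm**2
    if not mask.any():
        mask = np.zeros(shape, dtype=bool)
        mask[int(round(cx)), int(round(cy)), int(round(cz))] = True
    return mask


def make_phantom(config: PhantomConfig | None = None, seed: int = 0) -> PhantomVolume:
    """Build a phantom at unit kinetic scale (activity = t=0 default kinetics).

    Masks depend only on ``config``; the seed controls only the random
    multiplicative texture of the background activity, whose mean over the
    background region is normalised to exactly 1 so that total activity
    stays an exact sum of per-region volume x concentration.
    """
    config = config or PhantomConfig()
    shape = tuple(config.shape)
    if min(shape) < 32:
        raise ValueError(f"grid dimensions must be >= 32, got {shape}")
    vs = config.voxel_size_mm
    nx, ny, nz = shape
    ext = np.array(shape) * vs  # FOV extent in mm

    # body: elliptic cylinder along z spanning the full axial FOV
    X, Y, Z = _centered_coords_mm(shape, vs)
    bx = config.body_semiaxes_frac[0] * ext[0]
    by = config.body_semiaxes_frac[1] * ext[1]
    body = (X / bx) ** 2 + (Y / by) ** 2 <= 1.0

    kx = config.kidney_offset_frac[0] * ext[0]
    ky = config.kidney_offset_frac[1] * ext[1]
    kid_L = _kidney_mask(shape, vs, (-kx, ky, 0.0), config.kidney_volume_ml, config.kidney_aspect)
    kid_R = _kidney_mask(shape, vs, (+kx, ky, 0.0), config.kidney_volume_ml, config.kidney_aspect)

    # vertebral column: stack of cylinders with gaps (discs), marrow cavity inside
    vy = config.vertebra_offset_frac * ext[1]
    r2 = (X - 0.0) ** 2 + (Y - vy) ** 2
    column = r2 <= config.vertebra_radius_mm**2
    cavity = r2 <= config.marrow_cavity_radius_mm**2
    period = config.vertebra_height_mm + config.vertebra_gap_mm
    zmod = np.mod(Z - Z.min(), period)
    in_vertebra = zmod < config.vertebra_height_mm
    vertebrae = column & in_vertebra
    cavity = cavity & in_vertebra

    lesions = np.zeros(shape, dtype=bool)
    for fx, fy, fz in config.lesion_centers_frac:
        c = ((fx - 0.5) * ext[0], (fy - 0.5) * ext[1], (fz - 0.5) * ext[2])
        r = config.lesion_radius_mm
        lesions |= _ellipsoid_mask(shape, vs, c, (r, r, r))

    # 4-ml marrow spheres at each vertebra centroid (where they fit the cavity)
    marrow_spheres = np.zeros(shape, dtype=bool)
    z_idx = (np.arange(nz) * vs)  # mm from z start
    zmod_1d = np.mod(z_idx, period)
    centers = []
    k = 0
    while True:
        zc_mm = k * period + config.vertebra_height_mm / 2.0
        if zc_mm > z_idx[-1]:
            break
        centers.append(zc_mm / vs)
        k += 1
    vy_vox = (vy / vs) + (ny - 1) / 2.0
    cx_vox = (nx - 1) / 2.0
    r_sphere_mm = (3.0 * config.marrow_sphere_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1 / 3)
    for zc in centers:
        if (zc * vs - r_sphere_mm) < 0 or (zc * vs + r_sphere_mm) > z_idx[-1]:
            continue
        sph = sphere_mask(shape, vs, (cx_vox, vy_vox, zc), config.marrow_sphere_volume_ml)
        if lesions[sph].any():
            continue  # mirror the manual exclusion of metastasis-affected VOIs
        marrow_spheres |= sph

    masks = {
        "kidney_L": kid_L,
        "kidney_R": kid_R,
        "vertebrae": vertebrae,
        "marrow_spheres": marrow_spheres,
        "lesions": lesions,
        "body": body,
    }
    for name in ("kidney_L", "kidney_R", "vertebrae", "lesions"):
        if masks[name].any() and not (masks[name] <= body).all():
            raise ValueError(f"organ {name!r} extends outside the body outline")
    if (kid_L & kid_R).any():
        raise ValueError("kidney_L and kidney_R overlap; reduce kidney volume or offset")

    # attenuation: soft tissue inside body, bone in the vertebra shell
    mu = np.where(body, config.mu_soft, 0.0)
    mu[vertebrae & ~cavity] = config.mu_bone

    # multiplicative texture: 1 in organs, normalised lognormal in background
    rng = np.random.default_rng(seed)
    texture = np.ones(shape, dtype=float)
    cv = config.background_texture_cv
    if cv > 0:
        sigma = np.sqrt(np.log(1.0 + cv**2))
        field_ = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=shape)
        bg = body & ~(kid_L | kid_R | vertebrae | lesions)
        if bg.any():
            field_ = field_ / field_[bg].mean()  # exact unit mean over background
            texture[bg] = field_[bg]

    p = PhantomVolume(
        activity=np.zeros(shape, dtype=float),
        mu_map=mu,
        voxel_size_mm=vs,
        masks=masks,
        texture=texture,
        config=config,
        seed=seed,
    )
    p.activity = _paint_activity(p, DEFAULT_KINETICS, 0.0)
    return p


def _paint_activity(p: PhantomVolume, kinetics: dict[str, KineticsModel], t: float) -> np.ndarray:
    regions = p.region_masks()
    missing = [name for name in regions if regions[name].any() and name not in kinetics]
    if missing:
        raise KeyError(f"missing kinetics for organ(s): {', '.join(missing)}")
    act = np.zeros(p.activity.shape, dtype=float)
    tex = p.texture if p.texture is not None else 1.0
    for name, mask in regions.items():
        if not mask.any():
            continue
        conc = organ_concentration(kinetics[name], t)
        act[mask] = conc * (tex[mask] if isinstance(tex, np.ndarray) else 1.0)
    return act


def phantom_at_time(
    p: PhantomVolume, kinetics: dict[str, KineticsModel], t: float
) -> PhantomVolume:
    """Phantom with activity rescaled to each organ's concentration at time t.

    Masks, attenuation and texture are time-invariant; only the activity map
    changes.
    """
    out = dataclasses.replace(p)
    out.activity = _paint_activity(p, kinetics, t)
    return out


def total_activity_Bq(p: PhantomVolume) -> float:
    return float(p.activity.sum() * p.voxel_volume_ml)
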