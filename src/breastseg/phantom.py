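"""Synthetic multi-parametric breast MRI phantom with known ground truth.

The phantom emulates the anatomy and tissue contrasts the segmentation
pipeline relies on, on a scaled-down grid:

* two breast-shaped foreground regions (clipped ellipsoids) attached to a
  chest wall;
* a torso block behind the chest wall with a bright subcutaneous fat layer,
  a pectoral muscle band directly beneath the anterior fat, and dimmer
  interior organs (the posterior side runs off the field of view, as it does
  on axial breast acquisitions);
* a connected fibro-glandular (FG) compartment inside each breast sized to a
  target density;
* a one-voxel bright skin shell on the breast surface;
* bright fat on non-fat-sat images, suppressed fat on fat-sat images
  (two-point DIXON-style water/in-phase contrast);
* a 4-D DCE series in which an optional tumor follows a rise-to-plateau
  enhancement curve while the rest of the breast enhances far more weakly;
* additive Gaussian noise and small (<2 mm) rigid shifts between sequences.

Intensity means are arbitrary units chosen to mimic the T2-W TSE ordering
fat > FG ≈ pectoral > organs > background; they are a modelling choice of
this package, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CONTRASTS, BinaryMask, ImageStack, MultiParametricStudy

# Tissue intensity means, arbitrary units (non-fat-sat structural image).
INTENSITY = {
    "fat": 1000.0,
    "fg": 400.0,
    "pectoral": 380.0,
    "organ": 350.0,
    "tumor": 420.0,
    "skin": 800.0,
    "background": 0.0,
}
#: Skin (dermis, water-dominated) keeps signal under fat saturation.
SKIN_FATSAT = 500.0
#: Per-contrast global gain so the three structural contrasts are distinct.
CONTRAST_GAIN = {"T1W": 0.9, "T2W": 1.0, "PDW": 1.1}

# DCE baseline signal (fat-suppressed acquisition).
DCE_BASELINE = {"fat": 40.0, "tissue": 100.0}
#: Peak relative enhancement of tumor voxels, (post-pre)/pre.
TUMOR_ENHANCEMENT = 2.0
#: Non-tumor breast tissue enhances at most this fraction as strongly.
PARENCHYMAL_ENHANCEMENT_RATIO = 0.15


class PhantomError(ValueError):
    pass


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise settings of the synthetic study.

    All lengths are millimetres.  ``breast_radii`` holds per-breast
    ``(r_slice, r_row, r_col)`` semi-axes; asymmetric radii produce
    asymmetric left/right breasts.  ``rigid_shift_mm`` (``dz, dy, dx``,
    magnitude < 2) is applied to every non-reference sequence before any
    co-registration, emulating inter-sequence patient motion.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    spacing: tuple[float, float, float] = (3.0, 1.2, 1.2)
    breast_radii: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (54.0, 36.0, 31.2),
        (54.0, 36.0, 31.2),
    )
    fg_fraction: float = 0.10
    tumor_radius: float = 8.0
    fat_sat_residual: float = 0.10
    noise_sigma: float = 20.0
    dce_noise_sigma: float = 3.0
    rigid_shift_mm: tuple[float, float, float] = (0.0, 0.8, -0.6)
    rotation_deg: float = 0.0
    n_timepoints: int = 40
    include_skin: bool = True
    seed: int = 0
    #: Required ratio of fat/FG contrast to noise (Otsu separability guard).
    min_contrast_to_noise: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fg_fraction <= 1.0:
            raise PhantomError("fg_fraction must be in [0, 1]")
        if not 0.0 <= self.fat_sat_residual < 1.0:
            raise PhantomError("fat_sat_residual must be in [0, 1)")
        if float(np.linalg.norm(self.rigid_shift_mm)) >= 2.0:
            raise PhantomError("rigid shifts must stay below 2 mm")
        if self.n_timepoints < 8:
            raise PhantomError("DCE needs at least 8 time points")
        contrast = INTENSITY["fat"] - INTENSITY["fg"]
        if self.noise_sigma > 0 and contrast / self.noise_sigma < self.min_contrast_to_noise:
            raise PhantomError("noise_sigma too large for Otsu separability")


@dataclass
class GroundTruth:
    """True tissue masks and derived quantities of a generated phantom."""

    breast: BinaryMask          # fat + FG + tumor + skin
    fat: BinaryMask
    fg: BinaryMask
    tumor: BinaryMask
    skin: BinaryMask
    pectoral: BinaryMask
    body: BinaryMask            # whole torso block
    chest_row: int              # first torso row (breast/torso junction)
    midline_col: int
    breast_slices: tuple[int, int]  # inclusive slice range containing breasts
    applied_shift_mm: tuple[float, float, float]
    volumes_cm3: dict = field(default_factory=dict)
    density_pct: float = 0.0


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

_CHEST_ROW = 62          # anterior torso surface, in rows
_FAT_LAYER = 7           # subcutaneous fat thickness, in pixels
_PECTORAL_ROWS = 6       # pectoral band thickness, in rows
_TORSO_COLS = (20, 108)  # lateral torso extent [start, stop)
_BREAST_CENTRES_COL = (34.0, 93.0)
_BREAST_CENTRE_ROW = 41.0


def _grids(shape, rotation_deg):
    """(slice, row, col) index grids, with rows/cols rotated about the image
    centre by ``-rotation_deg`` so shapes evaluated on them appear rotated by
    ``+rotation_deg`` in the output (masks stay exact booleans)."""
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nx, dtype=float),
        indexing="ij",
    )
    if rotation_deg:
        th = np.deg2rad(rotation_deg)
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        y0, x0 = yy - cy, xx - cx
        yy = cy + np.cos(th) * y0 + np.sin(th) * x0
        xx = cx - np.sin(th) * y0 + np.cos(th) * x0
    return zz, yy, xx


def _ellipsoid(zz, yy, xx, centre, radii_vox):
    cz, cy, cx = centre
    rz, ry, rx = radii_vox
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig) -> tuple[MultiParametricStudy, GroundTruth]:
    """Generate a synthetic study and its ground truth.

    Deterministic: the same config (including seed) yields bit-identical
    arrays.
    """
    nz, ny, nx = config.shape
    dz, dy, dx = config.spacing
    rng = np.random.default_rng(config.seed)
    zz, yy, xx = _grids(config.shape, config.rotation_deg)
    z_centre = (nz - 1) / 2.0

    # --- breasts ---------------------------------------------------------
    breasts = np.zeros(config.shape, dtype=bool)
    centres = []
    for radii_mm, c_col in zip(config.breast_radii, _BREAST_CENTRES_COL):
        radii_vox = (radii_mm[0] / dz, radii_mm[1] / dy, radii_mm[2] / dx)
        centre = (z_centre, _BREAST_CENTRE_ROW, c_col)
        if radii_vox[1] <= 0 or radii_vox[2] <= 0:
            raise PhantomError("breast radii must be positive")
        breasts |= _ellipsoid(zz, yy, xx, centre, radii_vox)
        centres.append((centre, radii_vox))
    breasts &= yy < _CHEST_ROW  # clip at the chest wall plane

    # --- torso ----------------------------------------------------------
    # Full cross-section only on slices intersecting the breasts; outside the
    # breast extent the cross-section tapers rapidly, emulating the extreme
    # slices (shoulder / diaphragm level) on which no significant breast
    # tissue is visible.
    breast_slice_area = breasts.reshape(nz, -1).sum(axis=1)
    breast_idx = np.nonzero(breast_slice_area)[0]
    if breast_idx.size == 0:
        raise PhantomError("breasts do not intersect the grid")
    z_lo, z_hi = int(breast_idx[0]), int(breast_idx[-1])

    torso = np.zeros(config.shape, dtype=bool)
    fat_layer = np.zeros(config.shape, dtype=bool)
    c0, c1 = _TORSO_COLS
    in_torso_cols = (xx >= c0) & (xx < c1)
    full = (yy >= _CHEST_ROW) & in_torso_cols
    taper_profile = (0.28, 0.22, 0.16, 0.10, 0.05)
    for z in range(nz):
        if z_lo <= z <= z_hi:
            torso[z] = full[z]
        else:
            d = (z_lo - z) if z < z_lo else (z - z_hi)
            if d <= len(taper_profile):
                f = taper_profile[d - 1]
                half_w = (c1 - c0) / 2.0 * f
                depth = (ny - _CHEST_ROW) * f
                cc = (c0 + c1) / 2.0
                torso[z] = (
                    (yy[z] >= _CHEST_ROW)
                    & (yy[z] < _CHEST_ROW + depth)
                    & (np.abs(xx[z] - cc) <= half_w)
                )
    # Subcutaneous fat: anterior band + lateral strips (posterior off-FOV).
    fat_layer = torso & (
        (yy < _CHEST_ROW + _FAT_LAYER)
        | (xx < c0 + _FAT_LAYER)
        | (xx >= c1 - _FAT_LAYER)
    )
    pectoral = (
        torso
        & ~fat_layer
        & (yy >= _CHEST_ROW + _FAT_LAYER)
        & (yy < _CHEST_ROW + _FAT_LAYER + _PECTORAL_ROWS)
    )
    organs = torso & ~fat_layer & ~pectoral
    torso &= ~breasts  # breasts take precedence where the ellipsoids overlap
    fat_layer &= ~breasts
    pectoral &= ~breasts
    organs &= ~breasts

    # --- inner breast tissue --------------------------------------------
    fg = np.zeros(config.shape, dtype=bool)
    if config.fg_fraction > 0:
        scale = config.fg_fraction ** (1.0 / 3.0)
        for centre, radii_vox in centres:
            fg |= _ellipsoid(zz, yy, xx, centre, tuple(r * scale for r in radii_vox))
        fg &= breasts

    tumor = np.zeros(config.shape, dtype=bool)
    if config.tumor_radius > 0:
        (centre, radii_vox) = centres[0]
        max_radius_mm = min(config.breast_radii[0])
        if config.tumor_radius >= max_radius_mm:
            raise PhantomError("tumor does not fit inside the breast")
        t_centre = (centre[0], centre[1] + 12.0, centre[2] - 16.0)
        t_radii = (config.tumor_radius / dz, config.tumor_radius / dy, config.tumor_radius / dx)
        tumor = _ellipsoid(zz, yy, xx, t_centre, t_radii) & breasts & ~fg

    # --- skin shell ------------------------------------------------------
    from scipy.ndimage import binary_dilation

    if config.include_skin:
        shell = binary_dilation(breasts, structure=np.ones((1, 3, 3), bool)) & ~breasts
        skin = shell & ~torso & (yy < _CHEST_ROW)
    else:
        skin = np.zeros(config.shape, dtype=bool)

    fat = breasts & ~fg & ~tumor
    breast_total = breasts | skin

    # --- intensity volumes ----------------------------------------------
    def structural(fat_sat: bool, gain: float) -> np.ndarray:
        vol = np.zeros(config.shape, dtype=np.float64)
        fat_scale = config.fat_sat_residual if fat_sat else 1.0
        vol[fat] = INTENSITY["fat"] * fat_scale
        vol[fat_layer] = INTENSITY["fat"] * fat_scale
        vol[fg] = INTENSITY["fg"]
        vol[tumor] = INTENSITY["tumor"]
        vol[pectoral] = INTENSITY["pectoral"]
        vol[organs] = INTENSITY["organ"]
        vol[skin] = SKIN_FATSAT if fat_sat else INTENSITY["skin"]
        return vol * gain

    def add_noise(vol: np.ndarray, sigma: float) -> np.ndarray:
        if sigma <= 0:
            return vol
        return np.clip(vol + rng.normal(0.0, sigma, vol.shape), 0.0, None)

    def shift(vol: np.ndarray) -> np.ndarray:
        s = config.rigid_shift_mm
        if not any(s):
            return vol
        from scipy.ndimage import shift as nd_shift

        shift_vox = (s[0] / dz, s[1] / dy, s[2] / dx)
        return np.clip(nd_shift(vol, shift_vox, order=1, mode="constant", cval=0.0), 0.0, None)

    ref = ("T2W", False)
    stacks: dict[tuple[str, bool], ImageStack] = {}
    for contrast in CONTRASTS:
        for fat_sat in (False, True):
            vol = structural(fat_sat, CONTRAST_GAIN[contrast])
            if (contrast, fat_sat) != ref:
                vol = shift(vol)
            stacks[(contrast, fat_sat)] = ImageStack(
                add_noise(vol, config.noise_sigma), config.spacing
            )

    # --- DCE series ------------------------------------------------------
    base = np.zeros(config.shape, dtype=np.float64)
    base[fat | fat_layer] = DCE_BASELINE["fat"]
    base[fg | tumor | skin | pectoral | organs] = DCE_BASELINE["tissue"]
    curve = _enhancement_curve(config.n_timepoints)
    dce = np.empty((config.n_timepoints,) + config.shape, dtype=np.float32)
    tissue_enh = PARENCHYMAL_ENHANCEMENT_RATIO * TUMOR_ENHANCEMENT
    base_shifted = shift(base)
    tumor_shifted = shift(tumor.astype(np.float64))
    body_frac = shift((fg | skin | pectoral | organs).astype(np.float64))
    for t in range(config.n_timepoints):
        enh = 1.0 + tissue_enh * curve[t] * body_frac + (
            TUMOR_ENHANCEMENT - tissue_enh
        ) * curve[t] * tumor_shifted
        frame = base_shifted * enh
        dce[t] = add_noise(frame, config.dce_noise_sigma).astype(np.float32)

    study = MultiParametricStudy(stacks, dce=dce, reference_contrast="T2W")

    # --- ground truth ----------------------------------------------------
    vox_cm3 = dz * dy * dx / 1000.0

    def _mask(arr, name):
        return BinaryMask(arr, config.spacing, name=name)

    tissue_total = int(fat.sum() + fg.sum() + tumor.sum())
    volumes = {
        "breast": breast_total.sum() * vox_cm3,
        "breast_tissue": tissue_total * vox_cm3,
        "fat": fat.sum() * vox_cm3,
        "fg": fg.sum() * vox_cm3,
        "tumor": tumor.sum() * vox_cm3,
        "skin": skin.sum() * vox_cm3,
    }
    density = 100.0 * fg.sum() / tissue_total if tissue_total else 0.0
    gt = GroundTruth(
        breast=_mask(breast_total, "mask1"),
        fat=_mask(fat, "mask2"),
        fg=_mask(fg, "mask5"),
        tumor=_mask(tumor, "mask4"),
        skin=_mask(skin, "skin"),
        pectoral=_mask(pectoral, "skin"),
        body=_mask(torso, "skin"),
        chest_row=_CHEST_ROW,
        midline_col=int(round((_BREAST_CENTRES_COL[0] + _BREAST_CENTRES_COL[1]) / 2)),
        breast_slices=(z_lo, z_hi),
        applied_shift_mm=config.rigid_shift_mm,
        volumes_cm3=volumes,
        density_pct=float(density),
    )
    return study, gt


def _enhancement_curve(n_timepoints: int) -> np.ndarray:
    """Normalised bolus curve: flat baseline over the first 4+ frames, rise
    from frame 6, plateau ~1.0 reached around frame 12 with a gentle washout.
    """
    t = np.arange(n_timepoints, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-(t - 9.0) / 1.2))
    washout = np.where(t > 14, 1.0 - 0.004 * (t - 14), 1.0)
    curve = rise * washout
    curve[:5] = 0.0
    return curve
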