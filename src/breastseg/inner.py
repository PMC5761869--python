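"""Inner segmentation: fat / fibro-glandular / tumor decomposition of mask1.

Fat (mask2) comes from subtracting the fat-saturated member of a structural
pair from the non-fat-saturated one and Otsu-thresholding the difference
inside mask1.  The tumor (mask4) comes from the normalised DCE difference
image DI = (post - pre)/pre thresholded inside mask1 and regularised with a
disc-9 erosion/dilation.  FG is pure mask algebra: mask3 = mask1 - mask2,
mask5 = mask3 - mask4.  Skin is removed from mask1 beforehand with a
Hessian-based sheetness filter restricted to a band around the mask
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    LABEL_FAT,
    LABEL_FG,
    LABEL_TUMOR,
    BinaryMask,
    ImageStack,
    LabelMap,
)
from .outer import DegenerateHistogramError, fractional_otsu

log = logging.getLogger("breastseg")


class FatSeparabilityError(ValueError):
    """The with/without fat-saturation difference has no two-class structure."""


@dataclass
class InnerParams:
    tumor_morph_disc: int = 9     # disc diameter in pixels, odd
    pre_window: int = 4           # pre-contrast average length
    post_window: int = 4          # max point + 3 neighbours
    sheetness_scale_mm: float = 1.5
    sheetness_threshold: float = 0.6
    skin_removal_enabled: bool = True
    #: Largest credible enhancing-lesion fraction of the breast.  When the
    #: DI Otsu class above threshold exceeds this, the "lesion" is diffuse
    #: background parenchymal enhancement, not a tumor (the cohort maximum
    #: tumor is ~7 cm^3, one or two percent of a breast), and mask4 is
    #: returned empty with a warning — the no-tumor case.
    max_lesion_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.tumor_morph_disc % 2 == 0:
            raise ValueError("tumor_morph_disc must be odd")
        if self.pre_window < 1 or self.post_window < 1:
            raise ValueError("windows must be >= 1")


# ---------------------------------------------------------------------------
# Fat mask
# ---------------------------------------------------------------------------

def fat_mask(
    nofatsat: ImageStack, fatsat: ImageStack, mask1: BinaryMask
) -> BinaryMask:
    """mask2: fat voxels within mask1 from the WWFS difference.

    D = nofatsat - fatsat with negatives clamped to zero (a fat-sat voxel
    brighter than its non-fat-sat counterpart is noise, not tissue);
    mask2 = (D >= Otsu(D over mask1)) intersected with mask1.
    """
    if nofatsat.shape != fatsat.shape or nofatsat.shape != mask1.shape:
        raise ValueError("stacks and mask1 must share one grid")
    diff = np.clip(nofatsat.voxels - fatsat.voxels, 0.0, None)
    sample = diff[mask1.voxels]
    if sample.size < 2:
        raise FatSeparabilityError("fat/FG not separable: empty mask1")
    try:
        threshold = fractional_otsu(sample)
    except DegenerateHistogramError as exc:
        raise FatSeparabilityError("fat/FG not separable") from exc
    log.info("fat mask Otsu threshold: %.2f", threshold)
    return BinaryMask((diff >= threshold) & mask1.voxels, mask1.spacing, name="mask2")


# ---------------------------------------------------------------------------
# DCE difference image
# ---------------------------------------------------------------------------

def difference_image(
    dce: np.ndarray,
    params: InnerParams | None = None,
    mask1: BinaryMask | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ImageStack:
    """Normalised post-minus-pre enhancement map DI = (post - pre)/pre.

    pre is the voxelwise mean of the first four time points; the maximally
    enhanced time point t* (largest spatial mean enhancement, over mask1
    when given) is averaged with its three nearest neighbours by index
    (symmetric-preferred 4-frame window, clamped at the series ends) to form
    post.  The denominator carries a machine-scale guard so DI is invariant
    to a positive rescaling of the whole series; DI is clamped below at 0.
    """
    params = params or InnerParams()
    dce = np.asarray(dce, dtype=np.float64)
    if dce.ndim != 4 or dce.shape[0] < params.pre_window + params.post_window:
        raise ValueError("DCE stack must be 4-D with >= 8 time points")
    n_t = dce.shape[0]
    pre = dce[: params.pre_window].mean(axis=0)
    support = mask1.voxels if mask1 is not None else np.ones(pre.shape, bool)
    if not support.any():
        support = np.ones(pre.shape, bool)
    enhancement = np.array([
        float((dce[t] - pre)[support].mean()) for t in range(n_t)
    ])
    t_star = int(np.argmax(enhancement))
    if t_star < params.pre_window:
        log.warning("maximal enhancement at frame %d, inside the pre window "
                    "(no enhancement?)", t_star)
    start = int(np.clip(t_star - 1, 0, n_t - params.post_window))
    post = dce[start : start + params.post_window].mean(axis=0)
    eps = np.finfo(np.float64).eps * max(float(pre.max()), np.finfo(np.float64).tiny)
    di = np.clip((post - pre) / (pre + eps), 0.0, None)
    log.info("difference image: t*=%d, post window [%d, %d]",
             t_star, start, start + params.post_window - 1)
    return ImageStack(di, spacing)


def tumor_mask(
    di: ImageStack, mask1: BinaryMask, params: InnerParams | None = None
) -> BinaryMask:
    """mask4: enhancing tumor from the difference image.

    Otsu threshold of DI over mask1, intersected with mask1, then per-slice
    erosion followed by dilation with a disc of the configured diameter
    (default 9).  A degenerate DI histogram (no enhancing lesion) yields an
    empty mask with a warning.
    """
    params = params or InnerParams()
    sample = di.voxels[mask1.voxels]
    empty = BinaryMask(np.zeros(mask1.shape, bool), mask1.spacing, name="mask4")
    if sample.size < 2:
        log.warning("tumor mask: mask1 empty; returning empty mask4")
        return empty
    try:
        threshold = fractional_otsu(sample)
    except DegenerateHistogramError:
        log.warning("tumor mask: degenerate DI histogram; returning empty mask4")
        return empty
    log.info("tumor mask Otsu threshold: %.4f", threshold)
    m = (di.voxels >= threshold) & mask1.voxels
    fraction = m.sum() / max(mask1.count(), 1)
    if fraction > params.max_lesion_fraction:
        log.warning(
            "tumor mask: enhancing class covers %.1f%% of the breast "
            "(diffuse parenchymal enhancement, no focal lesion); "
            "returning empty mask4", 100 * fraction,
        )
        return empty
    from skimage.morphology import disk

    footprint = disk(params.tumor_morph_disc // 2)
    out = np.zeros_like(m)
    for z in range(m.shape[0]):
        if m[z].any():
            eroded = ndimage.binary_erosion(m[z], structure=footprint)
            out[z] = ndimage.binary_dilation(eroded, structure=footprint)
    return BinaryMask(out, mask1.spacing, name="mask4")


# ---------------------------------------------------------------------------
# FG mask algebra
# ---------------------------------------------------------------------------

def fg_mask(
    mask1: BinaryMask, mask2: BinaryMask, mask4: BinaryMask
) -> tuple[BinaryMask, BinaryMask]:
    """mask3 = mask1 - mask2 (FG + tumor); mask5 = mask3 - mask4 (FG)."""
    if not (mask1.shape == mask2.shape == mask4.shape):
        raise ValueError("masks must share one grid")
    m3 = mask1.voxels & ~mask2.voxels
    m5 = m3 & ~mask4.voxels
    return (
        BinaryMask(m3, mask1.spacing, name="mask3"),
        BinaryMask(m5, mask1.spacing, name="mask5"),
    )


# ---------------------------------------------------------------------------
# Skin removal
# ---------------------------------------------------------------------------

def sheetness_score(
    structural: ImageStack,
    scale_mm: float,
    brightness_reference: np.ndarray | None = None,
) -> np.ndarray:
    """Single-scale bright-sheet score: high where one Hessian eigenvalue
    dominates *and* the voxel itself is bright.

    Gaussian second derivatives are taken at ``scale_mm`` (per-axis sigma in
    voxels = scale/spacing) in physical units.  For bright thin sheets the
    dominant eigenvalue lambda3 is strongly negative while the in-plane
    eigenvalues stay small, giving the anisotropy term
    sqrt(1 - |lambda2|/|lambda3|).  Because a one-voxel sheet aliases the
    eigenvalue ratios of its dark neighbourhood, the score is additionally
    weighted by the voxel intensity relative to the 95th percentile of the
    region of interest (``brightness_reference`` mask; all positive voxels
    when omitted) — the "bright" in bright-sheet.  Scores lie in [0, 1].
    """
    vol = structural.voxels.astype(np.float64)
    spacing = np.asarray(structural.spacing)
    sigmas = scale_mm / spacing
    axes = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    H = {}
    for i, j in axes:
        order = [0, 0, 0]
        order[i] += 1
        order[j] += 1
        d = ndimage.gaussian_filter(vol, sigmas, order=order)
        # derivatives w.r.t. physical coordinates, gamma-normalised by scale^2
        H[(i, j)] = d * scale_mm**2 / (spacing[i] * spacing[j])
    hess = np.stack([
        np.stack([H[(0, 0)], H[(0, 1)], H[(0, 2)]], axis=-1),
        np.stack([H[(0, 1)], H[(1, 1)], H[(1, 2)]], axis=-1),
        np.stack([H[(0, 2)], H[(1, 2)], H[(2, 2)]], axis=-1),
    ], axis=-2)
    eig = np.linalg.eigvalsh(hess)                      # ascending
    order = np.argsort(np.abs(eig), axis=-1)
    eig = np.take_along_axis(eig, order, axis=-1)       # by |lambda|
    lam2, lam3 = eig[..., 1], eig[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        anisotropy = 1.0 - np.abs(lam2) / np.abs(lam3)
    anisotropy = np.where(np.isfinite(anisotropy), anisotropy, 0.0)
    anisotropy = np.where(lam3 < 0, np.clip(anisotropy, 0.0, 1.0), 0.0)
    region = brightness_reference if brightness_reference is not None else vol > 0
    if region.any():
        i_ref = float(np.percentile(vol[region], 95))
    else:
        i_ref = float(vol.max()) or 1.0
    brightness = np.clip(vol / max(i_ref, np.finfo(np.float64).tiny), 0.0, 1.0)
    return np.sqrt(anisotropy) * brightness


def remove_skin(
    structural: ImageStack, mask: BinaryMask, params: InnerParams | None = None
) -> BinaryMask:
    """Remove thin bright skin sheets from the mask boundary.

    Voxels with sheetness >= threshold lying within 2 x scale of the mask
    boundary are dropped.  The structural stack should be one on which skin
    is conspicuous against its surroundings (the fat-saturated member works
    well: dermis keeps signal while subcutaneous fat is suppressed).
    """
    params = params or InnerParams()
    if not params.skin_removal_enabled:
        return BinaryMask(mask.voxels.copy(), mask.spacing, name=mask.name)
    if not mask.voxels.any():
        return BinaryMask(mask.voxels.copy(), mask.spacing, name=mask.name)
    depth = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)
    band = mask.voxels & (depth <= 2.0 * params.sheetness_scale_mm)
    # brightness is judged against the whole mask: on fat-sat images skin is
    # as bright as the brightest soft tissue (FG), while subcutaneous fat is
    # dark, so a skin-free boundary never reaches the threshold
    score = sheetness_score(structural, params.sheetness_scale_mm,
                            brightness_reference=mask.voxels)
    skin = band & (score >= params.sheetness_threshold)
    log.info("skin removal: dropping %d voxels", int(skin.sum()))
    return BinaryMask(mask.voxels & ~skin, mask.spacing, name=mask.name)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def combine_labels(
    mask2: BinaryMask, mask5: BinaryMask, mask4: BinaryMask
) -> LabelMap:
    """Combined label volume: 1=fat, 2=FG, 3=tumor (tumor > fat > FG where
    morphology artifacts create overlaps)."""
    labels = np.zeros(mask2.shape, dtype=np.uint8)
    labels[mask5.voxels] = LABEL_FG
    labels[mask2.voxels] = LABEL_FAT
    labels[mask4.voxels] = LABEL_TUMOR
    return LabelMap(labels.astype(np.int16), mask2.spacing)
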