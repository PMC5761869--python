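"""Similarity metrics, volumes, breast density and cohort summaries.

Overlap metrics between a manual mask A and an automatic mask B:

    Dice        d = 2|A∩B| / (|A| + |B|)
    Jaccard     p = |A∩B| / (|A| + |B| - |A∩B|)   (= d / (2 - d))
    sensitivity s = |A∩B| / |B|

Breast density is 100 x FG volume / total breast volume, with tumor tissue
not counted as FG.  Left/right agreement is summarised Bland-Altman style as
[(L+R)/2, L-R] together with the Pearson correlation of the two densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import BinaryMask, voxel_volume

#: Evaluate similarity on every n-th slice (3 mirrors scoring against manual
#: masks drawn on every third slice; 1 scores every slice).
DEFAULT_SLICE_STRIDE = 1


class UndefinedMetricError(ValueError):
    pass


@dataclass
class SimilarityReport:
    dice: float
    jaccard: float
    sensitivity: float
    n_a: int
    n_b: int
    n_intersection: int


def _counts(a: BinaryMask, b: BinaryMask, slice_stride: int) -> tuple[int, int, int]:
    if a.shape != b.shape:
        raise ValueError("masks must share one shape")
    av = a.voxels[::slice_stride]
    bv = b.voxels[::slice_stride]
    return int(av.sum()), int(bv.sum()), int((av & bv).sum())


def dice(a: BinaryMask, b: BinaryMask, slice_stride: int = DEFAULT_SLICE_STRIDE) -> float:
    na, nb, ni = _counts(a, b, slice_stride)
    if na + nb == 0:
        raise UndefinedMetricError("undefined overlap: both masks empty")
    return 2.0 * ni / (na + nb)


def jaccard(a: BinaryMask, b: BinaryMask, slice_stride: int = DEFAULT_SLICE_STRIDE) -> float:
    na, nb, ni = _counts(a, b, slice_stride)
    union = na + nb - ni
    if union == 0:
        raise UndefinedMetricError("undefined overlap: both masks empty")
    return ni / union


def sensitivity(a: BinaryMask, b: BinaryMask, slice_stride: int = DEFAULT_SLICE_STRIDE) -> float:
    """|A∩B| / |B| with A the manual and B the automatic mask (asymmetric)."""
    _, nb, ni = _counts(a, b, slice_stride)
    if nb == 0:
        raise UndefinedMetricError("undefined: automatic mask empty")
    return ni / nb


def similarity_report(
    a: BinaryMask, b: BinaryMask, slice_stride: int = DEFAULT_SLICE_STRIDE
) -> SimilarityReport:
    na, nb, ni = _counts(a, b, slice_stride)
    return SimilarityReport(
        dice=dice(a, b, slice_stride),
        jaccard=jaccard(a, b, slice_stride),
        sensitivity=sensitivity(a, b, slice_stride),
        n_a=na, n_b=nb, n_intersection=ni,
    )


# ---------------------------------------------------------------------------
# Volumes and density
# ---------------------------------------------------------------------------

def mask_volume(mask: BinaryMask) -> float:
    """Mask volume in cm^3 (voxel count x voxel volume / 1000)."""
    return mask.count() * voxel_volume(mask) / 1000.0


def breast_density(fg_volume: float, total_volume: float) -> float:
    """Percent breast density: 100 x FG volume / total breast volume."""
    if total_volume <= 0:
        raise UndefinedMetricError("undefined density: total volume is 0")
    return 100.0 * fg_volume / total_volume


def split_left_right(
    mask: BinaryMask, midline_col: int
) -> tuple[BinaryMask, BinaryMask]:
    """(left, right) halves of a mask at a midline column.

    Patient right appears on the image left in radiological axial display,
    so image columns < midline are the right breast and columns >= midline
    the left.
    """
    if not 0 < midline_col < mask.shape[2]:
        raise ValueError("midline column outside the image")
    right = mask.voxels.copy()
    right[:, :, midline_col:] = False
    left = mask.voxels.copy()
    left[:, :, :midline_col] = False
    return (
        BinaryMask(left, mask.spacing, name=mask.name),
        BinaryMask(right, mask.spacing, name=mask.name),
    )


def bland_altman(left: float, right: float) -> tuple[float, float]:
    """Agreement pair [(L+R)/2, L-R] for left/right breast density."""
    return (left + right) / 2.0, left - right


@dataclass
class TissueReport:
    """Per-study volumes (cm^3), density (%) and left/right splits."""

    total_cm3: float
    fg_cm3: float
    tumor_cm3: float
    density_pct: float
    left_total_cm3: float = np.nan
    left_fg_cm3: float = np.nan
    left_density_pct: float = np.nan
    right_total_cm3: float = np.nan
    right_fg_cm3: float = np.nan
    right_density_pct: float = np.nan

    def bland_altman_lr(self) -> tuple[float, float]:
        return bland_altman(self.left_density_pct, self.right_density_pct)

    def as_row(self) -> dict:
        return {k: round(v, 2) if isinstance(v, float) else v
                for k, v in self.__dict__.items()}


def tissue_report(
    mask1: BinaryMask, mask5: BinaryMask, mask4: BinaryMask, midline_col: int
) -> TissueReport:
    """Volumes and densities from the final masks (tumor excluded from FG)."""
    total = mask_volume(mask1)
    fg = mask_volume(mask5)
    l1, r1 = split_left_right(mask1, midline_col)
    l5, r5 = split_left_right(mask5, midline_col)
    return TissueReport(
        total_cm3=total,
        fg_cm3=fg,
        tumor_cm3=mask_volume(mask4),
        density_pct=breast_density(fg, total),
        left_total_cm3=mask_volume(l1),
        left_fg_cm3=mask_volume(l5),
        left_density_pct=breast_density(mask_volume(l5), mask_volume(l1)),
        right_total_cm3=mask_volume(r1),
        right_fg_cm3=mask_volume(r5),
        right_density_pct=breast_density(mask_volume(r5), mask_volume(r1)),
    )


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

AGE_BINS = ((20, 40), (40, 60), (60, 80))


def cohort_summary(table: pd.DataFrame) -> dict:
    """Means/SDs of volumes and densities over a per-patient table.

    Expects columns ``total_cm3``, ``fg_cm3``, ``density_pct`` and optionally
    ``tumor_cm3`` (NaN for patients without tumor), ``left_density_pct`` /
    ``right_density_pct`` and ``age``.
    """
    if len(table) < 2:
        raise ValueError("cohort summary needs >= 2 patients")
    out: dict = {"n": int(len(table))}
    for col in ("total_cm3", "fg_cm3", "density_pct"):
        out[f"mean_{col}"] = float(table[col].mean())
        out[f"sd_{col}"] = float(table[col].std(ddof=1))
    if "tumor_cm3" in table:
        tumors = table["tumor_cm3"].dropna()
        out["n_tumor"] = int(len(tumors))
        if len(tumors):
            out["mean_tumor_cm3"] = float(tumors.mean())
            out["min_tumor_cm3"] = float(tumors.min())
            out["max_tumor_cm3"] = float(tumors.max())
    if {"left_density_pct", "right_density_pct"} <= set(table.columns):
        left = table["left_density_pct"].to_numpy(float)
        right = table["right_density_pct"].to_numpy(float)
        if np.std(left) == 0 or np.std(right) == 0:
            out["lr_density_pearson_r"] = np.nan
        else:
            from scipy import stats

            r, p = stats.pearsonr(left, right)
            out["lr_density_pearson_r"] = float(r)
            out["lr_density_pearson_p"] = float(p)
        mean, diff = np.vectorize(bland_altman)(left, right)
        out["lr_bland_altman_mean"] = [float(x) for x in mean]
        out["lr_bland_altman_diff"] = [float(x) for x in diff]
    if "age" in table:
        groups = {}
        for lo, hi in AGE_BINS:
            sel = table[(table["age"] >= lo) & (table["age"] < hi)]
            if len(sel):
                groups[f"{lo}-{hi}"] = float(sel["density_pct"].mean())
        out["density_by_age_group"] = groups
    return out


def load_reference_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Published per-patient volume tables of the 30-patient study the
    method was developed on (whole-breast table and left/right table).

    These ship as package data so density arithmetic and cohort statistics
    can be recomputed without patient images.
    """
    pkg = resources.files("breastseg") / "data"
    with resources.as_file(pkg / "reference_cohort.csv") as p:
        whole = pd.read_csv(p)
    with resources.as_file(pkg / "reference_cohort_lr.csv") as p:
        lr = pd.read_csv(p)
    return whole, lr
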