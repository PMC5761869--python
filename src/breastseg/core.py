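"""Domain types, coordinate conventions and readers/writers.

Coordinate convention used throughout the package
-------------------------------------------------
Volumes are indexed ``(slice, row, col)``, 0-based, with axial slices and the
*anterior* side of the patient at row 0 ("breasts at the top of the image",
the orientation in which all landmark logic is defined).  Spacing is given as
``(dz, dy, dx)`` in millimetres.  Loaders are responsible for rotating /
flipping acquired data into this frame; everything downstream assumes it.

Only axial acquisitions are supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

log = logging.getLogger("breastseg")

AXIAL_ANTERIOR_TOP = "axial-anterior-top"

#: Structural contrast tokens.
CONTRASTS = ("T1W", "T2W", "PDW")

#: Tokens a BinaryMask may carry.
MASK_NAMES = ("mask1", "mask2", "mask3", "mask4", "mask5", "skin")

LABEL_BACKGROUND = 0
LABEL_FAT = 1
LABEL_FG = 2
LABEL_TUMOR = 3


class StudyError(ValueError):
    """Raised for malformed or incomplete multi-parametric studies."""


class GeometryMismatchError(StudyError):
    """Member stacks cannot be brought onto a common grid."""


@dataclass
class ImageStack:
    """One 3-D scalar volume with voxel spacing and orientation metadata.

    Parameters
    ----------
    voxels
        Non-negative intensities, shape ``(n_slices, n_rows, n_cols)``.
        Stored as floating point regardless of the on-disk integer type
        (difference images and normalisation require it).
    spacing
        ``(dz, dy, dx)`` in mm, all components > 0.
    orientation_tag
        Token asserting the frame convention (anterior = top rows, axial
        slices).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    orientation_tag: str = AXIAL_ANTERIOR_TOP

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.floating):
            self.voxels = self.voxels.astype(np.float64)
        if self.voxels.size and float(np.min(self.voxels)) < 0:
            raise ValueError("intensities must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def copy_with(self, voxels: np.ndarray) -> "ImageStack":
        return ImageStack(voxels, self.spacing, self.orientation_tag)


@dataclass
class BinaryMask:
    """Voxelwise boolean tissue mask sharing the grid of its source stack."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    name: str = "mask1"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(np.count_nonzero(self.voxels))


@dataclass
class LabelMap:
    """Combined tissue label volume: 0=background, 1=fat, 2=FG, 3=tumor."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("labels must be integer")
        bad = set(np.unique(self.voxels)) - {LABEL_BACKGROUND, LABEL_FAT, LABEL_FG, LABEL_TUMOR}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")


@dataclass
class MultiParametricStudy:
    """Co-registered bundle of structural stacks plus one 4-D DCE stack.

    ``structural`` maps ``(contrast, fat_sat)`` — e.g. ``("T2W", False)`` for
    the non-fat-saturated T2-weighted member — to an :class:`ImageStack`.
    ``dce`` is ``(time, slice, row, col)`` with at least 8 time points (a
    pre-contrast average of 4 frames plus a 4-frame post window).  ``dce`` may
    be ``None``: the structural stages still run (degraded mode, no tumor
    mask).
    """

    structural: Mapping[tuple[str, bool], ImageStack]
    dce: np.ndarray | None = None
    reference_contrast: str = "T2W"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.structural:
            raise StudyError("incomplete study: no structural stacks")
        shapes = {s.shape for s in self.structural.values()}
        if len(shapes) != 1:
            raise GeometryMismatchError(f"geometry mismatch: member shapes {shapes}")
        spacings = {s.spacing for s in self.structural.values()}
        if len(spacings) != 1:
            raise GeometryMismatchError(f"geometry mismatch: member spacings {spacings}")
        self.spacing = next(iter(spacings))
        if not self.wwfs_pairs():
            raise StudyError("incomplete study: no complete with/without fat-saturation pair")
        if self.dce is not None:
            self.dce = np.asarray(self.dce)
            if self.dce.ndim != 4:
                raise StudyError("DCE stack must be 4-D (time, slice, row, col)")
            if self.dce.shape[0] < 8:
                raise StudyError(
                    f"incomplete study: DCE needs >= 8 time points, got {self.dce.shape[0]}"
                )
            if self.dce.shape[1:] != next(iter(shapes)):
                raise GeometryMismatchError("geometry mismatch: DCE grid differs from structural")

    def wwfs_pairs(self) -> list[str]:
        """Contrasts for which both fat-sat and non-fat-sat members exist."""
        return [c for c in CONTRASTS
                if (c, False) in self.structural and (c, True) in self.structural]

    def reference_pair(self) -> tuple[ImageStack, ImageStack]:
        """(non-fat-sat, fat-sat) pair used for fat/FG separation.

        Falls back to any complete pair when the reference contrast is
        incomplete (any of T2-W / T1-W / PD-W is acceptable).
        """
        contrast = self.reference_contrast
        if contrast not in self.wwfs_pairs():
            contrast = self.wwfs_pairs()[0]
        return self.structural[(contrast, False)], self.structural[(contrast, True)]

    def reference_stack(self) -> ImageStack:
        c = self.reference_contrast
        if (c, False) in self.structural:
            return self.structural[(c, False)]
        return self.structural[(self.wwfs_pairs()[0], False)]


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def voxel_volume(stack: ImageStack | BinaryMask) -> float:
    """Volume of one voxel in mm^3 (``dz * dy * dx``)."""
    dz, dy, dx = stack.spacing
    return dz * dy * dx


def normalize_orientation(voxels: np.ndarray, anterior_at_top: bool = True) -> np.ndarray:
    """Flip rows so the anterior (breast) side occupies the top rows.

    Idempotent by construction: the flip is applied only when
    ``anterior_at_top`` is False, i.e. the caller states the data's current
    orientation; normalising already-normalised data is the identity.
    """
    if anterior_at_top:
        return voxels
    return voxels[:, ::-1, :]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------
# On-disk NIfTI-1 frame: we store arrays as (x, y, z) = (col, row, slice) with
# an affine diag(dx, -dy, dz) so that increasing row moves in -y (anterior at
# row 0 for a supine axial acquisition).  read_stack inverts write_stack
# bit-exactly and accepts both .nii/.nii.gz files and DICOM series
# directories.

def _to_nifti(voxels: np.ndarray, spacing: tuple[float, float, float]):
    import nibabel as nib

    dz, dy, dx = spacing
    affine = np.diag([dx, -dy, dz, 1.0])
    data = np.transpose(voxels, (2, 1, 0))
    return nib.Nifti1Image(np.ascontiguousarray(data), affine)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    _to_nifti(stack.voxels, stack.spacing).to_filename(str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    _to_nifti(mask.voxels.astype(np.uint8), mask.spacing).to_filename(str(path))


def write_labels(labels: LabelMap, path: str | Path) -> None:
    _to_nifti(labels.voxels.astype(np.uint8), labels.spacing).to_filename(str(path))


def write_dce(dce: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    import nibabel as nib

    dz, dy, dx = spacing
    affine = np.diag([dx, -dy, dz, 1.0])
    data = np.transpose(dce, (3, 2, 1, 0))  # (t,z,y,x) -> (x,y,z,t)
    nib.Nifti1Image(np.ascontiguousarray(data), affine).to_filename(str(path))


def _read_nifti_array(path: Path) -> tuple[np.ndarray, tuple[float, ...]]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    return data, zooms


def read_stack(path: str | Path) -> ImageStack:
    """Read a 3-D volume from NIfTI (or a DICOM series directory)."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    data, zooms = _read_nifti_array(path)
    if data.ndim != 3:
        raise StudyError(f"{path} is not a 3-D volume")
    voxels = np.transpose(data, (2, 1, 0)).astype(np.float64)
    dx, dy, dz = zooms[:3]
    return ImageStack(voxels, (float(dz), float(dy), float(dx)))


def read_mask(path: str | Path, name: str = "mask1") -> BinaryMask:
    data, zooms = _read_nifti_array(Path(path))
    voxels = np.transpose(data, (2, 1, 0)) > 0
    dx, dy, dz = zooms[:3]
    return BinaryMask(voxels, (float(dz), float(dy), float(dx)), name=name)


def read_dce(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    data, zooms = _read_nifti_array(Path(path))
    if data.ndim != 4:
        raise StudyError(f"{path} is not a 4-D DCE series")
    dce = np.transpose(data, (3, 2, 1, 0)).astype(np.float32)
    dx, dy, dz = zooms[:3]
    return dce, (float(dz), float(dy), float(dx))


def _read_dicom_series(directory: Path) -> ImageStack:
    """Read one DICOM series directory via SimpleITK, reoriented to our frame."""
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(str(directory))
    if not names:
        raise StudyError(f"no DICOM series found in {directory}")
    reader.SetFileNames(names)
    img = sitk.DICOMOrient(reader.Execute(), "LPS")
    arr = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
    sx, sy, sz = img.GetSpacing()
    # LPS: +y posterior, so anterior already sits at small y (row 0).
    arr = np.clip(arr, 0, None)
    return ImageStack(arr, (float(sz), float(sy), float(sx)))


def load_study(
    paths: Mapping[str, str | Path],
    reference_contrast: str = "T2W",
) -> MultiParametricStudy:
    """Assemble a study from per-contrast file locations.

    ``paths`` keys are tokens like ``"t2w"``, ``"t2w_fs"`` (fat-saturated)
    and ``"dce"``; values are NIfTI files or DICOM series directories.  All
    members are resampled onto the grid of the reference stack when their
    shapes differ (linear interpolation, matching the scanner's own
    interpolation of the low-resolution DCE matrix).
    """
    structural: dict[tuple[str, bool], ImageStack] = {}
    dce = None
    dce_spacing = None
    for key, p in paths.items():
        key_l = key.lower()
        if key_l == "dce":
            dce, dce_spacing = read_dce(p)
            continue
        fat_sat = key_l.endswith("_fs")
        contrast = key_l[:-3] if fat_sat else key_l
        if contrast.upper() not in CONTRASTS:
            raise StudyError(f"unknown contrast token {key!r}")
        structural[(contrast.upper(), fat_sat)] = read_stack(p)

    ref_key = (reference_contrast, False)
    if ref_key not in structural:
        raise StudyError(f"incomplete study: reference stack {ref_key} missing")
    ref = structural[ref_key]
    structural = {k: _resample_to(s, ref) for k, s in structural.items()}
    if dce is not None:
        frames = [
            _resample_to(ImageStack(np.clip(f, 0, None), dce_spacing), ref).voxels
            for f in dce
        ]
        dce = np.stack(frames).astype(np.float32)
    return MultiParametricStudy(structural, dce=dce, reference_contrast=reference_contrast)


def _resample_to(stack: ImageStack, reference: ImageStack) -> ImageStack:
    """Linearly resample ``stack`` onto the reference grid (shape + spacing)."""
    if stack.shape == reference.shape and stack.spacing == reference.spacing:
        return stack
    from scipy.ndimage import zoom

    # Sample the stack's field of view on the reference grid.
    factors = [rs / ss for rs, ss in zip(reference.shape, stack.shape)]
    out = zoom(stack.voxels, factors, order=1)
    if out.shape != reference.shape:
        raise GeometryMismatchError(
            f"geometry mismatch: cannot resample {stack.shape} onto {reference.shape}"
        )
    return ImageStack(np.clip(out, 0, None), reference.spacing)
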