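"""Landmark-based outer segmentation of the breast from the chest wall.

Per axial slice (anterior at row 0):

1. lateral landmarks P1/P2 (first non-zero pixels scanning each row from the
   lateral edges toward the image mid-column) and the midline point P3
   (first non-zero pixel down the column midway between P1 and P2);
2. the slice is split at P3's row; the lower part is cleaned by fractional
   Otsu thresholding of its non-zero pixels plus erosion/dilation (kernel 7)
   and hole filling, the upper part is kept untouched;
3. P3 is refined to P3' (deepest non-zero pixel on P3's column);
4. corner points P4/P5 mark where breast fat merges into body fat: scanning
   rows from the extreme lateral endpoint downward, the first row whose fat
   width reaches ``fat_width_factor`` (default 1.5) times the baseline width
   ``t``; P4/P5 are located once on the middle slice and reused;
5. a smooth curve through P4, P3', P5 cuts away everything posterior to it;
6. leftover pectoral muscle below the midpoint of P3/P3' is removed by
   another fractional Otsu pass plus opening (kernel 3).

The union of the surviving support over slices is mask1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, binary_fill_holes, binary_opening

from .core import BinaryMask, ImageStack

log = logging.getLogger("breastseg")

Point = tuple[int, int]  # (row, col)


class DegenerateHistogramError(ValueError):
    pass


class NoLandmarksError(ValueError):
    pass


class NoMidlinePointError(NoLandmarksError):
    pass


@dataclass
class SliceLandmarks:
    """Per-slice anatomical points (rows/cols, 0-based)."""

    P1: Point
    P2: Point
    P3: Point
    P3_prime: Point | None = None

    def validate(self) -> None:
        assert self.P1[1] < self.P3[1] < self.P2[1], "landmark ordering violated"
        if self.P3_prime is not None:
            assert self.P3_prime[0] >= self.P3[0]


@dataclass
class LandmarkSet:
    """Per-slice landmarks plus the study-level corner points.

    P4/P5 and the baseline fat width ``t`` come from the middle slice and
    are kept fixed for all slices.
    """

    per_slice: dict[int, SliceLandmarks] = field(default_factory=dict)
    P4: Point | None = None
    P5: Point | None = None
    t: float = 0.0
    middle_slice: int | None = None

    def validate(self) -> None:
        for lm in self.per_slice.values():
            lm.validate()
        if self.P4 is not None and self.P5 is not None:
            mid_cols = [lm.P3[1] for lm in self.per_slice.values()]
            assert self.P4[1] < int(np.median(mid_cols)) < self.P5[1]
            assert self.t > 0


@dataclass
class OuterParams:
    fat_width_factor: float = 1.5
    otsu_fraction: float = 1.0
    lower_morph_kernel: int = 7
    pectoral_open_kernel: int = 3
    pectoral_hard_limit_mm: float | None = None
    tilt_safe: bool = False

    def __post_init__(self) -> None:
        if self.fat_width_factor <= 1.0:
            raise ValueError("fat_width_factor must be > 1")
        if not 0.0 < self.otsu_fraction <= 2.0:
            raise ValueError("otsu_fraction must be in (0, 2]")


# ---------------------------------------------------------------------------
# Fractional Otsu
# ---------------------------------------------------------------------------

def fractional_otsu(values: np.ndarray, fraction: float = 1.0) -> float:
    """``fraction`` x the Otsu threshold of a sample of positive intensities.

    The Otsu threshold is computed exactly on the supplied values (no
    histogram binning): over all splits between consecutive distinct values
    it maximises the between-class variance w0*w1*(mu0-mu1)^2 and returns the
    midpoint of the optimal split (lowest such threshold on ties).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise DegenerateHistogramError("need at least 2 values")
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size < 2:
        raise DegenerateHistogramError("degenerate histogram: constant input")
    w = np.cumsum(counts)[:-1]                   # class-0 sizes per split
    total = values.size
    csum = np.cumsum(uniq * counts)[:-1]         # class-0 sums per split
    mu0 = csum / w
    mu1 = (csum[-1] + uniq[-1] * counts[-1] - csum) / (total - w)
    between = (w / total) * (1 - w / total) * (mu0 - mu1) ** 2
    k = int(np.argmax(between))                  # argmax returns first (lowest) max
    threshold = 0.5 * (uniq[k] + uniq[k + 1])
    return fraction * threshold


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def detect_lateral_landmarks(slice2d: np.ndarray) -> tuple[Point, Point, Point]:
    """P1, P2 (lateral first-nonzero points) and P3 (midline first-nonzero).

    P1: scanning rows top to bottom, each row from the left edge to the image
    mid-column, the first non-zero pixel; P2 mirrored from the right; P3 the
    first non-zero pixel down the column midway between P1 and P2.
    """
    n_rows, n_cols = slice2d.shape
    mid = n_cols // 2
    left = slice2d[:, : mid + 1] > 0
    right = slice2d[:, mid:] > 0
    if not left.any() and not right.any():
        raise NoLandmarksError("no landmarks: empty foreground")
    if not (left.any() and right.any()):
        raise NoLandmarksError("no landmarks: foreground on one side only")
    r1 = int(np.argmax(left.any(axis=1)))
    c1 = int(np.argmax(left[r1]))
    right_flipped = right[:, ::-1]
    r2 = int(np.argmax(right_flipped.any(axis=1)))
    c2 = n_cols - 1 - int(np.argmax(right_flipped[r2]))
    mid_col = (c1 + c2) // 2
    column = slice2d[:, mid_col] > 0
    if not column.any():
        raise NoMidlinePointError("no P3: midline column entirely zero")
    r3 = int(np.argmax(column))
    return (r1, c1), (r2, c2), (r3, mid_col)


def clean_lower_part(slice2d: np.ndarray, P3: Point, params: OuterParams) -> np.ndarray:
    """Fractional-Otsu clean-up of the part of the slice below P3.

    Rows <= P3.row are returned untouched; below, voxels under the threshold
    are zeroed, then the binary support is eroded and dilated (square kernel,
    default 7) and holes are filled; surviving voxels keep their original
    intensity.
    """
    out = slice2d.astype(np.float64, copy=True)
    lower = out[P3[0] + 1 :]
    vals = lower[lower > 0]
    if vals.size == 0:
        return out
    try:
        threshold = fractional_otsu(vals, params.otsu_fraction)
    except DegenerateHistogramError:
        log.warning("lower part has a degenerate histogram; left unchanged")
        return out
    support = lower >= threshold
    k = params.lower_morph_kernel
    footprint = np.ones((k, k), bool)
    support = binary_erosion(support, structure=footprint)
    support = binary_dilation(support, structure=footprint)
    support = binary_fill_holes(support)
    out[P3[0] + 1 :] = lower * support
    return out


def refine_midline(slice2d: np.ndarray, P3: Point) -> Point:
    """P3': the deepest non-zero pixel on P3's column at or below P3."""
    column = slice2d[P3[0] :, P3[1]] > 0
    nz = np.nonzero(column)[0]
    if nz.size == 0:
        return P3
    return (P3[0] + int(nz[-1]), P3[1])


def _row_widths_from_left(binary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per row: column of the first non-zero pixel from the left and the run
    length of contiguous non-zero pixels starting there (0 for empty rows)."""
    n_rows, n_cols = binary.shape
    any_row = binary.any(axis=1)
    first = np.where(any_row, np.argmax(binary, axis=1), -1)
    widths = np.zeros(n_rows, dtype=int)
    for r in np.nonzero(any_row)[0]:
        run = binary[r, first[r] :]
        stop = np.argmin(run) if not run.all() else run.size
        widths[r] = stop
    return first, widths


def first_row_reaching_width(widths: np.ndarray, t: float, factor: float,
                             start: int = 0) -> int | None:
    """Stopping rule for the corner points: first index >= ``start`` whose
    width reaches ``factor * t`` (None if never)."""
    widths = np.asarray(widths)
    for r in range(start, widths.size):
        if widths[r] >= factor * t:
            return r
    return None


def locate_corner_points(
    middle_slice: np.ndarray,
    P1: Point,
    P2: Point,
    params: OuterParams,
    P3: Point | None = None,
) -> tuple[Point, Point, float]:
    """P4, P5 and the baseline fat width t from the (cleaned) middle slice.

    For each side, the fat width w(row) is the run of contiguous non-zero
    pixels inward from the lateral skin boundary.  Scanning starts at the
    extreme lateral endpoint (the lateral-most non-zero pixel of that half,
    where the baseline width t is measured) and moves toward the feet; the
    corner is the first row where w >= fat_width_factor * t — the row at
    which breast fat merges into the much wider body fat.  With
    ``tilt_safe`` (for tilted acquisitions) the vertical screening starts
    from P3 instead of the lateral extreme.
    """
    n_rows, n_cols = middle_slice.shape
    mid = n_cols // 2

    def one_side(binary_full: np.ndarray, flip: bool) -> tuple[Point, float]:
        # the extreme endpoint is searched in this side's half, but the fat
        # run extends across the full row (it may cross the midline once
        # breast fat merges with body fat)
        first, widths = _row_widths_from_left(binary_full)
        half = binary_full[:, :mid]
        half_rows = half.any(axis=1)
        nz_rows = np.nonzero(half_rows & (first < mid))[0]
        if nz_rows.size == 0:
            raise NoLandmarksError("no foreground on this side")
        if params.tilt_safe and P3 is not None:
            extreme_row = P3[0]
            if widths[extreme_row] == 0:
                extreme_row = int(nz_rows[np.argmin(np.abs(nz_rows - P3[0]))])
        else:
            extreme_row = int(nz_rows[np.argmin(first[nz_rows])])  # lateral-most
        t = float(widths[extreme_row])
        row = first_row_reaching_width(widths, t, params.fat_width_factor,
                                       start=extreme_row)
        if row is None:
            row = int(nz_rows[-1])
            warnings.warn("corner criterion never met; using last scanned row",
                          stacklevel=3)
        col_in_scan = int(first[row]) if widths[row] else int(first[extreme_row])
        col = (n_cols - 1 - col_in_scan) if flip else col_in_scan
        return (int(row), col), t

    binary = middle_slice > 0
    p4, t_left = one_side(binary, flip=False)
    p5, t_right = one_side(binary[:, ::-1], flip=True)
    return p4, p5, 0.5 * (t_left + t_right)


# ---------------------------------------------------------------------------
# Cuts
# ---------------------------------------------------------------------------

def cut_below_spline(slice2d: np.ndarray, P4: Point, P3_prime: Point, P5: Point) -> np.ndarray:
    """Zero pixels posterior to the smooth curve through P4, P3', P5.

    The interpolating quadratic through the three points (the minimal smooth
    curve; a straight line when they are collinear) is evaluated over
    columns [P4.col, P5.col]; pixels below it are zeroed.  Outside that
    column range everything below the horizontal lines through P4 / P5 is
    zeroed as well.
    """
    if not (P4[1] < P3_prime[1] < P5[1]):
        raise ValueError("corner/midline column ordering violated")
    out = slice2d.astype(np.float64, copy=True)
    n_rows, n_cols = out.shape
    cols = np.array([P4[1], P3_prime[1], P5[1]], dtype=np.float64)
    rows = np.array([P4[0], P3_prime[0], P5[0]], dtype=np.float64)
    coeffs = np.linalg.solve(np.vander(cols, 3), rows)
    span = np.arange(P4[1], P5[1] + 1)
    curve = np.polyval(coeffs, span)
    rr = np.arange(n_rows)[:, None]
    out[:, P4[1] : P5[1] + 1] *= rr <= curve[None, :]
    out[P4[0] + 1 :, : P4[1]] = 0.0
    out[P5[0] + 1 :, P5[1] + 1 :] = 0.0
    return out


def remove_pectoral(
    slice2d: np.ndarray,
    P3: Point,
    P3_prime: Point,
    params: OuterParams,
    spacing_row_mm: float | None = None,
) -> np.ndarray:
    """Remove leftover pectoral muscle below the midpoint of P3 and P3'.

    In that region, voxels under the fractional Otsu threshold of its
    non-zero values are zeroed, followed by an opening (kernel 3).  With
    ``pectoral_hard_limit_mm`` set, everything deeper than that distance
    below P3' is zeroed regardless (fallback for data without a clear bright
    fat boundary).
    """
    out = slice2d.astype(np.float64, copy=True)
    mid_row = (P3[0] + P3_prime[0]) / 2.0
    start = int(np.floor(mid_row)) + 1
    region = out[start:]
    vals = region[region > 0]
    if vals.size:
        try:
            threshold = fractional_otsu(vals, params.otsu_fraction)
            support = region >= threshold
            k = params.pectoral_open_kernel
            support = binary_opening(support, structure=np.ones((k, k), bool))
            out[start:] = region * support
        except DegenerateHistogramError:
            log.warning("pectoral region has a degenerate histogram; left unchanged")
    if params.pectoral_hard_limit_mm is not None and spacing_row_mm:
        limit_row = P3_prime[0] + int(round(params.pectoral_hard_limit_mm / spacing_row_mm))
        out[limit_row + 1 :] = 0.0
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def outer_segment(
    stack: ImageStack, params: OuterParams | None = None
) -> tuple[BinaryMask, LandmarkSet]:
    """Run the full landmark pipeline on a background-removed structural
    non-fat-sat stack (any of T1-W / T2-W / PD-W) and return mask1.

    Slices on which no landmarks can be found yield empty mask slices with a
    warning; a slice without a midline point falls back to the neighbouring
    slice's P3 column.
    """
    params = params or OuterParams()
    n_slices = stack.shape[0]
    landmarks = LandmarkSet()
    cleaned = np.zeros_like(stack.voxels, dtype=np.float64)

    last_p3: Point | None = None
    for z in range(n_slices):
        slice2d = stack.voxels[z]
        try:
            p1, p2, p3 = detect_lateral_landmarks(slice2d)
        except NoMidlinePointError:
            if last_p3 is None:
                log.warning("slice %d: no midline point and no neighbour fallback", z)
                continue
            column = slice2d[:, last_p3[1]] > 0
            if not column.any():
                log.warning("slice %d: fallback midline column empty", z)
                continue
            p3 = (int(np.argmax(column)), last_p3[1])
            left = slice2d[:, : p3[1]] > 0
            right = slice2d[:, p3[1] + 1 :] > 0
            if not (left.any() and right.any()):
                continue
            r1 = int(np.argmax(left.any(axis=1)))
            p1 = (r1, int(np.argmax(left[r1])))
            rf = right[:, ::-1]
            r2 = int(np.argmax(rf.any(axis=1)))
            p2 = (r2, slice2d.shape[1] - 1 - int(np.argmax(rf[r2])))
        except NoLandmarksError as exc:
            log.warning("slice %d: %s", z, exc)
            continue
        last_p3 = p3
        cleaned[z] = clean_lower_part(slice2d, p3, params)
        p3p = refine_midline(cleaned[z], p3)
        landmarks.per_slice[z] = SliceLandmarks(P1=p1, P2=p2, P3=p3, P3_prime=p3p)
        log.info("slice %d: P1=%s P2=%s P3=%s P3'=%s", z, p1, p2, p3, p3p)

    if not landmarks.per_slice:
        raise NoLandmarksError("no landmarks on any slice")

    processed = sorted(landmarks.per_slice)
    middle = processed[len(processed) // 2]
    landmarks.middle_slice = middle
    lm_mid = landmarks.per_slice[middle]
    p4, p5, t = locate_corner_points(cleaned[middle], lm_mid.P1, lm_mid.P2,
                                     params, P3=lm_mid.P3)
    landmarks.P4, landmarks.P5, landmarks.t = p4, p5, t
    log.info("corner points P4=%s P5=%s t=%.1f from slice %d", p4, p5, t, middle)

    out = np.zeros_like(cleaned)
    for z, lm in landmarks.per_slice.items():
        img = cut_below_spline(cleaned[z], p4, lm.P3_prime, p5)
        img = remove_pectoral(img, lm.P3, lm.P3_prime, params,
                              spacing_row_mm=stack.spacing[1])
        out[z] = img
    mask1 = BinaryMask(out > 0, stack.spacing, name="mask1")
    return mask1, landmarks
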