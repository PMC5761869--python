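# Methods

`breastseg` implements a fully automatic two-stage segmentation of breast
tissue from multi-parametric axial MRI: an **outer** stage that separates
the breast from the chest wall, pectoral muscle and thoracic organs, and an
**inner** stage that decomposes the breast into fatty, fibro-glandular (FG)
and tumor tissue.  The pipeline's end products are tissue volumes, percent
breast density and tumor volume, together with the overlap metrics needed to
score any segmentation against a reference.

## Input model and coordinate frame

A study consists of up to six structural 2-D TSE stacks — T1-, T2- and
PD-weighted, each with and without fat saturation (WWFS; in a two-point
DIXON acquisition the in-phase image serves as the non-fat-sat member and
the water-only reconstruction as the fat-sat member) — plus one 4-D DCE
series with at least 8 time points.  All volumes are held as
`(slice, row, col)` arrays with anterior anatomy at row 0; loaders reorient
NIfTI/DICOM input into this frame.  Only axial acquisitions are supported.
The T2-weighted non-fat-sat stack is the reference for registration and
outer segmentation; when a contrast is missing, any complete WWFS pair is
accepted for the inner stage.

## Pre-processing

1. **Background removal** — voxels below 5% of the maximum of the centre
   slice are zeroed and the per-slice support is opened with a 3×3 kernel.
   The threshold is computed independently per contrast.  "Centre slice" is
   `n_slices // 2` (the tie rule is unstated in the underlying procedure; a
   fixed floor keeps the stage deterministic).
2. **Relevant-slice selection** — the maximal contiguous range of slices
   whose foreground area reaches `min_area_fraction` (default 0.10) times
   the median slice area.  This drops the extreme slices (shoulder /
   diaphragm level) on which no significant breast tissue is visible.
3. **Rigid co-registration** — inter-sequence patient motion in this setting
   is small (< 2 mm) and rigid.  Each member is aligned to the reference by
   maximising Mattes mutual information over a 3-D translation (SimpleITK;
   regular sampling, 20% of voxels, fixed sampling seed), which is robust to
   the fat-sat/non-fat-sat contrast inversion.  The normative contract is
   parameter recovery: simulated shifts below 2 mm are recovered to within
   0.5 voxel (measured: ≈ 0.1 voxel).  Estimates beyond sanity caps (5 mm /
   10°) are discarded as non-converged and the identity is used with a
   warning.  The transform model carries a rotation term for completeness
   but the estimator is translation-only; rotational patient motion is out
   of scope here.  The DCE series is aligned once, via its temporal mean
   frame.

## Outer segmentation (mask1)

Per slice, on the background-removed reference stack:

* **P1, P2** — scanning rows anterior→posterior, each row from the lateral
  edge toward the image mid-column, the first non-zero pixels.  **P3** is
  the first non-zero pixel down the column midway between P1 and P2 (the
  cleavage/sternum line); a slice without a midline point borrows the
  neighbouring slice's P3 column.
* The horizontal line through P3 splits the slice.  The **lower part** is
  cleaned by fractional-Otsu thresholding of its non-zero pixels followed by
  erosion + dilation (square kernel 7) and hole filling; survivors keep
  their original intensity; the upper part is untouched.
* **P3′** — the deepest non-zero pixel on P3's column (sternum depth),
  recomputed per slice.
* **P4, P5** — the corners where breast fat merges into body fat, computed
  once on the middle slice of the relevant range and reused for all slices.
  For each side the fat width w(row) is the contiguous non-zero run inward
  from the lateral skin boundary.  Scanning starts at the extreme lateral
  endpoint (the lateral-most foreground pixel of that half), where the
  baseline width *t* is measured; the corner is the first row with
  w ≥ 1.5 · t.  The factor 1.5 is an empirical anatomical constant
  (configurable `fat_width_factor`).  This rule presumes the breasts extend
  laterally beyond the torso silhouette at breast level, which holds for a
  supine breast-coil acquisition; for tilted studies a `tilt_safe` flag
  starts the screening from P3 instead.
* **Curve cut** — the interpolating quadratic through P4, P3′, P5 (the
  minimal smooth curve through three points; collinear points degenerate to
  a line) is evaluated over [P4.col, P5.col]; everything posterior to it is
  zeroed, as is everything below the horizontal lines through P4/P5 outside
  that column span.
* **Pectoral removal** — in rows below the midpoint of P3 and P3′, another
  fractional-Otsu pass plus 3×3 opening removes leftover muscle.  An
  optional hard depth limit (`pectoral_hard_limit_mm`, disabled by default,
  ~10 mm is a sensible anatomical cap) guards against studies without a
  clear bright fat boundary.

"Fractional Otsu" is `fraction ×` the Otsu threshold (default fraction 1.0)
computed **exactly on the sample values**, not on a binned histogram: over
all splits between consecutive distinct values the between-class variance
w₀w₁(μ₀−μ₁)² is maximised and the midpoint of the optimal split is
returned, lowest split on ties.  This makes the threshold reproducible and
testable against exhaustive search.

## Skin removal

Skin is a thin bright sheet on the breast surface.  A single-scale Hessian
sheetness filter (scale 1.5 mm, γ-normalised Gaussian derivatives in
physical units) scores each voxel by
`sqrt(1 − |λ₂|/|λ₃|)` for λ₃ < 0 — high where one eigenvalue dominates —
multiplied by the voxel brightness relative to the 95th percentile of
intensities over the whole mask.  The brightness term encodes that on
fat-sat images skin (dermis, water) is as bright as the brightest soft
tissue while subcutaneous fat is dark; it suppresses the filter's classic
false response on the bright side of plain step edges, so a breast without
a skin layer loses essentially nothing (< 0.01% of the mask).  Voxels with
score ≥ 0.6 within 2 × scale of the mask boundary are removed from mask1
before any inner segmentation or volume computation (configurable off).
The cited multi-scale sheetness formulation is deliberately reduced to a
single scale: skin thickness varies little and the filter is only a thin
post-filter here.

## Inner segmentation

* **mask2 (fat)** — D = non-fat-sat − fat-sat, negatives clamped (sign has
  no tissue meaning); mask2 = (D ≥ Otsu(D over mask1)) ∩ mask1.
* **mask3 (FG + tumor)** = mask1 ∖ mask2.
* **DI (difference image)** — pre = mean of the first 4 DCE frames; t* =
  frame with maximal spatial mean enhancement over mask1 (a single global
  index; per-voxel maxima are noise-prone); post = mean of the 4-frame
  window t*−1 … t*+2, clamped at the series ends; DI = (post − pre)/(pre +
  ε) clamped at 0.  ε is machine-epsilon scaled by max(pre), so DI is
  exactly invariant to a positive rescaling of the series.
* **mask4 (tumor)** — Otsu of DI over mask1, intersected with mask1, then
  per-slice erosion + dilation with a disc of diameter 9.  If the
  above-threshold class exceeds `max_lesion_fraction` (default 5%) of the
  breast, the "lesion" is diffuse background parenchymal enhancement rather
  than a focal tumor and mask4 is returned empty with a warning — this is
  what happens for patients without tumor, where the DI histogram otherwise
  splits parenchyma from fat.  Only contrast-enhancing tumors are
  detectable by construction.
* **mask5 (FG)** = mask3 ∖ mask4; labels 1/2/3 = fat/FG/tumor with
  precedence tumor > fat > FG where morphology creates overlaps.

## Volumes, density, metrics

Volume = voxel count × dz·dy·dx / 1000 (cm³).  Breast density =
100 × FG volume / total breast volume, with tumor excluded from FG.
Left/right splits cut at the study-level midline column (P3 of the middle
slice); patient right is image left.  Agreement between left and right
density is summarised as the Bland–Altman pair [(L+R)/2, L−R] and the
Pearson correlation.  Overlap metrics between a manual mask A and an
automatic mask B: Dice 2|A∩B|/(|A|+|B|), Jaccard |A∩B|/|A∪B| (=
Dice/(2−Dice)), sensitivity |A∩B|/|B|.  A `slice_stride` option (3)
mirrors scoring against manual masks drawn on every third slice; phantom
work uses every slice (stride 1).

## The synthetic phantom

Patient data cannot ship with the package, so every stage is validated on a
generated phantom with exact ground truth: two clipped-ellipsoid breasts
(wider than the torso, as in a breast-coil acquisition) attached to a torso
block with a 7-px subcutaneous fat layer, a pectoral band and dim interior
organs running off the posterior field of view; a connected FG ellipsoid
inside each breast sized to the target density; a one-voxel bright skin
shell; an optional enhancing tumor; Gaussian noise; sub-2-mm rigid shifts
applied to every non-reference sequence; optional in-plane tilt evaluated
analytically (masks stay exact).  The torso cross-section collapses to
< 10% of its full area outside the breast extent so the area-based slice
rule excludes the extreme slices, emulating their appearance at shoulder /
diaphragm level.

Defaults: 64×128×128 voxels at (3.0, 1.2, 1.2) mm — a deliberately
scaled-down grid whose total breast volume (~470 cm³) and FG density (10%,
the cohort scale of the study the method targets, which spans roughly
2–27% with mean 8.6%) sit inside the clinically observed ranges; tumor
radius 8 mm; fat retains 10% of its signal under fat saturation; noise σ =
2% of the fat signal (fat/FG contrast ≥ 5σ, guarded at construction so
Otsu separability is a property of the conditions, not luck); tumor peak
enhancement 2.0 relative to baseline with non-tumor tissue enhancing 15% as
strongly; 40 DCE time points with bolus arrival around frame 6 and plateau
by frame 12.  Structural tissue means (fat 1000, FG 400, pectoral 380,
organs 350, tumor 420, skin 800/500 without/with fat-sat, arbitrary units)
mimic the T2-W TSE ordering the algorithm relies on; they are modelling
choices, not measured values.

What the phantom does **not** emulate — and hence what passing tests do not
show about patient data: B1/bias-field inhomogeneity, partial-volume mixing
beyond linear interpolation at shifted edges, non-rigid motion, thin or
fragmented FG architecture, imperfect fat saturation, saturation bands, and
anatomical variability of the chest wall.  Dice thresholds used in the
tests (0.95 outer / 0.95 fat / 0.85 FG / 0.90 tumor) are artifact
acceptance levels for this phantom, deliberately below the agreement the
method achieves against radiologists on patient data.

## Numerical and degenerate-input choices

* Otsu ties → lowest threshold; constant samples raise a degenerate-
  histogram error (callers leave the region unchanged, or report
  fat/FG non-separability, or return an empty tumor mask, as appropriate).
* A slice with no foreground yields an empty mask slice with a warning; a
  missing midline column falls back to the neighbouring slice's P3.
* The corner criterion never firing places P4/P5 at the last scanned row
  with a warning.
* DCE windows are clamped at the series ends (symmetric-preferred
  t*−1 … t*+2); a maximal enhancement inside the pre-contrast window logs a
  no-enhancement warning but still returns DI.
* Studies without DCE run in degraded mode: no tumor mask, mask5 = mask3.
* All stages are deterministic; identical input and configuration reproduce
  bit-identical masks.

## Known limitations

Axial orientation only; translation-only motion model; single-scale skin
filter; tumor detection requires contrast enhancement and a focal lesion
(< `max_lesion_fraction` of the breast); density is voxel-count based with
no partial-volume fat-fraction correction; the corner rule assumes breasts
wider than the torso silhouette at breast level (use `tilt_safe` otherwise).
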