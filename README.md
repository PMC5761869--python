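# breastseg

Automatic outer and inner breast tissue segmentation from multi-parametric
MRI, with breast-density and tumor-volume quantification and a synthetic
phantom for validation.

Breast MRI volumes include the chest wall, pectoral muscle and thoracic
organs; quantitative work — breast-density estimation, neoadjuvant-therapy
follow-up, tumor volumetry — first needs the breast separated from the rest
of the body (*outer segmentation*) and then decomposed into fatty,
fibro-glandular (FG) and tumor tissue (*inner segmentation*).  Manual
delineation is slow and subjective; `breastseg` automates both stages for
researchers working with standard clinical protocols (T1-/T2-/PD-weighted
turbo-spin-echo stacks acquired with and without fat saturation, plus a
dynamic contrast-enhanced series).

## Method in brief

* **Outer stage** — anatomical landmarks found by intensity-profile
  screening on each axial slice: lateral skin points P1/P2, midline point
  P3 and its posterior refinement P3′, and the corners P4/P5 where breast
  fat merges into body fat (fat width exceeding 1.5× its baseline).  A
  smooth curve through P4–P3′–P5 cuts the breast (mask1) away from the
  chest wall; fractional Otsu thresholding plus mathematical morphology
  removes organs and leftover pectoral muscle.  Thin bright skin is removed
  with a Hessian sheetness filter.
* **Inner stage** — mask algebra on co-registered images:
  fat `mask2 = Otsu(nofatsat − fatsat) ∩ mask1`;
  tumor `mask4 = Otsu(DI) ∩ mask1` with the DCE difference image
  `DI = (post − pre)/pre`; FG `mask5 = (mask1 ∖ mask2) ∖ mask4`.
* **Quantification** — volumes in cm³, breast density
  `BD = 100 · V_FG / V_breast` (tumor excluded), left/right splits with
  Bland–Altman agreement `[(L+R)/2, L−R]`, and the overlap metrics
  Dice `d = 2|A∩B|/(|A|+|B|)`, Jaccard `p = |A∩B|/|A∪B| = d/(2−d)` and
  sensitivity `s = |A∩B|/|B|` for scoring against reference masks.

Because patient images cannot ship with the code, the package includes a
first-class phantom generator (`breastseg.phantom`) producing
multi-parametric studies with exact ground-truth masks — breasts on a chest
wall with pectoral muscle and organs, bright/suppressed fat, skin, an
enhancing tumor, noise and sub-2-mm inter-sequence motion — so the whole
pipeline is testable offline.  See `docs/methods.md` for the full model,
parameter defaults and limitations.

## Worked example

```python
from breastseg import (PhantomConfig, generate_phantom,
                       PipelineConfig, segment_study, bland_altman)

study, truth = generate_phantom(PhantomConfig(seed=7))   # synthetic study
result = segment_study(study, PipelineConfig())          # full pipeline

r = result.report
print(f"breast volume {r.total_cm3:.2f} cm3  (truth {truth.volumes_cm3['breast_tissue']:.2f} cm3)")
print(f"FG volume     {r.fg_cm3:.2f} cm3   (truth {truth.volumes_cm3['fg']:.2f} cm3)")
print(f"tumor volume  {r.tumor_cm3:.2f} cm3    (truth {truth.volumes_cm3['tumor']:.2f} cm3)")
print(f"breast density {r.density_pct:.2f} %  (truth {truth.density_pct:.2f} %)")
mean, diff = bland_altman(r.left_density_pct, r.right_density_pct)
print(f"L/R density {r.left_density_pct:.2f} / {r.right_density_pct:.2f} %  (Bland-Altman {mean:.2f}, {diff:+.2f})")
```

prints

```
breast volume 503.03 cm3  (truth 473.64 cm3)
FG volume     52.74 cm3   (truth 50.91 cm3)
tumor volume  1.92 cm3    (truth 2.20 cm3)
breast density 10.49 %  (truth 10.75 %)
L/R density 10.43 / 10.54 %  (Bland-Altman 10.49, -0.12)
```

The segmented breast volume slightly exceeds the true tissue volume (the
anterior chest-wall fat right at the P4/P5 level is anatomically ambiguous
and retained), while density — a ratio — lands within ~0.3 percentage
points of the truth.  `result` also carries all five masks, the combined
fat/FG/tumor label map, the per-slice landmarks and the recovered rigid
transforms.

The same pipeline runs from the shell on NIfTI or DICOM studies:

```bash
breastseg phantom --out study/ --seed 7          # or your own data
breastseg run --config config.yaml
breastseg outer --study study/ --out mask1.nii.gz
breastseg report --labels out/labels.nii.gz --out report.csv
```

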