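"""End-to-end orchestration: configuration, the study-level pipeline and the
artifact-writing entry point used by the command line."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np

from . import core, inner, metrics, outer, preprocess
from .core import BinaryMask, ImageStack, MultiParametricStudy
from .inner import InnerParams
from .outer import LandmarkSet, OuterParams

log = logging.getLogger("breastseg")


@dataclass
class BackgroundConfig:
    threshold_fraction: float = preprocess.BACKGROUND_THRESHOLD_FRACTION
    open_kernel: int = preprocess.BACKGROUND_OPEN_KERNEL


@dataclass
class SlicesConfig:
    min_area_fraction: float = preprocess.MIN_AREA_FRACTION


@dataclass
class RegistrationConfig:
    enabled: bool = True
    sampling_fraction: float = 0.2


@dataclass
class MetricsConfig:
    slice_stride: int = 1


@dataclass
class PipelineConfig:
    """All module parameter blocks plus reproducibility plumbing.

    Round-trips through YAML unchanged; unknown keys are rejected so a typo
    in a config file fails loudly instead of silently using a default.
    """

    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    slices: SlicesConfig = field(default_factory=SlicesConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    outer: OuterParams = field(default_factory=OuterParams)
    inner: InnerParams = field(default_factory=InnerParams)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    reference_contrast: str = "T2W"
    seed: int = 0
    output_dir: str = "breastseg_out"
    verbosity: str = "INFO"
    study_paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        blocks = {f.name: f for f in fields(cls)}
        unknown = set(data) - set(blocks)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, value in data.items():
            if isinstance(value, dict) and name != "study_paths":
                sub_cls = type(blocks[name].default_factory())  # type: ignore[misc]
                sub_fields = {sf.name for sf in fields(sub_cls)}
                bad = set(value) - sub_fields
                if bad:
                    raise ValueError(f"unknown config keys in {name!r}: {sorted(bad)}")
                kwargs[name] = sub_cls(**value)
            else:
                kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All artifacts of one study run, on the relevant-slice grid."""

    mask1_raw: BinaryMask           # outer mask before skin removal
    mask1: BinaryMask               # after skin removal
    mask2: BinaryMask
    mask3: BinaryMask
    mask4: BinaryMask
    mask5: BinaryMask
    labels: core.LabelMap
    landmarks: LandmarkSet
    slice_range: tuple[int, int]
    report: metrics.TissueReport
    transforms: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def segment_study(study: MultiParametricStudy, config: PipelineConfig | None = None) -> PipelineResult:
    """Run outer + inner segmentation and reporting on an in-memory study.

    Deterministic: identical input and config reproduce identical outputs.
    Without a DCE member the pipeline runs in degraded mode (no tumor mask;
    mask5 = mask3).
    """
    config = config or PipelineConfig()
    notes: list[str] = []

    # 1. background removal, independently per contrast
    bg = {
        key: preprocess.remove_background(
            stack, config.background.threshold_fraction, config.background.open_kernel
        )
        for key, stack in study.structural.items()
    }
    ref_key = (config.reference_contrast, False)
    if ref_key not in bg:
        ref_key = (study.wwfs_pairs()[0], False)
    reference = bg[ref_key]

    # 2. relevant slices from the reference contrast
    slice_range = preprocess.select_relevant_slices(
        reference, config.slices.min_area_fraction
    )
    log.info("relevant slices: %s", slice_range)
    bg = {k: preprocess.crop_slices(s, slice_range) for k, s in bg.items()}
    reference = bg[ref_key]
    dce = None
    if study.dce is not None:
        dce = study.dce[:, slice_range[0] : slice_range[1] + 1]

    # 3. rigid co-registration of every member to the reference contrast
    transforms = {}
    if config.registration.enabled:
        for key in list(bg):
            if key == ref_key:
                continue
            aligned, tr = preprocess.coregister_rigid(
                bg[key], reference,
                sampling_fraction=config.registration.sampling_fraction,
                seed=config.seed + 12345,
            )
            bg[key] = aligned
            transforms[f"{key[0]}{'_fs' if key[1] else ''}"] = tr
        if dce is not None:
            mean_frame = ImageStack(dce.mean(axis=0, dtype=np.float64), study.spacing)
            _, tr = preprocess.coregister_rigid(
                mean_frame, reference,
                sampling_fraction=config.registration.sampling_fraction,
                seed=config.seed + 54321,
            )
            transforms["dce"] = tr
            if tr.converged and any(tr.translation_mm):
                dce = np.stack([
                    preprocess.apply_translation(f.astype(np.float64),
                                                 tr.translation_mm, study.spacing)
                    for f in dce
                ])

    # 4. outer segmentation on the reference non-fat-sat stack
    mask1_raw, landmarks = outer.outer_segment(reference, config.outer)

    # 5. skin removal (fat-sat member: dermis conspicuous there)
    fatsat_key = (ref_key[0], True)
    if config.inner.skin_removal_enabled and fatsat_key in bg:
        mask1 = inner.remove_skin(bg[fatsat_key], mask1_raw, config.inner)
    else:
        mask1 = BinaryMask(mask1_raw.voxels.copy(), mask1_raw.spacing, name="mask1")

    # 6. inner segmentation
    pair_contrast = ref_key[0] if ref_key[0] in study.wwfs_pairs() else study.wwfs_pairs()[0]
    mask2 = inner.fat_mask(bg[(pair_contrast, False)], bg[(pair_contrast, True)], mask1)
    if dce is not None:
        di = inner.difference_image(dce, config.inner, mask1, study.spacing)
        mask4 = inner.tumor_mask(di, mask1, config.inner)
    else:
        notes.append("no DCE series: tumor stage skipped (degraded mode)")
        log.warning(notes[-1])
        mask4 = BinaryMask(np.zeros(mask1.shape, bool), mask1.spacing, name="mask4")
    mask3, mask5 = inner.fg_mask(mask1, mask2, mask4)
    labels = inner.combine_labels(mask2, mask5, mask4)

    # 7. volumes, density, left/right split at the study-level midline
    mid_lm = landmarks.per_slice[landmarks.middle_slice]
    report = metrics.tissue_report(mask1, mask5, mask4, midline_col=mid_lm.P3[1])

    return PipelineResult(
        mask1_raw=mask1_raw, mask1=mask1, mask2=mask2, mask3=mask3,
        mask4=mask4, mask5=mask5, labels=labels, landmarks=landmarks,
        slice_range=slice_range, report=report, transforms=transforms,
        warnings=notes,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Load a study from ``config.study_paths``, segment it and write all
    artifacts plus a manifest into ``config.output_dir``.

    Returns the manifest.  Any stage error propagates with the stage name in
    the message (the CLI maps it to a nonzero exit status).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        study = core.load_study(config.study_paths, config.reference_contrast)
    except Exception as exc:
        raise RuntimeError(f"load_study: {exc}") from exc
    try:
        result = segment_study(study, config)
    except Exception as exc:
        raise RuntimeError(f"segment_study: {exc}") from exc

    artifacts: dict[str, str] = {}
    for name in ("mask1", "mask2", "mask3", "mask4", "mask5"):
        path = out_dir / f"{name}.nii.gz"
        core.write_mask(getattr(result, name), path)
        artifacts[name] = str(path)
    labels_path = out_dir / "labels.nii.gz"
    core.write_labels(result.labels, labels_path)
    artifacts["labels"] = str(labels_path)

    lm_path = out_dir / "landmarks.json"
    lm_payload = {
        "per_slice": {
            str(z): {"P1": lm.P1, "P2": lm.P2, "P3": lm.P3, "P3_prime": lm.P3_prime}
            for z, lm in result.landmarks.per_slice.items()
        },
        "P4": result.landmarks.P4,
        "P5": result.landmarks.P5,
        "t": result.landmarks.t,
        "middle_slice": result.landmarks.middle_slice,
        "slice_range": result.slice_range,
    }
    lm_path.write_text(json.dumps(lm_payload, indent=2))
    artifacts["landmarks"] = str(lm_path)

    import pandas as pd

    report_path = out_dir / "report.csv"
    pd.DataFrame([result.report.as_row()]).to_csv(report_path, index=False)
    artifacts["report"] = str(report_path)

    manifest = {
        "config_hash": config.config_hash(),
        "artifacts": artifacts,
        "slice_range": list(result.slice_range),
        "transforms": {
            k: {"translation_mm": list(t.translation_mm), "converged": t.converged}
            for k, t in result.transforms.items()
        },
        "warnings": result.warnings,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
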