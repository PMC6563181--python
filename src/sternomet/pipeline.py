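"""End-to-end measurement pipeline: directory of images -> tables.

Each image carries one bone (filename convention ``<subject>_<bone>.<ext>``).
Per image: segment -> landmarks -> measure; per subject with both bones:
indices and sex classification by the configured discriminant functions.
Failures are isolated per image and logged; the batch continues.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as sio
from .osteometry import (PIPELINE_LANDMARK_PARAMS, LandmarkParams,
                         MeasurementError, MeasurementRecord, compute_indices,
                         measure_image)
from .segmentation import SegmentationError, SegmentationParams
from .sex_estimation import builtin_functions, classify_sex

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".tif", ".tiff", ".png", ".dcm", ".dicom")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end run.

    seg_params : segmentation parameters (e.g. from training).
    landmark_params : landmark-detection parameters.
    spacing : cm/px override for images without spacing metadata.
    functions : names of built-in discriminant functions to apply
        (None = all nine).
    tie_policy : classification label when a score equals the sectioning
        point ("male" | "female" | "indeterminate").
    """

    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    landmark_params: LandmarkParams = PIPELINE_LANDMARK_PARAMS
    spacing: Optional[float] = None
    functions: Optional[Sequence[str]] = None
    tie_policy: str = "indeterminate"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.spacing is not None and not self.spacing > 0:
            raise ValueError("spacing override must be > 0")
        if self.tie_policy not in ("male", "female", "indeterminate"):
            raise ValueError(f"invalid tie policy {self.tie_policy!r}")


def run_pipeline(image_dir: Path | str, config: PipelineConfig | None = None,
                 out_dir: Path | str | None = None):
    """Process every bone image in a directory.

    Returns (measurements DataFrame, classification DataFrame, log lines).
    When ``out_dir`` is given, writes measurements.csv, classifications.csv
    and run.log there.  Raises :class:`PipelineError` when no image succeeds.
    """
    config = config or PipelineConfig()
    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.iterdir()
                   if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise PipelineError(f"no readable images in {image_dir}")

    log_lines: list[str] = []

    def log(stage, name, msg, t0=None):
        wall = f" ({time.perf_counter() - t0:.2f}s)" if t0 is not None else ""
        line = f"{stage}\t{name}\t{msg}{wall}"
        log_lines.append(line)
        logger.info(line)

    records: list[MeasurementRecord] = []
    per_subject: dict[str, dict] = {}
    failures = 0
    for path in paths:
        t0 = time.perf_counter()
        try:
            image = sio.read_bone_image(path, spacing=config.spacing)
            rec = measure_image(image, config.seg_params,
                                config.landmark_params,
                                subject_id=sio.infer_bone_kind(path)[0])
            records.append(rec)
            subject = rec.subject_id
            per_subject.setdefault(subject, {}).update(rec.values())
            log("measure", path.name, f"ok {rec.values()}", t0)
        except (SegmentationError, MeasurementError, ValueError) as e:
            failures += 1
            log("measure", path.name, f"FAILED: {e}", t0)
    if not records:
        raise PipelineError(
            f"no image processed successfully ({failures} failures)")

    # merge per-subject rows (manubrium + corpus) and compute indices
    merged_records: list[MeasurementRecord] = []
    indices = {}
    for subject, vals in sorted(per_subject.items()):
        rec = MeasurementRecord(subject_id=subject, source="automatic", **vals)
        merged_records.append(rec)
        if len(vals) == 5:
            indices[subject] = compute_indices(rec)

    measurements = sio.measurement_frame(merged_records, indices)

    funcs = builtin_functions()
    if config.functions is not None:
        wanted = set(config.functions)
        funcs = [f for f in funcs if f.name in wanted]
    cls_rows = []
    for subject, idx in indices.items():
        vals = dict(per_subject[subject])
        vals.update({"SI": idx.SI, "SA": idx.SA, "CL": idx.CL})
        row = {"subject_id": subject}
        for f in funcs:
            try:
                row[f.name] = classify_sex(f, vals, tie_policy=config.tie_policy)
            except ValueError:
                row[f.name] = ""
        cls_rows.append(row)
    classifications = pd.DataFrame(
        cls_rows, columns=["subject_id"] + [f.name for f in funcs])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        measurements.to_csv(out_dir / "measurements.csv", index=False,
                            float_format="%.8g")
        classifications.to_csv(out_dir / "classifications.csv", index=False)
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return measurements, classifications, log_lines
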