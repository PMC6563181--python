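"""Ground-truth validation experiments for the automatic pipeline.

Two reproducible experiments quantify the pipeline on synthetic phantoms
whose true measurements are known exactly:

* :func:`measurement_recovery_experiment` — a batch of corrupted phantoms is
  measured end to end (segment -> landmarks -> measure) and the per-measure
  percentage discrepancy against ground truth is computed with the agreement
  module, the phantom truth standing in for the manual reference.
* :func:`training_experiment` — the segmentation-parameter training loop is
  run on a batch of corrupted phantoms of one bone and its achieved
  efficiency reported.

Both draw their subject measurements from the default population model and
use the default corruption level, so they characterize the pipeline under
the package's reference study conditions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import agreement_summary
from .osteometry import (PIPELINE_LANDMARK_PARAMS, MeasurementError,
                         TrainingResult, measure_image, tune_parameters)
from .phantom import (CORPUS_MEASUREMENTS, DEFAULT_SPACING,
                      MANUBRIUM_MEASUREMENTS, CorruptionSpec, PopulationSpec,
                      corrupt_image, render_phantom, sample_ground_truth)
from .segmentation import SegmentationError, SegmentationParams

__all__ = ["RecoveryResult", "measurement_recovery_experiment",
           "training_experiment", "phantom_batch"]


@dataclass
class RecoveryResult:
    """Outcome of a measurement-recovery experiment."""

    discrepancy_pct: dict          # measure -> percentage discrepancy
    mean_distance_cm: dict         # measure -> mean |difference| (cm)
    n_images: int
    n_failed: int

    @property
    def max_discrepancy_pct(self) -> float:
        return max(self.discrepancy_pct.values())


def phantom_batch(seed: int, n_per_bone: int = 63,
                  spacing: float = DEFAULT_SPACING,
                  corruption: CorruptionSpec | None = None,
                  kinds: tuple = ("corpus", "manubrium")):
    """Yield (image, truth) phantoms drawn from the default population.

    ``n_per_bone`` phantoms are generated per bone kind; subjects are a
    seeded shuffle of the default population sample, so both sexes are
    represented in every batch.
    """
    rng = np.random.default_rng(seed)
    spec = PopulationSpec(seed=int(rng.integers(2**31)))
    table = sample_ground_truth(spec)
    table = table.sample(frac=1.0, random_state=int(rng.integers(2**31))
                         ).reset_index(drop=True)
    for kind in kinds:
        names = CORPUS_MEASUREMENTS if kind == "corpus" else MANUBRIUM_MEASUREMENTS
        for i in range(n_per_bone):
            row = table.iloc[i % len(table)]
            lengths = {k: float(row[k]) for k in names}
            render_seed = int(rng.integers(2**31))
            image, truth = render_phantom(lengths, spacing, kind,
                                          seed=render_seed)
            if corruption is None:
                corruption_i = CorruptionSpec(seed=render_seed)
            else:
                corruption_i = CorruptionSpec(
                    **{**corruption.__dict__, "seed": render_seed})
            image = corrupt_image(image, truth, corruption_i)
            image.ident = f"{row.subject_id}-{kind}-{i:03d}"
            yield image, truth


def measurement_recovery_experiment(
        seed: int, n_per_bone: int = 63,
        seg_params: SegmentationParams | None = None,
        corruption: CorruptionSpec | None = None) -> RecoveryResult:
    """Measure a corrupted phantom batch and compare against ground truth.

    Discrepancy per measure = 100 x mean |truth - automatic| / mean
    automatic value, computed by the agreement module with the phantom truth
    as the reference table.
    """
    truth_rows, auto_rows = [], []
    n_failed = n_images = 0
    for image, truth in phantom_batch(seed, n_per_bone, corruption=corruption):
        n_images += 1
        try:
            rec = measure_image(image, seg_params, PIPELINE_LANDMARK_PARAMS,
                                subject_id=image.ident)
        except (SegmentationError, MeasurementError):
            n_failed += 1
            continue
        truth_rows.append({"subject_id": image.ident, **truth.lengths})
        auto_rows.append({"subject_id": image.ident, **rec.values()})
    truth_df = pd.DataFrame(truth_rows)
    auto_df = pd.DataFrame(auto_rows)
    discrepancy, distance = {}, {}
    for measure in ("M", "MW", "B", "CSW1", "CSW2"):
        entry = agreement_summary(truth_df, auto_df, measure)
        discrepancy[measure] = entry.discrepancy_pct
        distance[measure] = entry.mean_distance
    return RecoveryResult(discrepancy_pct=discrepancy,
                          mean_distance_cm=distance,
                          n_images=n_images, n_failed=n_failed)


def training_experiment(seed: int, n_images: int = 35, kind: str = "corpus",
                        tolerance: float = 0.05,
                        grid=None) -> TrainingResult:
    """Run the parameter-training loop on corrupted phantoms of one bone."""
    training = list(phantom_batch(seed, n_images, kinds=(kind,)))
    return tune_parameters(training, grid, tolerance)
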