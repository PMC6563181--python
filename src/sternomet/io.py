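"""File formats: bone images (TIFF/PNG/DICOM), contours, measurement tables.

Pixel spacing is carried in cm/pixel everywhere.  DICOM files provide it via
the standard pixel-spacing attribute (mm, converted to cm); TIFF/PNG need an
explicit spacing from the caller or pipeline configuration.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .osteometry import IndexRecord, MeasurementRecord
from .phantom import PhantomTruth
from .segmentation import BoneImage, Contour

__all__ = [
    "read_bone_image",
    "write_phantom",
    "read_truth",
    "write_contour_json",
    "read_contour_json",
    "write_overlay_png",
    "write_measurement_table",
    "read_measurement_table",
    "infer_bone_kind",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = ["subject_id", "source", "M", "MW", "B", "CSW1", "CSW2",
                       "SI", "SA", "CL"]

#: filename convention `<subject>_<bone>.<ext>` used by the pipeline
_KIND_PATTERN = re.compile(r"(?P<id>.+)_(?P<kind>manubrium|corpus)$", re.IGNORECASE)


def infer_bone_kind(path: Path | str) -> tuple[str, str]:
    """(subject id, bone kind) from a `<id>_<bone>.<ext>` filename."""
    stem = Path(path).stem
    m = _KIND_PATTERN.match(stem)
    if not m:
        return stem, "unknown"
    return m.group("id"), m.group("kind").lower()


def read_bone_image(path: Path | str, spacing: Optional[float] = None,
                    kind: Optional[str] = None) -> BoneImage:
    """Read a TIFF/PNG/DICOM bone image.

    ``spacing`` (cm/px) overrides any file metadata; DICOM pixel spacing
    (mm) is converted to cm.  Raises when no spacing is available anywhere.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    ident, inferred = infer_bone_kind(path)
    kind = kind or inferred

    if suffix in (".dcm", ".dicom"):
        import pydicom
        ds = pydicom.dcmread(str(path))
        pixels = ds.pixel_array.astype(float)
        if spacing is None:
            ps = getattr(ds, "PixelSpacing", None)
            if ps is None:
                raise ValueError(
                    f"{path}: DICOM has no pixel spacing; pass an explicit "
                    f"spacing override (cm/px)")
            spacing = float(ps[0]) / 10.0  # mm -> cm
    elif suffix in (".tif", ".tiff"):
        import tifffile
        pixels = tifffile.imread(str(path)).astype(float)
    elif suffix == ".png":
        import imageio.v3 as iio
        pixels = np.asarray(iio.imread(str(path))).astype(float)
        if pixels.ndim == 3:
            pixels = pixels.mean(axis=2)
    else:
        raise ValueError(f"unsupported image format {suffix!r} ({path})")

    if spacing is None:
        raise ValueError(
            f"{path}: no pixel spacing available; set the spacing override "
            f"(cm/px) in the configuration")
    return BoneImage(pixels=pixels, spacing=spacing, kind=kind, ident=ident)


def write_phantom(image: BoneImage, truth: PhantomTruth, path: Path | str) -> Path:
    """Write a phantom as 16-bit TIFF plus a `.truth.json` sidecar."""
    import tifffile
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.clip(image.pixels, 0, 65535).astype(np.uint16))
    sidecar = path.with_suffix("").with_suffix(".truth.json") \
        if path.suffix else path.with_suffix(".truth.json")
    sidecar = path.parent / (path.stem + ".truth.json")
    sidecar.write_text(truth.to_json())
    return sidecar


def read_truth(path: Path | str) -> PhantomTruth:
    return PhantomTruth.from_json(Path(path).read_text())


def write_contour_json(contour: Contour, path: Path | str) -> None:
    d = {
        "points": np.asarray(contour.points).tolist(),
        "centroid": list(contour.centroid),
        "area": contour.area,
        "perimeter": contour.perimeter,
        "mean_interior_intensity": contour.mean_interior_intensity,
        "elongation": contour.elongation,
        "solidity": contour.solidity,
        "accepted": contour.accepted,
    }
    Path(path).write_text(json.dumps(d))


def read_contour_json(path: Path | str) -> Contour:
    d = json.loads(Path(path).read_text())
    return Contour(points=np.asarray(d["points"]), centroid=tuple(d["centroid"]),
                   area=d["area"], perimeter=d["perimeter"],
                   mean_interior_intensity=d["mean_interior_intensity"],
                   elongation=d["elongation"], solidity=d["solidity"],
                   accepted=d["accepted"])


def write_overlay_png(image: BoneImage, contour: Contour, path: Path | str) -> None:
    """Diagnostic overlay: image with the contour and its centroid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image.pixels, cmap="gray")
    pts = np.asarray(contour.points)
    ax.plot(pts[:, 0], pts[:, 1], color="yellow", lw=1.0)
    ax.plot(*contour.centroid, marker="o", color="magenta", ms=4)
    ax.set_axis_off()
    fig.savefig(str(path), bbox_inches="tight", dpi=150)
    plt.close(fig)


def write_measurement_table(records, path: Path | str,
                            indices: Optional[dict] = None) -> None:
    """Write MeasurementRecords (plus optional per-subject indices) as CSV.

    ``indices`` maps subject_id -> IndexRecord.  Missing values are empty
    cells; numbers are serialized with 8 significant digits.
    """
    rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id, "source": rec.source}
        row.update({k: getattr(rec, k) for k in ("M", "MW", "B", "CSW1", "CSW2")})
        idx = (indices or {}).get(rec.subject_id)
        if idx is not None:
            row.update({"SI": idx.SI, "SA": idx.SA, "CL": idx.CL})
        rows.append(row)
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.8g")


def read_measurement_table(path: Path | str) -> list[MeasurementRecord]:
    """Read a measurement CSV back into records, validating invariants."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing_cols = [c for c in ("subject_id", "source") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    records = []
    for i, row in df.iterrows():
        vals = {}
        for m in ("M", "MW", "B", "CSW1", "CSW2"):
            v = row.get(m)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            vals[m] = float(v)
        try:
            records.append(MeasurementRecord(
                subject_id=str(row["subject_id"]), source=str(row["source"]),
                **vals))
        except ValueError as e:
            # +2: header line and 1-based numbering
            raise ValueError(f"{path}, line {i + 2}: {e}") from e
    return records


def measurement_frame(records, indices: Optional[dict] = None) -> pd.DataFrame:
    """Records (plus optional indices) as a DataFrame with the CSV schema."""
    rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id, "source": rec.source,
               **{k: getattr(rec, k) for k in ("M", "MW", "B", "CSW1", "CSW2")}}
        idx = (indices or {}).get(rec.subject_id)
        if idx is not None:
            row.update({"SI": idx.SI, "SA": idx.SA, "CL": idx.CL})
        rows.append(row)
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
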