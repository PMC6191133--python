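"""File I/O: images, annotation JSON, detection/result CSV, config.

Formats
-------
* Images: 8-bit RGB PNG or JPEG (greyscale and RGBA inputs are
  promoted/stripped to RGB on read).
* Annotations: one JSON document per photo —
  ``{"photo_id": ..., "inner_corners": [[x, y] * 4],
  "regions": [{"label": ..., "polygon": [[x, y], ...]}, ...]}``
  with 0-based pixel coordinates.
* Detections and results: RFC-4180 CSV (UTF-8, header row).
* Config: plain ``KEY = value`` text; ``#`` starts a comment.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detection import CellDetectionSet, DetectionParams
from .errors import InvalidAnnotationError, InvalidImageError
from .quantify import FrameAnnotation, FrameMeasurement
from .stats import MassConstants

__all__ = [
    "read_image",
    "write_image",
    "read_annotation",
    "write_annotation",
    "detections_to_frame",
    "write_detections_csv",
    "read_detections_csv",
    "measurement_to_row",
    "RESULT_COLUMNS",
    "parse_config",
    "detection_params_from_config",
    "mass_constants_from_config",
]

DETECTION_COLUMNS = ["photo_id", "x", "y", "detected_radius", "accumulator_threshold_used"]

RESULT_COLUMNS = [
    "photo_id",
    "inner_area_px2",
    "inner_area_cm2",
    "capped_brood_gross_px2",
    "capped_brood_n_uncapped",
    "capped_brood_subtracted_px2",
    "capped_brood_px2",
    "capped_brood_cm2",
    "capped_brood_fraction",
    "capped_honey_gross_px2",
    "capped_honey_n_uncapped",
    "capped_honey_subtracted_px2",
    "capped_honey_px2",
    "capped_honey_cm2",
    "capped_honey_fraction",
    "error",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG photograph as an (H, W, 3) uint8 RGB array."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.repeat(arr[..., None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise InvalidImageError(f"{path}: unsupported raster shape {arr.shape}")
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_annotation(path: str | Path) -> FrameAnnotation:
    """Load one per-photo annotation JSON document."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InvalidAnnotationError(f"{path}: malformed JSON ({exc})") from exc
    try:
        return FrameAnnotation(
            photo_id=str(doc["photo_id"]),
            inner_corners=tuple(tuple(map(float, p)) for p in doc["inner_corners"]),
            regions=tuple(
                (str(r["label"]), tuple(tuple(map(float, p)) for p in r["polygon"]))
                for r in doc.get("regions", [])
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise InvalidAnnotationError(f"{path}: bad annotation schema ({exc})") from exc


def write_annotation(path: str | Path, annotation: FrameAnnotation) -> None:
    doc = {
        "photo_id": annotation.photo_id,
        "inner_corners": [list(p) for p in annotation.inner_corners],
        "regions": [
            {"label": label, "polygon": [list(p) for p in poly]}
            for label, poly in annotation.regions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def detections_to_frame(photo_id: str, detections: CellDetectionSet) -> pd.DataFrame:
    """Tabulate a detection set with one row per detected circle."""
    return pd.DataFrame(
        {
            "photo_id": photo_id,
            "x": detections.centres[:, 0],
            "y": detections.centres[:, 1],
            "detected_radius": detections.detected_radii,
            "accumulator_threshold_used": detections.accumulator_threshold_used,
        },
        columns=DETECTION_COLUMNS,
    )


def write_detections_csv(
    path: str | Path, photo_id: str, detections: CellDetectionSet
) -> None:
    detections_to_frame(photo_id, detections).to_csv(
        path, index=False, lineterminator="\r\n"
    )


def read_detections_csv(
    path: str | Path, params: DetectionParams
) -> tuple[str, CellDetectionSet]:
    """Rebuild a CellDetectionSet from an exported CSV.

    The lattice spacing and effective radius are recomputed from the
    stored centres with the supplied parameters.
    """
    from .detection import effective_cell_radius, median_neighbour_spacing

    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidAnnotationError(f"{path}: missing columns {sorted(missing)}")
    photo_id = str(df["photo_id"].iloc[0]) if len(df) else Path(path).stem
    centres = df[["x", "y"]].to_numpy(dtype=np.float64)
    spacing = median_neighbour_spacing(centres) if len(centres) >= 2 else None
    return photo_id, CellDetectionSet(
        centres=centres,
        detected_radii=df["detected_radius"].to_numpy(dtype=np.float64),
        accumulator_threshold_used=(
            int(df["accumulator_threshold_used"].iloc[0])
            if len(df)
            else params.accumulator_threshold
        ),
        median_spacing_px=spacing,
        effective_radius_px=(
            effective_cell_radius(spacing, params) if spacing is not None else None
        ),
    )


def measurement_to_row(
    m: FrameMeasurement, error: str = ""
) -> dict[str, Any]:
    """Flatten a FrameMeasurement into one results-CSV row."""
    row: dict[str, Any] = {
        "photo_id": m.photo_id,
        "inner_area_px2": m.inner_area_px2,
        "inner_area_cm2": m.inner_area_cm2,
        "error": error,
    }
    for label, reg in m.per_label.items():
        row[f"{label}_gross_px2"] = reg.gross_polygon_area_px2
        row[f"{label}_n_uncapped"] = reg.n_uncapped_inside
        row[f"{label}_subtracted_px2"] = reg.subtracted_area_px2
        row[f"{label}_px2"] = reg.capped_area_px2
        row[f"{label}_cm2"] = reg.capped_area_cm2
        row[f"{label}_fraction"] = reg.capped_fraction_of_inner
    return row


# --- plain-text configuration -------------------------------------------------

_PARAM_KEYS = {
    "EDGE_THRESHOLD": ("edge_threshold", float),
    "ACC_THRESHOLD": ("accumulator_threshold", int),
    "THRESHOLD_INC": ("threshold_step", int),
    "CELL_INFLATE": ("cell_inflate", float),
    "RADIUS_FRACTION": ("radius_fraction", float),
    "MIN_RADIUS": ("min_radius_px", float),
    "MAX_RADIUS": ("max_radius_px", float),
    "MIN_DIST": ("min_centre_distance_px", float),
    "EXPECTED_PITCH": ("expected_pitch_px", float),
}


def parse_config(path: str | Path) -> dict[str, str]:
    """Parse a ``KEY = value`` config file into a string dict."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected KEY = value, got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip().upper()] = value.strip()
    return out


def detection_params_from_config(
    config: dict[str, str], **overrides: Any
) -> DetectionParams:
    """Build DetectionParams from a parsed config, with keyword overrides."""
    kwargs: dict[str, Any] = {}
    for key, (attr, cast) in _PARAM_KEYS.items():
        if key in config:
            kwargs[attr] = cast(config[key])
    for attr, value in overrides.items():
        if value is not None:
            kwargs[attr] = value
    return DetectionParams(**kwargs)


def mass_constants_from_config(config: dict[str, str]) -> MassConstants | None:
    """Mass constants from HONEY_G_PER_CM2 / BROOD_G_PER_CM2 / EMPTY_FRAME_G.

    Returns None when none of the keys are present; raises if only a
    subset is given.
    """
    keys = ("HONEY_G_PER_CM2", "BROOD_G_PER_CM2", "EMPTY_FRAME_G")
    present = [k for k in keys if k in config]
    if not present:
        return None
    if len(present) != len(keys):
        raise ValueError(f"mass constants need all of {keys}, got {present}")
    return MassConstants(
        honey_mass_per_cm2=float(config["HONEY_G_PER_CM2"]),
        brood_mass_per_cm2=float(config["BROOD_G_PER_CM2"]),
        empty_frame_mass=float(config["EMPTY_FRAME_G"]),
    )
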