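"""Bounding boxes to disk-area estimates, and a classical blob detector.

Upstream organoid detectors (e.g. a convolutional network run on brightfield
frames) emit per-frame bounding boxes. Organoid cross-sections are close to
circular, so each box is reduced to a disk: a diameter is derived from the two
box extents and the projected area is pi*(d/2)^2. For synthetic rendered
frames, :func:`detect_blobs` provides a threshold/label stand-in detector so
the whole pipeline can be exercised without the neural network.

Box convention: 0-based, half-open ``[x_min, x_max) x [y_min, y_max)``, so
``width = x_max - x_min``. Detection CSV columns: ``plate_id, well, frame,
x_min, y_min, x_max, y_max, confidence`` (confidence optional, carried through
but unused by default).
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from ._io import read_csv, write_csv
from .errors import DataError, InvalidBoxError

DiameterRule = Literal["mean", "min", "max", "geometric_mean"]

DETECTION_COLUMNS = [
    "plate_id", "well", "frame",
    "x_min", "y_min", "x_max", "y_max", "confidence",
]
AREA_COLUMNS = ["plate_id", "well", "frame", "x", "y", "area"]


def _diameter(width: float, height: float, rule: DiameterRule) -> float:
    if rule == "mean":
        return (width + height) / 2.0
    if rule == "min":
        return min(width, height)
    if rule == "max":
        return max(width, height)
    if rule == "geometric_mean":
        return math.sqrt(width * height)
    raise DataError(f"unknown diameter rule {rule!r}")


def area_from_box(
    box: Sequence[float], rule: DiameterRule = "mean"
) -> tuple[tuple[float, float], float]:
    """Reduce one bounding box to a disk-area observation.

    Parameters
    ----------
    box:
        ``(x_min, y_min, x_max, y_max)`` in pixels, half-open.
    rule:
        How to reduce the two box extents to one diameter. ``"mean"``
        (arithmetic mean of width and height) is the default: it is symmetric
        in the extents and exact for square boxes.

    Returns
    -------
    ``((x_center, y_center), area)`` with area in pixel^2.
    """
    x_min, y_min, x_max, y_max = (float(v) for v in box)
    width = x_max - x_min
    height = y_max - y_min
    if width <= 0 or height <= 0:
        raise InvalidBoxError(
            f"box {tuple(box)} has non-positive extent "
            f"(width={width}, height={height})"
        )
    d = _diameter(width, height, rule)
    area = math.pi * (d / 2.0) ** 2
    center = ((x_min + x_max) / 2.0, (y_min + y_max) / 2.0)
    return center, area


def areas_from_detections(
    detections: pd.DataFrame, rule: DiameterRule = "mean"
) -> pd.DataFrame:
    """Vectorized :func:`area_from_box` over a detection table.

    Returns a table with columns ``plate_id, well, frame, x, y, area``.
    """
    required = ["plate_id", "well", "frame", "x_min", "y_min", "x_max", "y_max"]
    missing = [c for c in required if c not in detections.columns]
    if missing:
        raise DataError(f"detection table missing columns {missing}")
    width = detections["x_max"].to_numpy(float) - detections["x_min"].to_numpy(float)
    height = detections["y_max"].to_numpy(float) - detections["y_min"].to_numpy(float)
    bad = (width <= 0) | (height <= 0)
    if bad.any():
        rows = detections.index[bad].tolist()[:10]
        raise InvalidBoxError(f"non-positive box extent at rows {rows}")
    if rule == "mean":
        d = (width + height) / 2.0
    elif rule == "min":
        d = np.minimum(width, height)
    elif rule == "max":
        d = np.maximum(width, height)
    elif rule == "geometric_mean":
        d = np.sqrt(width * height)
    else:
        raise DataError(f"unknown diameter rule {rule!r}")
    out = pd.DataFrame({
        "plate_id": detections["plate_id"].to_numpy(),
        "well": detections["well"].to_numpy(),
        "frame": detections["frame"].to_numpy(int),
        "x": (detections["x_min"].to_numpy(float) + detections["x_max"].to_numpy(float)) / 2.0,
        "y": (detections["y_min"].to_numpy(float) + detections["y_max"].to_numpy(float)) / 2.0,
        "area": np.pi * (d / 2.0) ** 2,
    })
    return out


def detect_blobs(
    image: np.ndarray,
    min_area: float = 50.0,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Detect bright blobs in a grayscale frame and emit tight bounding boxes.

    Thresholds the image, fills ring interiors so hollow organoid outlines
    become solid disks, labels connected components, discards components
    smaller than ``min_area`` pixels, and returns boxes sorted by
    ``(y_min, x_min)``. The default threshold is ``max(Otsu, mean + 3*std)``:
    plain Otsu bisects the noise of a background-only frame into percolating
    foreground, while the guard leaves only tiny speckles that ``min_area``
    removes; on frames with bright objects Otsu dominates. Pass an explicit
    ``threshold`` to override the policy.

    Returns a DataFrame with columns ``x_min, y_min, x_max, y_max,
    confidence`` (confidence fixed at 1.0). An image with no blobs yields an
    empty table, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DataError(f"expected a 2-D grayscale image, got shape {img.shape}")
    cols = ["x_min", "y_min", "x_max", "y_max", "confidence"]
    if img.size == 0 or np.ptp(img) == 0:
        return pd.DataFrame(columns=cols)
    if threshold is None:
        thr = max(threshold_otsu(img), img.mean() + 3 * img.std())
    else:
        thr = threshold
    mask = img > thr
    mask = ndimage.binary_fill_holes(mask)
    labeled = label(mask)
    rows = []
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        y0, x0, y1, x1 = region.bbox  # skimage bbox is half-open
        rows.append((float(x0), float(y0), float(x1), float(y1), 1.0))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["y_min", "x_min"], kind="mergesort").reset_index(drop=True)


def detect_frames(
    frames: Iterable[tuple[str, str, int, np.ndarray]],
    min_area: float = 50.0,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Run :func:`detect_blobs` over ``(plate_id, well, frame, image)`` tuples."""
    parts = []
    for plate_id, well, frame, image in frames:
        boxes = detect_blobs(image, min_area=min_area, threshold=threshold)
        boxes.insert(0, "frame", int(frame))
        boxes.insert(0, "well", well)
        boxes.insert(0, "plate_id", plate_id)
        parts.append(boxes)
    if not parts:
        return pd.DataFrame(columns=DETECTION_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def read_detections(path) -> pd.DataFrame:
    """Read a detection CSV in the dialect documented in this module."""
    df = read_csv(path)
    missing = [c for c in DETECTION_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise DataError(f"detection file {path} missing columns {missing}")
    if "confidence" not in df.columns:
        df["confidence"] = 1.0
    return df


def write_areas(areas: pd.DataFrame, path) -> None:
    areas.pipe(write_csv, path)
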