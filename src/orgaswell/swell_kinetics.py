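"""Per-organoid swell rates, QC exclusions, and per-well aggregation.

The swell rate of an organoid is the slope of an ordinary least-squares
regression of projected area (pixel^2) on frame index (time point), fitted
over whichever frames the organoid was actually observed in (gaps are simply
absent points, never interpolated). Two quality-control rules then exclude
unreliable fits:

1. frame rule — the organoid must be observed in at least 8 of the 13
   acquisition time points (scaled proportionally, ``ceil(8/13 * n_frames)``,
   for acquisitions of a different length); checked first;
2. precision rule — the slope standard error must not exceed a cutoff
   (default 2.5, in the fit's own area units per time point); the rule is
   strict: SE exactly at the cutoff is still included.

The per-well score is the arithmetic mean swell rate over included organoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from ._io import read_csv
from .errors import DataError, UnfittableTrackError

QCStatus = Literal["included", "excluded_frames", "excluded_se"]

FIT_COLUMNS = [
    "track_id", "plate_id", "well",
    "slope", "intercept", "slope_se", "n_frames_observed", "qc_status",
]
WELL_COLUMNS = ["plate_id", "well", "mean_swell_rate", "n_included"]


@dataclass(frozen=True)
class QCRules:
    """QC thresholds: minimum observed-frame fraction and max slope SE."""

    n_frames_total: int = 13
    min_frames_frac: float = 8.0 / 13.0
    se_max: float = 2.5

    @property
    def min_frames(self) -> int:
        return math.ceil(self.min_frames_frac * self.n_frames_total)


def fit_swell_rate(frames: np.ndarray, areas: np.ndarray) -> tuple[float, float, float]:
    """OLS of area on frame index.

    Returns ``(slope, intercept, slope_se)``. With exactly two points the fit
    is exact and the residual-based SE is undefined; it is reported as
    ``inf`` so the precision QC rule excludes it.
    """
    frames = np.asarray(frames, float)
    areas = np.asarray(areas, float)
    if frames.size != areas.size:
        raise DataError("frames and areas differ in length")
    if np.unique(frames).size < 2:
        raise UnfittableTrackError(
            f"need >= 2 observations at distinct frames, got {np.unique(frames).size}"
        )
    res = stats.linregress(frames, areas)
    se = float(res.stderr) if frames.size > 2 else math.inf
    # a perfect line through >2 points has zero residual SE, never NaN
    if frames.size > 2 and not np.isfinite(se):
        se = math.inf
    return float(res.slope), float(res.intercept), se


def apply_qc(n_frames_observed: int, slope_se: float, rules: QCRules) -> QCStatus:
    """Classify a fit as included or excluded, frame rule first."""
    if n_frames_observed < rules.min_frames:
        return "excluded_frames"
    if slope_se > rules.se_max:
        return "excluded_se"
    return "included"


def fit_tracks(tracks: pd.DataFrame, rules: QCRules | None = None) -> pd.DataFrame:
    """Fit every track in a track table and attach QC status.

    Tracks with a single observation cannot be fitted; they are reported with
    NaN slope and ``qc_status="excluded_frames"`` (one frame can never meet
    the frame rule) rather than raising, so whole-plate runs do not abort on
    a spurious one-frame track.
    """
    if rules is None:
        rules = QCRules()
    rows = []
    for (track_id, plate_id, well), grp in tracks.groupby(
        ["track_id", "plate_id", "well"], sort=True
    ):
        n_obs = len(grp)
        if grp["frame"].nunique() < 2:
            rows.append((track_id, plate_id, well, np.nan, np.nan, np.inf,
                         n_obs, "excluded_frames"))
            continue
        slope, intercept, se = fit_swell_rate(
            grp["frame"].to_numpy(), grp["area"].to_numpy()
        )
        status = apply_qc(n_obs, se, rules)
        rows.append((track_id, plate_id, well, slope, intercept, se, n_obs, status))
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def aggregate_wells(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean swell rate of included organoids per well.

    Wells where every organoid was excluded are omitted from the output (they
    are counted in :func:`exclusion_summary`); downstream plate normalization
    simply never sees them.
    """
    inc = fits[fits["qc_status"] == "included"]
    if inc.empty:
        return pd.DataFrame(columns=WELL_COLUMNS)
    out = (
        inc.groupby(["plate_id", "well"], sort=True)
        .agg(mean_swell_rate=("slope", "mean"), n_included=("slope", "size"))
        .reset_index()
    )
    return out


def exclusion_summary(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-well tally of included / excluded_frames / excluded_se counts."""
    counts = (
        fits.groupby(["plate_id", "well", "qc_status"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    for col in ("included", "excluded_frames", "excluded_se"):
        if col not in counts.columns:
            counts[col] = 0
    counts["n_organoids"] = counts[["included", "excluded_frames", "excluded_se"]].sum(axis=1)
    return counts.reset_index()


def read_tracks(path) -> pd.DataFrame:
    df = read_csv(path)
    missing = [c for c in ["track_id", "plate_id", "well", "frame", "area"] if c not in df.columns]
    if missing:
        raise DataError(f"track file {path} missing columns {missing}")
    return df
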