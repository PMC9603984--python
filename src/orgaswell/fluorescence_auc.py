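"""Conventional calcein-based swelling quantification: normalized curves + AUC.

In the fluorescence assay the readout is the total labelled organoid area per
well over time. Each well's curve is normalized to its own t=0 value (100%),
the area under the normalized curve minus the 100% baseline is integrated by
the trapezoidal rule up to t=120 min (so a non-swelling well scores exactly 0
and shrinkage is negative), and optionally the mean AUC of same-plate DMSO
wells is subtracted as a baseline correction.

Curve CSV columns: ``plate_id, well, time_min, total_area``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, TraceError


def normalize_curve(times: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Percent-of-baseline series: 100 * area(t) / area(0).

    Requires t=0 present with positive area; times strictly increasing.
    """
    times = np.asarray(times, float)
    areas = np.asarray(areas, float)
    if times.size == 0 or times[0] != 0:
        raise TraceError("curve must start at t=0")
    if np.any(np.diff(times) <= 0):
        raise TraceError("curve times must be strictly increasing")
    if areas[0] <= 0:
        raise TraceError(f"area at t=0 must be > 0, got {areas[0]}")
    return 100.0 * areas / areas[0]


def compute_auc(
    times: np.ndarray,
    normalized: np.ndarray,
    t_end: float = 120.0,
    subtract_baseline: bool = True,
) -> float:
    """Signed trapezoidal AUC of the normalized curve over [0, t_end].

    With ``subtract_baseline`` (default) the integrand is (normalized - 100),
    so a flat 100% curve scores 0 and shrinkage is negative. If ``t_end``
    falls between samples the curve is evaluated there by linear
    interpolation; a curve not reaching ``t_end`` is an error.
    """
    times = np.asarray(times, float)
    normalized = np.asarray(normalized, float)
    if times[-1] < t_end:
        raise TraceError(
            f"curve ends at t={times[-1]} min, before t_end={t_end} min"
        )
    mask = times <= t_end
    t = times[mask]
    y = normalized[mask]
    if t[-1] < t_end:
        y = np.append(y, np.interp(t_end, times, normalized))
        t = np.append(t, t_end)
    integrand = y - 100.0 if subtract_baseline else y
    return float(np.trapezoid(integrand, t))


def auc_table(
    curves: pd.DataFrame, t_end: float = 120.0, subtract_baseline: bool = True
) -> pd.DataFrame:
    """Per-well AUCs from a long-format curve table."""
    required = ["plate_id", "well", "time_min", "total_area"]
    missing = [c for c in required if c not in curves.columns]
    if missing:
        raise DataError(f"curve table missing columns {missing}")
    rows = []
    for (plate_id, well), grp in curves.groupby(["plate_id", "well"], sort=True):
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(float)
        norm = normalize_curve(t, grp["total_area"].to_numpy(float))
        rows.append((plate_id, well, compute_auc(t, norm, t_end, subtract_baseline)))
    return pd.DataFrame(rows, columns=["plate_id", "well", "auc"])


def baseline_correct(aucs: pd.DataFrame, dmso_wells: dict[str, list[str]]) -> pd.DataFrame:
    """Subtract the same-plate mean DMSO AUC from every well's AUC.

    ``dmso_wells`` maps plate_id to that plate's DMSO well names. A plate
    without any DMSO well is an error naming the plate.
    """
    out = aucs.copy()
    corrected = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        plate = str(row.plate_id)
        wells = dmso_wells.get(plate, [])
        ref = out[(out["plate_id"] == row.plate_id) & (out["well"].isin(wells))]
        if ref.empty:
            raise TraceError(f"plate {plate} has no DMSO well for baseline correction")
        corrected[i] = row.auc - ref["auc"].mean()
    out["auc_baseline_corrected"] = corrected
    return out
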