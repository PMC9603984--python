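"""Plate normalization, compound averaging, hit calling and pool deconvolution.

Baseline swelling varies between assay plates and donors, so raw per-well
swell rates are not comparable across plates. Each plate is normalized
robustly::

    norm_rate = (raw_rate - median_plate) / IQR_plate

where the median and interquartile range are computed over the plate's
compound wells (controls excluded under the default policy; a flag includes
them). Normalized rates are then averaged per compound across all wells,
plates and donors that contain it, and a compound is a hit when its mean
normalized rate is strictly above the threshold (default 1.0, i.e. one IQR
above the plate median). In the pooled 384-well design each well holds two
compounds; the well's score is attributed fully to both, and hit wells are
deconvolved by carrying both compounds forward with set semantics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegeneratePlateError, InsufficientWellsError, LayoutError
from .layout import PlateLayout

NORMALIZED_COLUMNS = ["plate_id", "well", "condition", "raw_rate", "norm_rate"]

MIN_ELIGIBLE_WELLS = 4


def plate_median_iqr(
    rates: np.ndarray, quantile_method: str = "linear"
) -> tuple[float, float]:
    """Median and IQR (75th minus 25th percentile) of a rate vector."""
    q25, q50, q75 = np.percentile(rates, [25, 50, 75], method=quantile_method)
    return float(q50), float(q75 - q25)


def normalize_plate(
    well_scores: pd.DataFrame,
    layout: PlateLayout,
    exclude_controls: bool = True,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Normalize one plate's well scores to (raw - median) / IQR.

    Parameters
    ----------
    well_scores:
        Table with columns ``plate_id, well, mean_swell_rate`` for a single
        plate (wells with no included organoids are simply absent).
    layout:
        The plate's layout; used to annotate conditions and to restrict the
        median/IQR reference set to compound wells when ``exclude_controls``.

    Raises
    ------
    InsufficientWellsError
        Fewer than 4 eligible reference wells.
    DegeneratePlateError
        Reference IQR is zero (all reference wells identical).
    """
    plates = well_scores["plate_id"].unique()
    if len(plates) != 1 or str(plates[0]) != layout.plate_id:
        raise LayoutError(
            f"well scores cover plates {list(plates)} but layout is {layout.plate_id}"
        )
    df = well_scores.copy()
    df["condition"] = [layout.condition(w).label for w in df["well"]]
    df["role"] = [layout.condition(w).role for w in df["well"]]
    if exclude_controls:
        ref = df.loc[df["role"] == "compound", "mean_swell_rate"]
    else:
        ref = df["mean_swell_rate"]
    if len(ref) < MIN_ELIGIBLE_WELLS:
        raise InsufficientWellsError(
            f"plate {layout.plate_id}: {len(ref)} eligible wells, "
            f"need >= {MIN_ELIGIBLE_WELLS}"
        )
    median, iqr = plate_median_iqr(ref.to_numpy(float), quantile_method)
    if iqr <= 0:
        raise DegeneratePlateError(
            f"plate {layout.plate_id}: reference IQR is zero, cannot normalize"
        )
    out = pd.DataFrame({
        "plate_id": df["plate_id"].to_numpy(),
        "well": df["well"].to_numpy(),
        "condition": df["condition"].to_numpy(),
        "raw_rate": df["mean_swell_rate"].to_numpy(float),
        "norm_rate": (df["mean_swell_rate"].to_numpy(float) - median) / iqr,
    })
    return out


def normalize_plates(
    well_scores: pd.DataFrame,
    layouts: list[PlateLayout],
    exclude_controls: bool = True,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Apply :func:`normalize_plate` per plate and concatenate."""
    by_id = {lay.plate_id: lay for lay in layouts}
    parts = []
    for plate_id, grp in well_scores.groupby("plate_id", sort=True):
        if str(plate_id) not in by_id:
            raise LayoutError(f"no layout for plate {plate_id}")
        parts.append(
            normalize_plate(grp, by_id[str(plate_id)], exclude_controls, quantile_method)
        )
    return pd.concat(parts, ignore_index=True)


def average_conditions(
    normalized: pd.DataFrame, layouts: list[PlateLayout]
) -> tuple[pd.DataFrame, list[str]]:
    """Average normalized rates per compound across wells, plates and donors.

    A pooled well contributes its full norm_rate to each of its compounds
    (unweighted per-well mean; no deconvolution model). Returns the screen
    table (``compound, mean_norm_rate, n_measurements, source_wells``) and
    the list of layout compounds with zero surviving wells (dropped report).
    """
    by_id = {lay.plate_id: lay for lay in layouts}
    records = []
    for row in normalized.itertuples(index=False):
        lay = by_id.get(str(row.plate_id))
        if lay is None:
            raise LayoutError(f"no layout for plate {row.plate_id}")
        cond = lay.condition(row.well)
        for compound in cond.compounds:
            records.append((compound, row.norm_rate, f"{row.plate_id}:{row.well}"))
    if records:
        df = pd.DataFrame(records, columns=["compound", "norm_rate", "source"])
        table = (
            df.groupby("compound", sort=True)
            .agg(
                mean_norm_rate=("norm_rate", "mean"),
                n_measurements=("norm_rate", "size"),
                source_wells=("source", lambda s: ";".join(sorted(s))),
            )
            .reset_index()
        )
    else:
        table = pd.DataFrame(
            columns=["compound", "mean_norm_rate", "n_measurements", "source_wells"]
        )
    all_compounds = set()
    for lay in layouts:
        all_compounds |= lay.compounds()
    dropped = sorted(all_compounds - set(table["compound"]))
    return table, dropped


def call_hits(table: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Flag hits: mean normalized rate strictly above the threshold."""
    out = table.copy()
    out["hit"] = out["mean_norm_rate"] > threshold
    return out


def deconvolve_pairs(
    hit_wells: pd.DataFrame, layouts: list[PlateLayout]
) -> list[str]:
    """Compounds to carry to secondary screening from hit wells.

    Every hit well contributes both of its pooled compounds; duplicates are
    removed (set semantics). Output sorted for determinism.
    """
    by_id = {lay.plate_id: lay for lay in layouts}
    compounds: set[str] = set()
    for row in hit_wells.itertuples(index=False):
        lay = by_id.get(str(row.plate_id))
        if lay is None:
            raise LayoutError(f"no layout for plate {row.plate_id}")
        cond = lay.condition(row.well)
        compounds.update(cond.compounds)
    return sorted(compounds)
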