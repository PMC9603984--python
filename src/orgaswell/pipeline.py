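"""End-to-end orchestration: simulate/load -> areas -> tracks -> rates -> hits.

Every run writes its stage outputs as CSV, a machine-readable summary
(organoid counts, per-rule exclusion tallies, dropped wells, hits), a plain
log, and its resolved configuration, into one run directory. Re-running any
stage from its input CSV reproduces downstream outputs byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import detection, layout as layout_mod, screen_stats, swell_kinetics, tracking
from ._io import write_csv
from .config import PipelineConfig
from .errors import DegeneratePlateError, InsufficientWellsError, OrgaswellError
from .synthetic_data import make_primary_screen, simulate_screen


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full screening analysis; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str):
        log_lines.append(msg)

    config.to_yaml(out / "resolved_config.yaml")

    # --- stage: inputs (simulate or load) ----------------------------------
    actives: set[str] = set()
    if config.detections_csv:
        detections = detection.read_detections(config.detections_csv)
        layouts = layout_mod.read_layouts(config.layout_csv)
        log(f"loaded {len(detections)} detections from {config.detections_csv}")
    else:
        layouts, sim_cfg, actives = make_primary_screen(
            seed=config.seed,
            n_plates=config.n_plates,
            n_compound_wells=config.n_compound_wells,
            n_dmso=config.n_dmso,
            n_eact=config.n_eact,
            n_actives=config.n_actives,
            active_effect_iqr=config.active_effect_iqr,
            n_frames=config.n_frames,
        )
        detections, truth = simulate_screen(layouts, sim_cfg)
        truth.detections_truth.pipe(write_csv, out / "truth.csv")
        log(
            f"simulated {len(truth.organoids)} organoids over "
            f"{len(layouts)} plates ({len(detections)} detections, "
            f"{truth.n_clipped} clipped areas)"
        )
    layout_mod.write_layouts(layouts, out / "layout.csv")
    detections.pipe(write_csv, out / "detections.csv")
    # each stage below consumes the CSV it just wrote, so re-running the
    # pipeline from any intermediate file reproduces downstream outputs
    # byte-identically (CSV float formatting is not bit-exact round-trip)
    detections = detection.read_detections(out / "detections.csv")

    # --- stage: areas ------------------------------------------------------
    areas = detection.areas_from_detections(detections, rule=config.diameter_rule)
    areas.pipe(write_csv, out / "areas.csv")
    areas = tracking.read_areas(out / "areas.csv")
    log(f"converted {len(areas)} boxes to disk areas (rule={config.diameter_rule})")

    # --- stage: tracking ---------------------------------------------------
    params = tracking.LinkingParams(
        max_displacement=config.max_displacement, memory=config.memory
    )
    tracks = tracking.link_tracks(areas, params)
    tracks.pipe(write_csv, out / "tracks.csv")
    tracks = swell_kinetics.read_tracks(out / "tracks.csv")
    log(f"linked into {tracks['track_id'].nunique()} tracks")

    # --- stage: swell kinetics --------------------------------------------
    rules = swell_kinetics.QCRules(
        n_frames_total=config.n_frames,
        min_frames_frac=config.min_frames_frac,
        se_max=config.se_max,
    )
    fits = swell_kinetics.fit_tracks(tracks, rules)
    fits.pipe(write_csv, out / "fits.csv")
    excl = swell_kinetics.exclusion_summary(fits)
    excl.pipe(write_csv, out / "exclusions.csv")
    wells = swell_kinetics.aggregate_wells(fits)
    wells.pipe(write_csv, out / "wells.csv")
    qc_counts = fits["qc_status"].value_counts().to_dict()
    log(f"fitted {len(fits)} organoids; QC {qc_counts}")

    # --- stage: screen statistics -----------------------------------------
    dropped_plates: list[str] = []
    parts = []
    by_id = {lay.plate_id: lay for lay in layouts}
    for plate_id, grp in wells.groupby("plate_id", sort=True):
        try:
            parts.append(
                screen_stats.normalize_plate(
                    grp, by_id[str(plate_id)],
                    exclude_controls=config.exclude_controls,
                    quantile_method=config.quantile_method,
                )
            )
        except (DegeneratePlateError, InsufficientWellsError) as exc:
            dropped_plates.append(str(plate_id))
            log(f"plate {plate_id} dropped from normalization: {exc}")
    if not parts:
        raise OrgaswellError("screen stage: no plate could be normalized")
    normalized = pd.concat(parts, ignore_index=True)
    normalized.pipe(write_csv, out / "normalized.csv")

    table, dropped_compounds = screen_stats.average_conditions(normalized, layouts)
    table = screen_stats.call_hits(table, threshold=config.hit_threshold)
    table.pipe(write_csv, out / "screen_table.csv")
    hits = table[table["hit"]]
    hits.pipe(write_csv, out / "hits.csv")

    hit_compounds = set(hits["compound"])
    hit_wells = normalized[
        normalized["condition"].map(
            lambda lbl: any(c in hit_compounds for c in lbl.split("+"))
        )
        & ~normalized["condition"].isin(["dmso", "eact"])
    ][["plate_id", "well"]].drop_duplicates()
    secondary = screen_stats.deconvolve_pairs(hit_wells, layouts)
    pd.Series(secondary, name="compound").pipe(write_csv, out / "secondary_compounds.csv")
    log(f"{len(hits)} hit compounds; {len(secondary)} compounds to secondary screen")

    summary = {
        "n_detections": int(len(detections)),
        "n_tracks": int(len(fits)),
        "qc": {
            "included": int(qc_counts.get("included", 0)),
            "excluded_frames": int(qc_counts.get("excluded_frames", 0)),
            "excluded_se": int(qc_counts.get("excluded_se", 0)),
        },
        "n_wells_scored": int(len(wells)),
        "dropped_plates": dropped_plates,
        "dropped_compounds": dropped_compounds,
        "n_hits": int(len(hits)),
        "hit_compounds": sorted(hit_compounds),
        "secondary_compounds": secondary,
        "simulated_active_compounds": sorted(actives),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
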