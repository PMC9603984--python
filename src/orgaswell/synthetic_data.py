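"""Synthetic screening data with known ground truth.

Emulates a pooled 384-well organoid swelling screen: each well holds a few
organoids whose projected areas grow linearly over a 13-frame, 15-minute
time-lapse. The generative model per organoid is::

    area(f)      = baseline + slope * f + Normal(0, area_obs_noise_sd)
    slope        = plate_scale * (basal + condition_effect
                                  + Normal(0, slope_noise_sd)) + plate_shift

where the condition effect is the sum of the well's compound effects (zero
for DMSO vehicle wells, a large positive value for the Eact positive
control), and plate_shift / plate_scale reproduce the plate- and donor-level
baseline-swelling variation that motivates plate normalization downstream.
Observed areas become square bounding boxes (side ``2*sqrt(area/pi)``, the
inverse of the analysis-side disk assumption) whose edges are independently
jittered; whole frames are dropped with a configurable probability to mimic
detection dropout.

Random streams are split per (plate, well) via seed-sequence spawn keys, so
adding wells or plates never perturbs the draws of existing ones, and a fixed
seed reproduces the tables byte-identically.

The module also renders brightfield-like frames (bright organoid ring, darker
lumen, noisy background) for exercising the blob detector, and synthesizes
short-circuit-current step traces and YFP-quenching decay traces.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import DETECTION_COLUMNS
from .errors import ConfigurationError, DataError
from .layout import Condition, PlateLayout

TRUTH_COLUMNS = DETECTION_COLUMNS + ["organoid_id", "true_slope", "true_area", "dropped"]


@dataclass(frozen=True)
class PlateEffect:
    """Additive slope offset and multiplicative slope factor for one plate."""

    shift: float = 0.0
    scale: float = 1.0


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic screen.

    Defaults mirror the primary-screen acquisition (13 frames every 15 min)
    and plausible 5x-objective pixel scales: baseline organoid areas around
    300 px^2 (radius ~10 px), a small basal swell rate present in every
    well, and a strong Eact positive-control effect. Noise scales are chosen
    coherently with the slope-SE quality cutoff applied downstream: box
    jitter couples into area noise as ~sqrt(pi * area) px^2 per pixel of
    edge jitter, so with these defaults a typical fully observed organoid
    has a slope SE well inside the cutoff and only noisy/short tracks are
    excluded, as in the real assay.
    """

    seed: int = 0
    n_frames: int = 13
    frame_interval_min: float = 15.0
    organoids_per_well: float = 15.0       # Poisson mean
    baseline_area_mean: float = 300.0      # px^2
    baseline_area_sd: float = 75.0
    basal_slope: float = 2.0               # px^2 per time point, all wells
    eact_effect: float = 10.0              # positive-control added slope
    compound_effects: dict[str, float] = field(default_factory=dict)
    default_compound_effect: float = 0.0
    slope_noise_sd: float = 1.5            # organoid-to-organoid slope spread
    area_obs_noise_sd: float = 10.0        # per-frame area measurement noise
    detection_dropout_p: float = 0.1
    bbox_jitter_sd: float = 0.5            # per-edge box jitter, px
    plate_effects: dict[str, PlateEffect] = field(default_factory=dict)
    min_area: float = 1.0                  # clip floor for simulated areas
    image_size: tuple[int, int] = (512, 512)
    min_separation_factor: float = 2.0     # x max radius, centre separation
    allow_overlap: bool = False

    def __post_init__(self):
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        for name in ("detection_dropout_p",):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        for name in ("frame_interval_min", "organoids_per_well",
                     "baseline_area_mean", "min_area"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("baseline_area_sd", "slope_noise_sd",
                     "area_obs_noise_sd", "bbox_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def condition_effect(self, cond: Condition) -> float:
        if cond.role == "dmso":
            return 0.0
        if cond.role == "eact":
            return self.eact_effect
        return sum(
            self.compound_effects.get(c, self.default_compound_effect)
            for c in cond.compounds
        )

    def plate_effect(self, plate_id: str) -> PlateEffect:
        return self.plate_effects.get(plate_id, PlateEffect())


@dataclass
class GroundTruth:
    """What was actually simulated.

    organoids:
        One row per organoid: identity, position, baseline area, the true
        (plate-effect-applied) slope, and its condition label.
    observations:
        One row per (organoid, frame) — including dropped frames — mirroring
        the detection table plus ``organoid_id, true_slope, true_area,
        dropped``.
    active_compounds:
        Compounds simulated with a positive swelling effect.
    n_clipped:
        Number of simulated areas clipped at the ``min_area`` floor.
    """

    organoids: pd.DataFrame
    observations: pd.DataFrame
    active_compounds: set[str]
    n_clipped: int = 0

    @property
    def detections_truth(self) -> pd.DataFrame:
        """Truth rows for emitted (non-dropped) detections only."""
        return self.observations[~self.observations["dropped"]].reset_index(drop=True)


def _well_rng(seed: int, plate_id: str, well: str) -> np.random.Generator:
    key = (zlib.crc32(plate_id.encode()), zlib.crc32(well.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _place_centers(
    rng: np.random.Generator, n: int, radii: np.ndarray, cfg: SimulationConfig
) -> np.ndarray:
    """Uniform placement with a minimum centre separation (dart throwing)."""
    h, w = cfg.image_size
    r_max = float(radii.max()) if n else 0.0
    sep = 0.0 if cfg.allow_overlap else cfg.min_separation_factor * r_max
    lo, hi_x, hi_y = r_max, w - r_max, h - r_max
    if hi_x <= lo or hi_y <= lo:
        raise ConfigurationError(
            f"image_size {cfg.image_size} too small for organoid radius {r_max:.0f}"
        )
    centers = np.empty((n, 2))
    for i in range(n):
        for _ in range(2000):
            x = rng.uniform(lo, hi_x)
            y = rng.uniform(lo, hi_y)
            if i == 0 or np.hypot(
                centers[:i, 0] - x, centers[:i, 1] - y
            ).min() >= sep:
                centers[i] = (x, y)
                break
        else:
            # crowded well: accept the last candidate rather than fail
            centers[i] = (x, y)
    return centers


def simulate_screen(
    layouts: list[PlateLayout] | PlateLayout, cfg: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate detections and ground truth for one or more plates.

    Returns the detection table (dropped frames removed) and the
    :class:`GroundTruth`. Deterministic for a fixed (layouts, cfg).
    """
    if isinstance(layouts, PlateLayout):
        layouts = [layouts]
    org_rows = []
    obs_rows = []
    n_clipped = 0
    for lay in sorted(layouts, key=lambda l: l.plate_id):
        eff = cfg.plate_effect(lay.plate_id)
        for well in sorted(lay.wells):
            cond = lay.wells[well]
            rng = _well_rng(cfg.seed, lay.plate_id, well)
            n_org = int(rng.poisson(cfg.organoids_per_well))
            baselines = np.maximum(
                rng.normal(cfg.baseline_area_mean, cfg.baseline_area_sd, n_org),
                cfg.min_area,
            )
            mean_slope = cfg.basal_slope + cfg.condition_effect(cond)
            slopes = eff.scale * (
                mean_slope + rng.normal(0.0, cfg.slope_noise_sd, n_org)
            ) + eff.shift
            max_areas = np.maximum(baselines, baselines + slopes * (cfg.n_frames - 1))
            radii = np.sqrt(np.maximum(max_areas, cfg.min_area) / np.pi)
            centers = _place_centers(rng, n_org, radii, cfg) if n_org else np.empty((0, 2))
            for k in range(n_org):
                oid = f"{lay.plate_id}:{well}:{k}"
                org_rows.append((
                    lay.plate_id, well, oid, centers[k, 0], centers[k, 1],
                    baselines[k], slopes[k], cond.label, cond.role,
                ))
                frames = np.arange(cfg.n_frames)
                true_areas = baselines[k] + slopes[k] * frames
                obs_areas = true_areas + rng.normal(
                    0.0, cfg.area_obs_noise_sd, cfg.n_frames
                )
                clip = obs_areas < cfg.min_area
                n_clipped += int(clip.sum())
                obs_areas = np.maximum(obs_areas, cfg.min_area)
                dropped = rng.random(cfg.n_frames) < cfg.detection_dropout_p
                half = np.sqrt(obs_areas / np.pi)  # square box side / 2
                jit = rng.normal(0.0, cfg.bbox_jitter_sd, (cfg.n_frames, 4))
                x_min = centers[k, 0] - half + jit[:, 0]
                y_min = centers[k, 1] - half + jit[:, 1]
                x_max = centers[k, 0] + half + jit[:, 2]
                y_max = centers[k, 1] + half + jit[:, 3]
                # jitter must never produce a degenerate box, and a real
                # detector never reports a box outside the frame
                h_img, w_img = cfg.image_size
                x_min = np.clip(x_min, 0.0, w_img - 0.5)
                y_min = np.clip(y_min, 0.0, h_img - 0.5)
                x_max = np.clip(np.maximum(x_max, x_min + 0.5), 0.5, w_img)
                y_max = np.clip(np.maximum(y_max, y_min + 0.5), 0.5, h_img)
                for f in frames:
                    obs_rows.append((
                        lay.plate_id, well, int(f),
                        x_min[f], y_min[f], x_max[f], y_max[f], 1.0,
                        oid, slopes[k], true_areas[f], bool(dropped[f]),
                    ))
    organoids = pd.DataFrame(org_rows, columns=[
        "plate_id", "well", "organoid_id", "x", "y",
        "baseline_area", "true_slope", "condition", "role",
    ])
    observations = pd.DataFrame(obs_rows, columns=TRUTH_COLUMNS)
    active = set()
    for lay in layouts:
        for c in lay.compounds():
            if cfg.compound_effects.get(c, cfg.default_compound_effect) > 0:
                active.add(c)
    truth = GroundTruth(organoids, observations, active, n_clipped)
    detections = (
        observations.loc[~observations["dropped"], DETECTION_COLUMNS]
        .reset_index(drop=True)
    )
    return detections, truth


# ---------------------------------------------------------------------------
# canonical screen construction

def expected_well_rate_iqr(cfg: SimulationConfig) -> float:
    """Normal-theory IQR of inactive-well mean swell rates.

    A well's mean rate averages ~``organoids_per_well`` fitted slopes, each
    with organoid-to-organoid spread ``slope_noise_sd`` plus OLS estimation
    noise from per-frame area noise. Per-frame area noise combines the
    direct observation noise with the box-jitter coupling (jitter of sd s on
    each edge perturbs the inferred disk area by ~``sqrt(pi*area)*s``), and
    propagates to the slope as ``sigma_area / sqrt(Sxx)``. The well-to-well
    SD is then ``sqrt((slope_noise_sd^2 + se^2) / n)`` and the IQR is 1.349
    times that. Used to express compound effect sizes in IQR units before
    simulating.
    """
    f = np.arange(cfg.n_frames)
    sxx = float(((f - f.mean()) ** 2).sum())
    jitter_area_sd = np.sqrt(np.pi * cfg.baseline_area_mean) * cfg.bbox_jitter_sd
    sigma_area2 = cfg.area_obs_noise_sd ** 2 + jitter_area_sd ** 2
    se_obs2 = sigma_area2 / sxx
    sd_well = np.sqrt(
        (cfg.slope_noise_sd ** 2 + se_obs2) / cfg.organoids_per_well
    )
    return float(2 * 0.67448975 * sd_well)


def make_primary_screen(
    seed: int = 0,
    n_plates: int = 4,
    n_compound_wells: int = 160,
    n_dmso: int = 8,
    n_eact: int = 8,
    n_actives: int = 10,
    active_effect_iqr: float = 3.0,
    **cfg_overrides,
) -> tuple[list[PlateLayout], SimulationConfig, set[str]]:
    """Construct the pooled primary-screen study: layouts, config, actives.

    Replicate plates (one per donor) share a single well arrangement of
    ``n_compound_wells`` pooled compound pairs plus DMSO and Eact control
    wells, but carry distinct plate-level shift/scale effects. ``n_actives``
    compounds in distinct wells are spiked with a swelling effect of
    ``active_effect_iqr`` times the expected inactive-well IQR; all other
    compounds are inert.
    """
    rng = np.random.default_rng(seed)
    compounds = [f"C{i:03d}" for i in range(1, 2 * n_compound_wells + 1)]
    pairs = [
        (compounds[2 * i], compounds[2 * i + 1]) for i in range(n_compound_wells)
    ]
    active_wells = rng.choice(n_compound_wells, size=n_actives, replace=False)
    actives = {pairs[int(w)][0] for w in sorted(active_wells)}
    plate_effects = {
        f"P{p + 1}": PlateEffect(
            shift=float(rng.uniform(-1.0, 1.0)),
            scale=float(rng.uniform(0.7, 1.3)),
        )
        for p in range(n_plates)
    }
    cfg = SimulationConfig(seed=seed, plate_effects=plate_effects, **cfg_overrides)
    effect = active_effect_iqr * expected_well_rate_iqr(cfg)
    cfg.compound_effects = {c: effect for c in actives}
    from .layout import make_screen_layout

    layouts = [
        make_screen_layout(f"P{p + 1}", pairs, n_dmso, n_eact)
        for p in range(n_plates)
    ]
    return layouts, cfg, actives


# ---------------------------------------------------------------------------
# frame rendering

def render_frame(
    detections: pd.DataFrame,
    image_size: tuple[int, int] = (512, 512),
    rng: np.random.Generator | None = None,
    background: float = 2000.0,
    background_noise_sd: float = 100.0,
    ring_intensity: float = 30000.0,
    lumen_intensity: float = 8000.0,
    ring_width_frac: float = 0.25,
) -> np.ndarray:
    """Render one frame's detections as bright rings on a noisy background.

    Each organoid is a bright annulus (the epithelial shell) around a dimmer
    lumen, which is how cystic organoids appear in thresholded brightfield;
    16-bit grayscale. Boxes must lie inside the image bounds.
    """
    h, w = image_size
    bad = detections[
        (detections["x_min"] < 0) | (detections["y_min"] < 0)
        | (detections["x_max"] > w) | (detections["y_max"] > h)
    ]
    if not bad.empty:
        raise DataError(
            f"{len(bad)} detections outside {image_size} bounds, "
            f"first rows: {bad.index.tolist()[:5]}"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    img = background + rng.normal(0.0, background_noise_sd, (h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for row in detections.itertuples(index=False):
        cx = (row.x_min + row.x_max) / 2.0
        cy = (row.y_min + row.y_max) / 2.0
        r = ((row.x_max - row.x_min) + (row.y_max - row.y_min)) / 4.0
        dist = np.hypot(xx - cx, yy - cy)
        inner = r * (1.0 - ring_width_frac)
        img[dist <= r] = lumen_intensity
        img[(dist <= r) & (dist >= inner)] = ring_intensity
    return np.clip(img, 0, 65535).astype(np.uint16)


def render_frames(
    detections: pd.DataFrame,
    image_size: tuple[int, int] = (512, 512),
    seed: int = 0,
    **render_kwargs,
):
    """Yield ``(plate_id, well, frame, image)`` per (well, frame) group."""
    for (plate_id, well, frame), grp in detections.groupby(
        ["plate_id", "well", "frame"], sort=True
    ):
        rng = _well_rng(seed, str(plate_id), f"{well}:{frame}")
        yield plate_id, well, int(frame), render_frame(
            grp, image_size, rng=rng, **render_kwargs
        )


# ---------------------------------------------------------------------------
# electrophysiology / fluorescence traces

def simulate_isc_trace(
    duration_s: float = 300.0,
    sample_interval_s: float = 10.0,
    event_time_s: float = 150.0,
    baseline_uA: float = 10.0,
    step_uA: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Piecewise-constant short-circuit-current trace with a step at an event.

    Returns columns ``time_s, isc``; samples at the event time carry the
    pre-step level (the chemical acts after the sample is taken).
    """
    times = np.arange(0.0, duration_s + 1e-9, sample_interval_s)
    if not times[0] < event_time_s < times[-1]:
        raise ConfigurationError(
            f"event_time_s={event_time_s} outside trace [0, {times[-1]}]"
        )
    rng = np.random.default_rng(seed)
    isc = np.full_like(times, baseline_uA)
    isc[times > event_time_s] += step_uA
    isc += rng.normal(0.0, noise_sd, times.shape)
    return pd.DataFrame({"time_s": times, "isc": isc})


def simulate_yfp_trace(
    segments: list[tuple[float, float]],
    pre_injection_s: float = 2.0,
    injection_time_s: float = 2.0,
    sample_interval_s: float = 0.2,
    initial_fluorescence: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Piecewise-linear YFP decay trace after an iodide injection.

    ``segments`` is a list of ``(duration_s, slope_per_s)`` pieces applied in
    order after the injection, with slopes in fraction of initial
    fluorescence per second (so a segment slope of -0.05 loses 5% of the
    initial fluorescence per second). Before injection the trace is flat.
    Returns columns ``time_s, fluorescence``.
    """
    if not segments:
        raise ConfigurationError("segments must contain at least one piece")
    if injection_time_s < 0:
        raise ConfigurationError("injection_time_s must be >= 0")
    total_post = sum(d for d, _ in segments)
    times = np.arange(
        0.0, pre_injection_s + total_post + 1e-9, sample_interval_s
    )
    if injection_time_s > times[-1]:
        raise ConfigurationError(
            f"injection_time_s={injection_time_s} outside trace [0, {times[-1]}]"
        )
    frac = np.ones_like(times)
    t0 = injection_time_s
    level = 1.0
    for dur, slope in segments:
        seg = (times >= t0) & (times <= t0 + dur + 1e-9)
        frac[seg] = level + slope * (times[seg] - t0)
        level += slope * dur
        t0 += dur
    frac[times > t0] = level
    rng = np.random.default_rng(seed)
    fluor = initial_fluorescence * frac + rng.normal(0.0, noise_sd, times.shape)
    return pd.DataFrame({"time_s": times, "fluorescence": fluor})


def simulate_traces(kind: str, **params) -> pd.DataFrame:
    """Dispatch to :func:`simulate_isc_trace` or :func:`simulate_yfp_trace`."""
    if kind == "isc":
        return simulate_isc_trace(**params)
    if kind == "yfp":
        return simulate_yfp_trace(**params)
    raise ConfigurationError(f"kind must be 'isc' or 'yfp', got {kind!r}")
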