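# Methods

## The assay and its quantification

Organoids secreting fluid into their lumen enlarge; in a time-lapse of
brightfield frames (13 frames, one every 15 min, 3 h total in the primary
screening configuration) each organoid's projected cross-sectional area
grows approximately linearly over the acquisition. The pipeline estimates
that growth per organoid and aggregates it to wells, plates and compounds.

**Box → disk area.** Upstream detectors report axis-aligned bounding boxes.
Organoid cross-sections are treated as disks; the diameter of a non-square
box is the arithmetic mean of width and height (config `diameter_rule`, also
`min | max | geometric_mean`). The mean rule is symmetric in the two extents
and exact for square boxes; for mildly elongated boxes the choices differ by
less than the box jitter itself. Boxes are half-open, 0-based
(`width = x_max − x_min`).

**Tracking.** Within each well, consecutive frame pairs are matched by a
minimum-total-displacement one-to-one assignment (Hungarian algorithm on the
Euclidean centre-distance matrix). Pairs farther apart than
`max_displacement` (default 30 px per frame step) are forbidden; the solver
therefore first maximizes the number of feasible matches, then minimizes
total displacement. A track missing up to `memory` consecutive frames
(default 5) may re-link under a proportionally enlarged gate, keeping its
identity — the default permits exactly the worst case still analyzable under
the 8-of-13 frame rule. Area change is not part of the cost (an optional
area-ratio gate exists, off by default). Determinism: observations and open
tracks are processed in canonical (y, x) order and final ids are relabelled
by first frame then first (y, x), so the output is independent of input row
order. Tracks are never merged or split after linking.

**Swell rate and QC.** The swell rate is the OLS slope of area (px²) on
frame index, using the actual frame indices of observed points (gaps are
not interpolated), so units are px² per time point; divide by the frame
interval for per-minute rates. Exclusion rules, applied in order:

1. *frame rule*: fewer than `ceil(8/13 · n_frames)` observed frames
   (= 8 when `n_frames = 13`);
2. *precision rule*: slope standard error (residual-based OLS SE) strictly
   greater than `se_max` (default 2.5). A 2-point track has an exact fit but
   an undefined residual SE; it is reported as infinite and excluded.

The SE cutoff is configurable because its natural unit is ambiguous: the
assay literature quotes "pixels/time point" while the regression is on
areas in px². It is applied here in the fit's own units (px²/time point).
A well's score is the arithmetic mean over included organoids; a well with
zero included organoids is absent from downstream analysis (tallied, never
imputed).

**Plate normalization and hit calling.** Baseline swelling varies between
plates and donors, so each plate is normalized as
`(rate − median) / IQR` with median and IQR (75th − 25th percentile, linear
"type-7" interpolation; config `quantile_method`) computed over the plate's
*compound* wells — controls are excluded from the reference set by default
(flag to include). Plates with fewer than 4 eligible wells or zero IQR are
rejected as degenerate. Normalized scores are averaged per compound,
unweighted, over every contributing well across plates and donors (a
per-donor-mean alternative is a flag); a compound is a hit when its mean is
strictly above `hit_threshold` (default 1.0, i.e. one IQR above the plate
median). Pooled wells attribute their full score to both compounds — no
deconvolution model is attempted; both members of a hit well proceed to
secondary screening, deduplicated (set semantics).

**Fluorescence AUC.** Per-well calcein-labelled total-area curves are
normalized to 100% at t = 0; the AUC is the trapezoidal integral of
(normalized − 100) over [0, 120 min], so a non-swelling well scores exactly
0 and shrinkage is negative (integrating raw percent instead is a config
flag). When several same-plate DMSO wells exist, their mean AUC is
subtracted for the baseline-corrected variant.

**Traces.** ΔI_sc = mean of the 5 samples after an addition minus the mean
of the 5 before, divided by membrane area (µA/cm²); the sample at the event
instant belongs to neither window, and windows sit immediately adjacent to
the event (config `gap`, default 0). The YFP quenching rate normalizes the
post-injection trace to its first value, fits a slope in every sliding
window (default width 5 samples — the width is not fixed by the assay
description, so it is config and echoed in output) and reports the
magnitude of the most negative slope; a never-decaying trace scores 0.
Background subtraction before normalization covers the variant used for
stable YFP cell lines. QRs are usually reported relative to the mean
control QR.

## Synthetic data generator

The generator emulates the screening assay, not organoid biology:

- per well, `Poisson(organoids_per_well)` organoids (default mean 15 — the
  assay literature does not report per-well counts; 15 per 7-µL Matrigel
  droplet at 5× magnification is a plausible density) placed uniformly with
  centre separation ≥ 2× the largest radius, so noise-free tracking is
  unambiguous (overlap only when explicitly enabled);
- per organoid, baseline area ~ Normal(300, 75²) px² (radius ≈ 10 px at a
  5× objective) and true slope
  `plate_scale · (basal + condition effect + Normal(0, slope_noise_sd)) + plate_shift`;
  the basal slope (2 px²/tp) models intrinsic lumen formation present in
  every well, the Eact positive control adds 10 px²/tp, compound effects
  come from a per-compound map;
- per frame, observed area = true area + Normal(0, `area_obs_noise_sd`),
  clipped at `min_area` (1 px², clips counted); the box is the square with
  side `2·sqrt(area/π)` — the exact inverse of the analysis-side disk
  assumption — with each edge jittered independently
  (Normal(0, `bbox_jitter_sd`)); whole frames drop out independently with
  `detection_dropout_p`.

Noise scales are mutually coherent: edge jitter of sd *s* perturbs the
inferred disk area by ≈ `sqrt(π·A)·s` px², so the defaults
(A ≈ 300, s = 0.5, direct area noise 10) give a typical slope SE of ≈ 1.4
px²/tp for a fully observed track — inside the 2.5 cutoff, with only noisy
or short tracks excluded, as in the real assay. Larger organoids with the
same pixel jitter would push most fits over the cutoff, which is a property
to keep in mind when mapping real magnifications onto these defaults.

Randomness is split per (plate, well) via seed-sequence spawn keys derived
from CRC32 of the identifiers, so adding wells or plates never changes the
draws of existing ones and a fixed seed reproduces every table byte for
byte.

`make_primary_screen` builds the canonical study: 4 replicate plates (one
per donor) sharing one arrangement of 160 pooled compound-pair wells plus 8
DMSO and 8 Eact wells, each plate with its own shift/scale drawn from
U(−1, 1) and U(0.7, 1.3); `n_actives` compounds in distinct wells receive an
effect of `active_effect_iqr` (default 3) times the *expected* inactive-well
IQR, computed analytically (`expected_well_rate_iqr`) from the configured
noise before any simulation — the effect size is a stated condition, not a
fitted number.

What the generator does **not** emulate: organoid morphology and texture
(rendered frames are bright rings with darker lumina — sufficient for a
threshold detector, not for training one), organoid death/bursting,
spatial plate gradients (only global shift/scale), non-linear swelling
kinetics, and detector confidence behaviour (confidence is carried but
constant). Passing tests therefore demonstrate correctness of the analysis
chain under its stated model, not detector performance on real images.

## Numerical and design choices

- OLS via `scipy.stats.linregress`; the test suite checks it against an
  independently coded closed form at 1e-10 relative tolerance.
- Assignment ties (equidistant candidates) are resolved by the canonical
  (y, x) processing order; random instances in tests have unique optima.
- The blob detector thresholds at `max(Otsu, mean + 3·std)`: plain Otsu
  bisects the noise of a background-only frame; the guard leaves only
  speckles below `min_area`. Ring interiors are filled before labelling.
- CSV floats are written as `%.17g` and parsed with pandas'
  `float_precision="round_trip"`, making every stage's CSV a bit-exact
  checkpoint; the pipeline re-reads each file it writes, so re-running from
  any intermediate reproduces downstream outputs byte-identically.
- Degenerate inputs fail loudly with typed errors naming the offending
  plate/field/records; one-frame tracks are the exception (flagged
  `excluded_frames` instead of aborting a whole-plate run).
- Problem sizes in tests and the acceptance script (4 plates × 384 wells,
  ~10⁴ organoids; 10⁴-replicate Monte-Carlo checks) were chosen so the full
  suite completes in a few minutes on one CPU while keeping sampling error
  well below the tested tolerances.

## Known limitations

- The tracker is greedy over consecutive frame pairs (no global
  multi-frame optimization, motion model, or split/merge handling); it is
  exact for the well-separated, near-stationary organoids it is built for.
- Hit calling has no error control (no FDR); the 1-IQR rule is the assay's
  own convention and is sensitive to the quantile method on small plates,
  which is why both are explicit config.
- The fluorescence module takes per-well total area as input; calcein image
  segmentation itself is out of scope.
- Pooled-well scores cannot distinguish which member of a pair is active;
  deconvolution is by design deferred to single-compound secondary screens.
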