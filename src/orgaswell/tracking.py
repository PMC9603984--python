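"""Link per-frame area observations into per-organoid tracks.

Organoids barely move between consecutive time-lapse frames, so linking is a
nearest-neighbour assignment problem: for every consecutive frame pair within
a well, a minimum-total-displacement one-to-one matching is solved between
open tracks and new observations (Hungarian algorithm). Matches farther than
``max_displacement`` pixels per frame step are forbidden; unmatched
observations start new tracks; a track may miss up to ``memory`` consecutive
frames (detection dropout) and still re-link under a proportionally larger
displacement gate, retaining its identity.

The output is deterministic and independent of input row order: observations
and open tracks are processed in a canonical ``(y, x)`` order, and final track
ids are relabelled by (first frame, first y, first x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._io import read_csv, write_csv
from .errors import ConfigurationError, DataError

TRACK_COLUMNS = ["track_id", "plate_id", "well", "frame", "x", "y", "area"]

_BIG = 1e12  # sentinel cost for gate-violating pairs


@dataclass(frozen=True)
class LinkingParams:
    """Linking gates.

    max_displacement:
        Largest allowed centre movement in pixels per frame step. A track
        re-linking across a gap of g missed frames may move up to
        ``(g + 1) * max_displacement``.
    memory:
        Maximum number of consecutive missed frames a track survives.
    area_ratio_max:
        Optional gate on frame-to-frame area ratio (max/min); ``None``
        disables it (area change is not part of the linking cost).
    """

    max_displacement: float = 30.0
    memory: int = 5
    area_ratio_max: float | None = None

    def __post_init__(self):
        if not self.max_displacement > 0:
            raise ConfigurationError("max_displacement must be > 0")
        if self.memory < 0:
            raise ConfigurationError("memory must be >= 0")
        if self.area_ratio_max is not None and self.area_ratio_max < 1:
            raise ConfigurationError("area_ratio_max must be >= 1")


class _Track:
    __slots__ = ("obs",)

    def __init__(self, frame, x, y, area):
        self.obs = [(frame, x, y, area)]

    @property
    def last(self):
        return self.obs[-1]


def _link_one_well(obs: pd.DataFrame, params: LinkingParams) -> list[_Track]:
    frames = np.sort(obs["frame"].unique())
    tracks: list[_Track] = []
    for f in frames:
        cur = obs[obs["frame"] == f].sort_values(["y", "x"], kind="mergesort")
        pts = cur[["x", "y", "area"]].to_numpy(float)
        # open tracks that may still re-link, canonical order by last (y, x)
        open_tracks = [
            t for t in tracks if f - t.last[0] - 1 <= params.memory and t.last[0] < f
        ]
        open_tracks.sort(key=lambda t: (t.last[2], t.last[1]))
        matched_obs = set()
        if open_tracks and len(pts):
            last = np.array([[t.last[1], t.last[2], t.last[3]] for t in open_tracks])
            steps = np.array([f - t.last[0] for t in open_tracks], float)
            dist = np.hypot(
                last[:, 0:1] - pts[None, :, 0], last[:, 1:2] - pts[None, :, 1]
            )
            gate = steps[:, None] * params.max_displacement
            feasible = dist <= gate
            if params.area_ratio_max is not None:
                a0 = last[:, 2:3]
                a1 = pts[None, :, 2]
                ratio = np.maximum(a0, a1) / np.minimum(a0, a1)
                feasible &= ratio <= params.area_ratio_max
            cost = np.where(feasible, dist, _BIG)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] >= _BIG:
                    continue
                open_tracks[r].obs.append((int(f), pts[c, 0], pts[c, 1], pts[c, 2]))
                matched_obs.add(c)
        for c in range(len(pts)):
            if c not in matched_obs:
                tracks.append(_Track(int(f), pts[c, 0], pts[c, 1], pts[c, 2]))
    return tracks


def link_tracks(
    observations: pd.DataFrame, params: LinkingParams | None = None
) -> pd.DataFrame:
    """Link area observations into tracks, well by well.

    Parameters
    ----------
    observations:
        Table with columns ``plate_id, well, frame, x, y, area``.
    params:
        Linking gates; defaults to :class:`LinkingParams()`.

    Returns
    -------
    Track table with columns ``track_id, plate_id, well, frame, x, y, area``,
    sorted by (plate, well, track, frame). Every input observation appears in
    exactly one track.
    """
    if params is None:
        params = LinkingParams()
    required = ["plate_id", "well", "frame", "x", "y", "area"]
    missing = [c for c in required if c not in observations.columns]
    if missing:
        raise DataError(f"observation table missing columns {missing}")
    dup = observations.duplicated(subset=["plate_id", "well", "frame", "x", "y"])
    if dup.any():
        rows = observations.index[dup].tolist()[:10]
        raise DataError(f"duplicate (frame, center) observations at rows {rows}")

    out_rows = []
    next_id = 0
    keys = sorted(
        observations.groupby(["plate_id", "well"], sort=True).groups.items()
    )
    for (plate_id, well), idx in keys:
        tracks = _link_one_well(observations.loc[idx], params)
        # canonical ids: by first frame, then first (y, x)
        tracks.sort(key=lambda t: (t.obs[0][0], t.obs[0][2], t.obs[0][1]))
        for t in tracks:
            for frame, x, y, area in t.obs:
                out_rows.append((next_id, plate_id, well, frame, x, y, area))
            next_id += 1
    return pd.DataFrame(out_rows, columns=TRACK_COLUMNS)


def read_areas(path) -> pd.DataFrame:
    df = read_csv(path)
    missing = [c for c in ["plate_id", "well", "frame", "x", "y", "area"] if c not in df.columns]
    if missing:
        raise DataError(f"area file {path} missing columns {missing}")
    return df


def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.pipe(write_csv, path)
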