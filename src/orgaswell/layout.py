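"""Plate layouts: which well holds which compounds or controls.

A screening plate maps every well to exactly one condition: a compound pair
(384-well primary screen pools two distinct compounds per well), a single
compound (96-well validation format), a DMSO vehicle negative control, or an
Eact positive control (calcium-dependent, CFTR-independent secretagogue).

Layout CSV columns: ``plate_id, well, role, compound_1, compound_2`` with
role in {compound, dmso, eact}; empty compound columns for controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

from .errors import ConfigurationError, DataError, LayoutError

Role = Literal["compound", "dmso", "eact"]

_FORMATS = {384: ("ABCDEFGHIJKLMNOP", 24), 96: ("ABCDEFGH", 12)}


def well_names(plate_format: int) -> list[str]:
    """All well names for a plate format, row-major (``A01 ... P24``)."""
    try:
        rows, ncol = _FORMATS[plate_format]
    except KeyError:
        raise ConfigurationError(f"format must be 384 or 96, got {plate_format}")
    return [f"{r}{c:02d}" for r in rows for c in range(1, ncol + 1)]


@dataclass(frozen=True)
class Condition:
    role: Role
    compounds: tuple[str, ...] = ()

    def __post_init__(self):
        if self.role == "compound":
            if not 1 <= len(self.compounds) <= 2:
                raise ConfigurationError(
                    f"compound wells carry 1 or 2 compounds, got {self.compounds}"
                )
            if len(set(self.compounds)) != len(self.compounds):
                raise ConfigurationError(
                    f"pooled compounds must be distinct, got {self.compounds}"
                )
        elif self.role in ("dmso", "eact"):
            if self.compounds:
                raise ConfigurationError(
                    f"{self.role} control wells carry no compounds"
                )
        else:
            raise ConfigurationError(f"unknown role {self.role!r}")

    @property
    def label(self) -> str:
        if self.role == "compound":
            return "+".join(self.compounds)
        return self.role


@dataclass
class PlateLayout:
    plate_id: str
    plate_format: int
    wells: dict[str, Condition] = field(default_factory=dict)

    def __post_init__(self):
        valid = set(well_names(self.plate_format))
        bad = set(self.wells) - valid
        if bad:
            raise ConfigurationError(
                f"wells not in {self.plate_format}-format plate: {sorted(bad)[:5]}"
            )

    def condition(self, well: str) -> Condition:
        try:
            return self.wells[well]
        except KeyError:
            raise LayoutError(f"well {well} has no layout entry on plate {self.plate_id}")

    def compound_wells(self) -> list[str]:
        return [w for w, c in sorted(self.wells.items()) if c.role == "compound"]

    def control_wells(self) -> list[str]:
        return [w for w, c in sorted(self.wells.items()) if c.role != "compound"]

    def compounds(self) -> set[str]:
        out: set[str] = set()
        for c in self.wells.values():
            out.update(c.compounds)
        return out


def make_screen_layout(
    plate_id: str,
    compound_pairs: list[tuple[str, str]],
    n_dmso: int = 8,
    n_eact: int = 8,
    plate_format: int = 384,
) -> PlateLayout:
    """Build a pooled screening layout: pairs first (row-major), then controls.

    Raises if pairs + controls exceed the plate capacity.
    """
    names = well_names(plate_format)
    need = len(compound_pairs) + n_dmso + n_eact
    if need > len(names):
        raise ConfigurationError(
            f"{need} wells requested but a {plate_format}-well plate has {len(names)}"
        )
    wells: dict[str, Condition] = {}
    i = 0
    for pair in compound_pairs:
        wells[names[i]] = Condition("compound", tuple(pair))
        i += 1
    for _ in range(n_dmso):
        wells[names[i]] = Condition("dmso")
        i += 1
    for _ in range(n_eact):
        wells[names[i]] = Condition("eact")
        i += 1
    return PlateLayout(plate_id, plate_format, wells)


def layouts_to_frame(layouts: list[PlateLayout]) -> pd.DataFrame:
    rows = []
    for lay in layouts:
        for well, cond in sorted(lay.wells.items()):
            c1 = cond.compounds[0] if len(cond.compounds) > 0 else ""
            c2 = cond.compounds[1] if len(cond.compounds) > 1 else ""
            rows.append((lay.plate_id, well, cond.role, c1, c2))
    return pd.DataFrame(rows, columns=["plate_id", "well", "role", "compound_1", "compound_2"])


def frame_to_layouts(df: pd.DataFrame, plate_format: int = 384) -> list[PlateLayout]:
    required = ["plate_id", "well", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"layout table missing columns {missing}")
    layouts = []
    for plate_id, grp in df.groupby("plate_id", sort=True):
        wells = {}
        for _, row in grp.iterrows():
            comps = tuple(
                str(row[c]) for c in ("compound_1", "compound_2")
                if c in grp.columns and pd.notna(row.get(c)) and str(row.get(c)) != ""
            )
            wells[row["well"]] = Condition(row["role"], comps)
        layouts.append(PlateLayout(str(plate_id), plate_format, wells))
    return layouts


def write_layouts(layouts: list[PlateLayout], path) -> None:
    layouts_to_frame(layouts).to_csv(path, index=False)


def read_layouts(path, plate_format: int = 384) -> list[PlateLayout]:
    return frame_to_layouts(pd.read_csv(path, keep_default_na=False), plate_format)
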