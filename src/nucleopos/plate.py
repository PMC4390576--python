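"""Plate-reader time-series container and delimited-text I/O.

A plate run is a shared time grid (minutes) plus one record per well
holding the raw OD600 and raw fluorescence series and the well's
annotation: which reporter insertion site it carries, the growth medium,
whether it is a medium-only blank or a non-fluorescent background
strain, and the replicate (independent experiment) id.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WellRecord",
    "PlateTimeSeries",
    "read_plate_long",
    "read_plate_wide",
    "read_wells",
    "write_plate_long",
]


@dataclass
class WellRecord:
    well_id: str
    od_raw: np.ndarray
    fl_raw: np.ndarray
    site_label: str | None = None
    medium: str = ""
    is_blank: bool = False
    is_background: bool = False
    replicate_id: int = 1
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.od_raw = np.asarray(self.od_raw, dtype=float)
        self.fl_raw = np.asarray(self.fl_raw, dtype=float)
        if self.od_raw.shape != self.fl_raw.shape:
            raise ValueError(f"well {self.well_id}: OD and fluorescence lengths differ")
        if self.is_blank and self.site_label:
            raise ValueError(f"blank well {self.well_id} must not carry a site label")


@dataclass
class PlateTimeSeries:
    times: np.ndarray  # minutes, strictly increasing, shared by all wells
    wells: list[WellRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need a 1-D time grid with at least two points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for w in self.wells:
            if len(w.od_raw) != len(self.times):
                raise ValueError(f"well {w.well_id} does not share the plate time grid")

    def blanks(self) -> list[WellRecord]:
        return [w for w in self.wells if w.is_blank]

    def backgrounds(self, medium: str | None = None) -> list[WellRecord]:
        out = [w for w in self.wells if w.is_background]
        if medium is not None:
            out = [w for w in out if w.medium == medium]
        return out

    def samples(self) -> list[WellRecord]:
        return [w for w in self.wells if not w.is_blank and not w.is_background]

    def well(self, well_id: str) -> WellRecord:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per timepoint per well."""
        frames = []
        for w in self.wells:
            frames.append(
                pd.DataFrame(
                    {
                        "time_min": self.times,
                        "well_id": w.well_id,
                        "od600": w.od_raw,
                        "fluor": w.fl_raw,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_id": [w.well_id for w in self.wells],
                "site_label": [w.site_label or "" for w in self.wells],
                "medium": [w.medium for w in self.wells],
                "is_blank": [int(w.is_blank) for w in self.wells],
                "is_background": [int(w.is_background) for w in self.wells],
                "replicate": [w.replicate_id for w in self.wells],
                "temperature": [w.temperature for w in self.wells],
            }
        )


def _records_from_annotation(wells_df: pd.DataFrame, series: dict[str, tuple[np.ndarray, np.ndarray]]) -> list[WellRecord]:
    records = []
    meta = wells_df.set_index("well_id")
    for well_id, (od, fl) in series.items():
        if well_id in meta.index:
            row = meta.loc[well_id]
            site = row.get("site_label", "")
            site = None if (pd.isna(site) or site == "") else str(site)
            temp = row.get("temperature", np.nan)
            records.append(
                WellRecord(
                    well_id=well_id,
                    od_raw=od,
                    fl_raw=fl,
                    site_label=site,
                    medium=str(row.get("medium", "")),
                    is_blank=bool(row.get("is_blank", 0)),
                    is_background=bool(row.get("is_background", 0)),
                    replicate_id=int(row.get("replicate", 1)),
                    temperature=None if pd.isna(temp) else float(temp),
                )
            )
        else:
            records.append(WellRecord(well_id=well_id, od_raw=od, fl_raw=fl))
    return records


def read_plate_long(plate_path, wells_path) -> PlateTimeSeries:
    """Read a long-format plate CSV (time_min, well_id, od600, fluor)
    plus a well-annotation CSV (well_id, site_label, medium, is_blank,
    is_background, replicate[, temperature])."""
    df = pd.read_csv(plate_path)
    wells_df = pd.read_csv(wells_path)
    times = np.sort(df["time_min"].unique())
    series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for well_id, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("time_min")
        if len(grp) != len(times) or not np.array_equal(grp["time_min"].to_numpy(), times):
            raise ValueError(f"well {well_id} does not share the common time grid")
        series[str(well_id)] = (grp["od600"].to_numpy(float), grp["fluor"].to_numpy(float))
    return PlateTimeSeries(times=times, wells=_records_from_annotation(wells_df, series))


def read_plate_wide(od_path, fluor_path, wells_path) -> PlateTimeSeries:
    """Read wide-format plate CSVs: a time_min column plus one column per well."""
    od = pd.read_csv(od_path)
    fl = pd.read_csv(fluor_path)
    wells_df = pd.read_csv(wells_path)
    times = od["time_min"].to_numpy(float)
    if not np.array_equal(times, fl["time_min"].to_numpy(float)):
        raise ValueError("OD and fluorescence files have different time grids")
    series = {}
    for col in od.columns:
        if col == "time_min":
            continue
        if col not in fl.columns:
            raise ValueError(f"well {col} present in OD file but not fluorescence file")
        series[col] = (od[col].to_numpy(float), fl[col].to_numpy(float))
    return PlateTimeSeries(times=times, wells=_records_from_annotation(wells_df, series))


def read_wells(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_plate_long(plate: PlateTimeSeries, plate_path, wells_path) -> None:
    plate.to_frame().to_csv(plate_path, index=False)
    plate.annotation_frame().to_csv(wells_path, index=False)
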