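"""Minimal flow-cytometry processing: scatter gating and FL1 summaries.

Mirrors the single-cell verification of the plate-reader measurements:
a live gate in forward/side-scatter space selects the bacterial
population, and per-cell FL1 (reporter fluorescence) is summarised per
sample, with a non-fluorescent sample providing the background level.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CytometryEvents",
    "RectangleGate",
    "PolygonGate",
    "auto_gate",
    "apply_gate",
    "fl1_summary",
    "read_events_csv",
]


@dataclass
class CytometryEvents:
    fsc: np.ndarray
    ssc: np.ndarray
    fl1: np.ndarray
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.fsc = np.asarray(self.fsc, dtype=float)
        self.ssc = np.asarray(self.ssc, dtype=float)
        self.fl1 = np.asarray(self.fl1, dtype=float)
        if not (len(self.fsc) == len(self.ssc) == len(self.fl1)):
            raise ValueError("FSC, SSC and FL1 must have equal lengths")
        if not (np.isfinite(self.fsc).all() and np.isfinite(self.ssc).all() and np.isfinite(self.fl1).all()):
            raise ValueError("event channels must be finite")

    def __len__(self) -> int:
        return len(self.fsc)


@dataclass(frozen=True)
class RectangleGate:
    fsc_min: float
    fsc_max: float
    ssc_min: float
    ssc_max: float

    def __post_init__(self) -> None:
        if not (self.fsc_max > self.fsc_min and self.ssc_max > self.ssc_min):
            raise ValueError("degenerate (zero-area) rectangle gate")

    def contains(self, fsc: np.ndarray, ssc: np.ndarray) -> np.ndarray:
        return (
            (fsc >= self.fsc_min)
            & (fsc <= self.fsc_max)
            & (ssc >= self.ssc_min)
            & (ssc <= self.ssc_max)
        )


@dataclass(frozen=True)
class PolygonGate:
    """Simple (non-self-intersecting) polygon in (FSC, SSC) space."""

    vertices: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
            raise ValueError("polygon needs >= 3 (fsc, ssc) vertices")
        x, y = v[:, 0], v[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area == 0:
            raise ValueError("degenerate (zero-area) polygon gate")

    def contains(self, fsc: np.ndarray, ssc: np.ndarray) -> np.ndarray:
        from matplotlib.path import Path

        path = Path(np.asarray(self.vertices, dtype=float))
        pts = np.column_stack([fsc, ssc])
        # union of both radius signs makes the boundary inclusive
        return path.contains_points(pts, radius=1e-9) | path.contains_points(pts, radius=-1e-9)


def auto_gate(events: CytometryEvents, lower_pct: float = 1.0, upper_pct: float = 99.0) -> RectangleGate:
    """Default live gate: central-percentile rectangle of the sample itself.

    Captures a bell-shaped population without cutting it off while
    excluding extreme scatter (debris / aggregates).
    """
    flo, fhi = np.percentile(events.fsc, [lower_pct, upper_pct])
    slo, shi = np.percentile(events.ssc, [lower_pct, upper_pct])
    return RectangleGate(flo, fhi, slo, shi)


def apply_gate(events: CytometryEvents, gate) -> tuple[CytometryEvents, float]:
    """Keep events inside the gate (boundary inclusive); return fraction retained."""
    inside = gate.contains(events.fsc, events.ssc)
    gated = CytometryEvents(
        fsc=events.fsc[inside],
        ssc=events.ssc[inside],
        fl1=events.fl1[inside],
        sample_label=events.sample_label,
    )
    frac = float(inside.mean()) if len(events) else 0.0
    return gated, frac


def fl1_summary(gated: CytometryEvents, background: CytometryEvents | None = None) -> dict:
    """Per-sample FL1 statistics: mean, median, robust CV, net mean.

    robust CV = 1.4826 * MAD / median (unit-free spread); the net mean
    subtracts the mean FL1 of the non-fluorescent background sample.
    Both mean and median are reported since either may be compared with
    bulk (plate-reader) measurements.
    """
    if len(gated) == 0:
        raise ValueError("no events inside the gate")
    fl1 = gated.fl1
    med = float(np.median(fl1))
    mad = float(np.median(np.abs(fl1 - med)))
    out = {
        "sample": gated.sample_label,
        "n_events": len(gated),
        "mean_fl1": float(fl1.mean()),
        "median_fl1": med,
        "robust_cv": 1.4826 * mad / med if med != 0 else np.nan,
    }
    if background is not None:
        if len(background) == 0:
            raise ValueError("empty background sample")
        out["net_mean_fl1"] = out["mean_fl1"] - float(background.fl1.mean())
    return out


def read_events_csv(path, sample_label: str | None = None) -> CytometryEvents:
    """Read an event table CSV with (case-insensitive) fsc, ssc, fl1 columns."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        fsc, ssc, fl1 = (df[cols[k]].to_numpy(float) for k in ("fsc", "ssc", "fl1"))
    except KeyError as exc:
        raise ValueError(f"missing channel column in {path}: {exc}") from exc
    if sample_label is None:
        import os

        sample_label = os.path.splitext(os.path.basename(str(path)))[0]
    return CytometryEvents(fsc=fsc, ssc=ssc, fl1=fl1, sample_label=sample_label)
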