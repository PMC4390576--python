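"""Circular-genome coordinate arithmetic and genomic-context profiles.

Coordinates are 1-based inclusive at every public interface (matching
how bacterial insertion sites are conventionally reported); BED input is
interpreted per the BED convention (0-based, half-open) and converted on
read.  Internally windows are handled 0-based half-open.

The module provides:

* ``circular_distance`` / ``relative_position`` -- shortest-arc distance
  and the per-replichore relative map position m' (0 at oriC, 1 at ter)
  used by the gene-dosage model;
* ``at_content_windows`` -- sliding-window A+T fraction on a circular
  (or linear) genome, the scale at which nucleoid proteins such as H-NS
  preferentially bind;
* ``occupancy_overlap`` -- does a site (with flank) fall inside
  published protein-occupancy intervals, and how far is the nearest one;
* ``binned_counts`` -- feature-midpoint histogram over equal circular
  bins.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeLayout",
    "InsertionSite",
    "IntervalSet",
    "ATProfile",
    "OverlapReport",
    "circular_distance",
    "relative_position",
    "at_content_windows",
    "occupancy_overlap",
    "binned_counts",
    "read_fasta",
    "read_bed",
    "write_bed",
    "write_bedgraph",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Replication frame of a (usually circular) bacterial chromosome.

    ter defaults to the point diametrically opposite oriC when not
    supplied; real termination regions are close to, but not exactly at,
    that point, so supply ter explicitly when known.
    """

    length: int
    oriC: int
    ter: int | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be >= 1")
        if not (1 <= self.oriC <= self.length):
            raise ValueError("oriC outside genome")
        if self.ter is not None:
            if not (1 <= self.ter <= self.length):
                raise ValueError("ter outside genome")
            if self.ter == self.oriC:
                raise ValueError("ter must differ from oriC")

    @property
    def ter_effective(self) -> int:
        if self.ter is not None:
            return self.ter
        return (self.oriC - 1 + self.length // 2) % self.length + 1


@dataclass
class InsertionSite:
    """A reporter insertion site on the chromosome."""

    label: str
    position: int
    orientation: int = 1
    m_prime: float | None = None

    def annotate(self, layout: GenomeLayout) -> "InsertionSite":
        self.m_prime = relative_position(self.position, layout)
        return self


@dataclass
class IntervalSet:
    """A named set of 1-based closed genomic intervals (an occupancy track).

    Intervals that wrap across the origin are represented as two
    non-wrapping records; ``write_bed`` re-merges nothing (they stay as
    two lines, which round-trips).
    """

    name: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def validate(self, layout: GenomeLayout | None = None) -> "IntervalSet":
        for s, e in self.intervals:
            if s < 1 or e < s:
                raise ValueError(f"bad interval ({s}, {e}) in {self.name}")
            if layout is not None and e > layout.length:
                raise ValueError(f"interval ({s}, {e}) beyond genome end")
        return self

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class ATProfile:
    """Sliding-window A+T fraction along the genome."""

    window_bp: int
    shift_bp: int
    centers: np.ndarray  # 1-based window-center coordinates (float)
    at_fraction: np.ndarray  # in [0,1]; NaN where the window had no ACGT


@dataclass(frozen=True)
class OverlapReport:
    """Result of intersecting one site (with flank) with one track."""

    track: str
    overlaps: bool
    overlap_bp: int
    nearest_distance: int | None  # bp from the site to the nearest interval; None if track empty


# ---------------------------------------------------------------------------
# coordinate arithmetic


def _check_coord(x: int, layout: GenomeLayout) -> None:
    if not (1 <= x <= layout.length):
        raise ValueError(f"coordinate {x} outside genome [1, {layout.length}]")


def circular_distance(a: int, b: int, layout: GenomeLayout) -> int:
    """Shortest separation between two coordinates, in bp."""
    _check_coord(a, layout)
    _check_coord(b, layout)
    d = abs(a - b)
    if layout.circular:
        return min(d, layout.length - d)
    return d


def relative_position(position, layout: GenomeLayout):
    """Relative map position m' in [0, 1]: 0 at oriC, 1 at ter.

    Each replichore (oriC->ter arc) is scaled linearly to [0, 1], so m'
    is continuous across the oriC wrap and the two replichores may have
    different physical lengths.
    """
    pos = np.asarray(position)
    if np.any(pos < 1) or np.any(pos > layout.length):
        raise ValueError("position outside genome")
    L = layout.length
    ter = layout.ter_effective
    d_cw = (pos - layout.oriC) % L  # clockwise offset from oriC
    r1 = (ter - layout.oriC) % L  # clockwise replichore length
    r2 = L - r1
    m = np.where(d_cw <= r1, d_cw / r1, (L - d_cw) / r2)
    if m.ndim == 0:
        return float(m)
    return m.astype(float)


# ---------------------------------------------------------------------------
# AT content


def at_content_windows(
    sequence: str,
    window_bp: int,
    shift_bp: int,
    layout: GenomeLayout | None = None,
    anchor: int = 1,
) -> ATProfile:
    """Sliding-window A+T fraction.

    Windows start at ``anchor`` (1-based) and advance by ``shift_bp``;
    the reported coordinate is the window centre.  On circular genomes
    windows wrap across the origin.  Ambiguous bases (anything outside
    ACGT, case-insensitive) are excluded from both numerator and
    denominator; a window with no unambiguous base is NaN.
    """
    seq = str(sequence).upper()
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    circular = layout.circular if layout is not None else True
    if layout is not None and layout.length != L:
        raise ValueError("sequence length does not match layout")
    if not (1 <= window_bp <= L):
        raise ValueError("window must be between 1 and the genome length")
    if shift_bp < 1:
        raise ValueError("shift must be >= 1")

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    is_acgt = is_at | (arr == ord("C")) | (arr == ord("G"))

    if circular:
        starts0 = np.arange(anchor - 1, anchor - 1 + L, shift_bp) % L
        starts0 = starts0[starts0 < L][: int(np.ceil(L / shift_bp))]
        # doubled-array cumulative sums handle the wrap
        at2 = np.concatenate([is_at, is_at[: window_bp - 1]]) if window_bp > 1 else is_at
        ok2 = np.concatenate([is_acgt, is_acgt[: window_bp - 1]]) if window_bp > 1 else is_acgt
        cat = np.concatenate([[0], np.cumsum(at2)])
        cok = np.concatenate([[0], np.cumsum(ok2)])
    else:
        starts0 = np.arange(anchor - 1, L - window_bp + 1, shift_bp)
        cat = np.concatenate([[0], np.cumsum(is_at)])
        cok = np.concatenate([[0], np.cumsum(is_acgt)])

    at_counts = cat[starts0 + window_bp] - cat[starts0]
    ok_counts = cok[starts0 + window_bp] - cok[starts0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(ok_counts > 0, at_counts / np.maximum(ok_counts, 1), np.nan)
    centers = starts0 + 1.0 + (window_bp - 1) / 2.0
    if circular:
        centers = (centers - 1.0) % L + 1.0
    return ATProfile(window_bp=window_bp, shift_bp=shift_bp, centers=centers, at_fraction=frac)


# ---------------------------------------------------------------------------
# occupancy overlap


def _segments(start: int, end: int, L: int, circular: bool) -> list[tuple[int, int]]:
    """Split a possibly-wrapping 1-based closed span into linear segments."""
    if not circular:
        return [(max(start, 1), min(end, L))] if end >= 1 and start <= L else []
    span = end - start + 1
    if span >= L:
        return [(1, L)]
    s = (start - 1) % L + 1
    e = (end - 1) % L + 1
    if s <= e:
        return [(s, e)]
    return [(s, L), (1, e)]


def _point_interval_distance(pos: int, start: int, end: int, layout: GenomeLayout) -> int:
    if start <= pos <= end:
        return 0
    return min(circular_distance(pos, start, layout), circular_distance(pos, end, layout))


def occupancy_overlap(
    site: InsertionSite | int,
    sets: list[IntervalSet],
    flank_bp: int,
    layout: GenomeLayout,
) -> dict[str, OverlapReport]:
    """Intersect a site's flanked window with occupancy tracks.

    For each track, reports whether ``[position - flank, position + flank]``
    intersects any interval, the total overlapped bp within the flank,
    and (when there is no overlap) the distance from the site to the
    nearest interval.
    """
    pos = site.position if isinstance(site, InsertionSite) else int(site)
    _check_coord(pos, layout)
    if flank_bp < 0:
        raise ValueError("flank must be >= 0")
    query = _segments(pos - flank_bp, pos + flank_bp, layout.length, layout.circular)
    out: dict[str, OverlapReport] = {}
    for track in sets:
        pieces = []
        for s, e in track.intervals:
            for qs, qe in query:
                lo, hi = max(s, qs), min(e, qe)
                if hi >= lo:
                    pieces.append((lo, hi))
        total = 0
        last_end = 0
        for lo, hi in sorted(pieces):  # union, so stacked intervals don't double-count
            lo = max(lo, last_end + 1)
            if hi >= lo:
                total += hi - lo + 1
                last_end = max(last_end, hi)
        if total > 0:
            nearest = 0
        elif track.intervals:
            nearest = min(_point_interval_distance(pos, s, e, layout) for s, e in track.intervals)
        else:
            nearest = None
        out[track.name] = OverlapReport(
            track=track.name,
            overlaps=total > 0,
            overlap_bp=total,
            nearest_distance=nearest,
        )
    return out


def binned_counts(features: IntervalSet, n_bins: int, layout: GenomeLayout) -> np.ndarray:
    """Histogram of feature midpoints over equal circular genome bins.

    The genome is split into ``n_bins`` equal arcs starting at
    coordinate 1; each feature contributes one count at the bin holding
    its midpoint, so the counts always sum to the number of features.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts = np.zeros(n_bins, dtype=int)
    L = layout.length
    for s, e in features.intervals:
        mid2 = s + e - 2  # 2 * (0-based midpoint)
        idx = min((mid2 * n_bins) // (2 * L), n_bins - 1)
        counts[idx] += 1
    return counts


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> str:
    """Read the first record of a FASTA file as an uppercase string."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def read_bed(path, name: str | None = None) -> IntervalSet:
    """Read a BED-like track (0-based half-open) into 1-based closed intervals."""
    intervals: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            start0, end0 = int(parts[1]), int(parts[2])
            intervals.append((start0 + 1, end0))
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return IntervalSet(name=name, intervals=intervals).validate()


def write_bed(track: IntervalSet, path, chrom: str = "genome") -> None:
    with open(path, "w") as fh:
        for s, e in track.intervals:
            fh.write(f"{chrom}\t{s - 1}\t{e}\t{track.name}\n")


def write_bedgraph(profile: ATProfile, path, chrom: str = "genome") -> None:
    """Write an AT profile as a bedGraph-style 4-column file (window centres)."""
    half = profile.shift_bp / 2.0
    with open(path, "w") as fh:
        for c, v in zip(profile.centers, profile.at_fraction):
            if np.isnan(v):
                continue
            s = max(0, int(round(c - 1 - half)))
            e = int(round(c - 1 + half))
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6f}\n")
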