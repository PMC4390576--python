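"""Cooper-Helmstetter gene copy number and dosage-expected expression.

In a steadily growing bacterial population with overlapping replication
rounds, the average copy number of a locus depends on its distance from
the replication origin:

    gcn(m') = 2 ** ((C * (1 - m') + D) / tau)

where ``C`` is the chromosome replication time, ``D`` the time from
replication termination to cell division, ``tau`` the population doubling
time, and ``m'`` the relative map position (0 at oriC, 1 at the
terminus).  Genes near the origin are present in more copies per cell at
fast growth; normalising observed expression by gcn separates this pure
dosage effect from genuine position-specific regulation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReplicationParams",
    "DosageCurve",
    "gene_copy_number",
    "dosage_expected_curve",
    "fit_dosage_scale",
    "dosage_normalize",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class ReplicationParams:
    """Replication cycle parameters, both in minutes.

    C : time to replicate the chromosome (C period), > 0.
    D : time from replication termination to division (D period), >= 0.

    No defaults are provided: C and D depend on strain and growth medium
    and must be supplied explicitly (see ``examples/params.yml`` for
    plausible example values).
    """

    C: float
    D: float

    def __post_init__(self) -> None:
        if not (self.C > 0):
            raise ValueError(f"C period must be > 0, got {self.C}")
        if self.D < 0:
            raise ValueError(f"D period must be >= 0, got {self.D}")


@dataclass(frozen=True)
class DosageCurve:
    """Expected relative expression along the origin-terminus axis.

    ``expected = scale * gcn``; the single free parameter ``scale`` maps
    copy number to concentration units (arbitrary instrument units).
    """

    positions: np.ndarray  # m' values in [0, 1]
    gcn: np.ndarray
    tau: float
    scale: float

    @property
    def expected(self) -> np.ndarray:
        return self.scale * self.gcn


def gene_copy_number(m_prime, tau, params: ReplicationParams):
    """Average gene copy number at relative position ``m_prime``.

    Parameters
    ----------
    m_prime : float or array-like in [0, 1]
        Relative distance from the origin (0 = oriC, 1 = terminus).
    tau : float or array-like, minutes, > 0
        Population doubling time.  ``tau = inf`` is allowed and gives the
        non-replicating limit gcn -> 1 (for D = 0) or 2**(D/tau) -> 1.
    params : ReplicationParams

    Returns
    -------
    float or ndarray, copy number >= 1 (for D >= 0).
    """
    m = np.asarray(m_prime, dtype=float)
    t = np.asarray(tau, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("m_prime must lie in [0, 1]")
    if np.any(t <= 0):
        raise ValueError("tau must be > 0")
    gcn = 2.0 ** ((params.C * (1.0 - m) + params.D) / t)
    if gcn.ndim == 0:
        return float(gcn)
    return gcn


def dosage_expected_curve(
    positions,
    tau: float,
    params: ReplicationParams,
    anchor_position: float,
    anchor_value: float,
) -> DosageCurve:
    """Expected concentration vs map position, anchored at one site.

    expected(s) = anchor_value * gcn(s) / gcn(anchor): a single free
    scale, fixed by requiring the curve to pass through
    (anchor_position, anchor_value).
    """
    if not (anchor_value > 0):
        raise ValueError("anchor_value must be > 0")
    pos = np.atleast_1d(np.asarray(positions, dtype=float))
    gcn = np.atleast_1d(gene_copy_number(pos, tau, params))
    gcn_anchor = gene_copy_number(float(anchor_position), tau, params)
    scale = anchor_value / gcn_anchor
    return DosageCurve(positions=pos, gcn=gcn, tau=float(tau), scale=scale)


def fit_dosage_scale(observed, gcn, exclude=None) -> float:
    """Least-squares single scale mapping copy number to concentration.

    Minimises sum over sites of (observed - scale * gcn)**2, optionally
    excluding flagged sites (e.g. suspected position-specific outliers).
    """
    obs = np.asarray(observed, dtype=float)
    g = np.asarray(gcn, dtype=float)
    keep = np.isfinite(obs) & np.isfinite(g)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    if not keep.any():
        raise ValueError("no sites left to fit the dosage scale")
    denom = float(np.sum(g[keep] ** 2))
    if denom == 0:
        raise ValueError("degenerate copy numbers (all zero)")
    return float(np.sum(obs[keep] * g[keep]) / denom)


def dosage_normalize(observed, m_prime, tau, params: ReplicationParams):
    """Divide observed expression by the expected copy number.

    If expression were fully explained by gene dosage, the corrected
    values would be equal across sites.
    """
    obs = np.asarray(observed, dtype=float)
    gcn = np.asarray(gene_copy_number(m_prime, tau, params), dtype=float)
    if obs.shape != gcn.shape:
        raise ValueError("observed and m_prime must have matching shapes")
    return obs / gcn
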