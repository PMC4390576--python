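"""Cross-position comparison of reporter expression.

Combines the per-well growth/reporter kinetics with the gene-dosage
model to ask the central question: after accounting for replication-
driven copy-number differences, does a reporter's chromosomal position
still change its expression?

Workflow (the `PositionEffectModel`):

1. sample each well's reporter concentration at its growth-phase
   landmarks (exponential = t_exp, entry into stationary = t_entry,
   stationary = t_stat);
2. aggregate replicates per (site, medium, temperature, phase) into
   mean +/- SEM;
3. normalise to a reference site within each stratum (delta-method SEM
   propagation, treating site and reference wells as independent);
4. compute the per-site repression index
       index = log2(observed / dosage-expected)
   where the dosage expectation is the Cooper-Helmstetter copy-number
   curve with a single least-squares scale (outlier sites excluded from
   the scale fit and refit once).  index << 0 flags position-specific
   repression; differences between sites are anchor-independent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage import ReplicationParams, fit_dosage_scale, gene_copy_number
from .growth import GrowthCurveResults, sample_series

__all__ = [
    "ReplicateStats",
    "aggregate_replicates",
    "normalize_to_reference",
    "repression_index",
    "phase_table",
    "PositionEffectModel",
    "PositionEffectResults",
]

PHASES = ("exp", "entry", "stat")
_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ReplicateStats:
    mean: float
    sem: float
    n: int
    single_replicate: bool = False


def aggregate_replicates(values) -> ReplicateStats:
    """Mean and standard error over independent experiments.

    SEM uses the sample SD (n-1 denominator) over sqrt(n); for a single
    replicate the SEM is reported as 0 with a flag rather than NaN.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to aggregate")
    n = int(v.size)
    mean = float(v.mean())
    if n == 1:
        return ReplicateStats(mean=mean, sem=0.0, n=1, single_replicate=True)
    sem = float(v.std(ddof=1) / np.sqrt(n))
    return ReplicateStats(mean=mean, sem=sem, n=n)


def normalize_to_reference(table: pd.DataFrame, reference_label: str) -> pd.DataFrame:
    """Add ratio-to-reference columns within each (medium, temperature, phase) stratum.

    ratio = mean(site) / mean(reference); its SEM by the first-order
    delta method assuming independent site and reference measurements:
    ratio * sqrt((sem_s/mean_s)^2 + (sem_r/mean_r)^2).
    """
    strata_cols = [c for c in ("medium", "temperature", "phase") if c in table.columns]
    out = table.copy()
    out["ratio_to_reference"] = np.nan
    out["ratio_sem"] = np.nan
    missing = []
    for key, grp in out.groupby(strata_cols, dropna=False) if strata_cols else [((), out)]:
        ref = grp[grp["site_label"] == reference_label]
        if ref.empty or not np.isfinite(ref["mean"].iloc[0]):
            missing.append(key)
            continue
        rm, rs = float(ref["mean"].iloc[0]), float(ref["sem"].iloc[0])
        ratio = grp["mean"] / rm
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.sqrt((grp["sem"] / grp["mean"]) ** 2 + (rs / rm) ** 2)
        out.loc[grp.index, "ratio_to_reference"] = ratio
        out.loc[grp.index, "ratio_sem"] = np.abs(ratio) * rel
    if missing:
        raise ValueError(
            f"reference site {reference_label!r} missing in strata: {missing}"
        )
    return out


def repression_index(
    observed,
    m_prime,
    tau: float,
    params: ReplicationParams,
    observed_sem=None,
    exclude_threshold: float = 0.5,
):
    """Per-site log2 deviation from the gene-dosage expectation.

    The expectation is ``scale * gcn(m')`` with a single least-squares
    scale.  Sites whose first-pass |index| exceeds ``exclude_threshold``
    log2 units are dropped from the scale fit and the scale refit once,
    so a strongly repressed site does not drag the baseline down.

    Returns ``(index, index_sem, flagged)``; ``index_sem`` (delta
    method, sem/(mean*ln2)) is NaN when no SEMs are given, and
    ``flagged`` marks sites with |index| > 2 * index_sem outside the
    noise band.
    """
    obs = np.asarray(observed, dtype=float)
    gcn = np.atleast_1d(np.asarray(gene_copy_number(m_prime, tau, params), dtype=float))
    scale = fit_dosage_scale(obs, gcn)
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.log2(obs / (scale * gcn))
    outliers = np.abs(index) > exclude_threshold
    if outliers.any() and not outliers.all():
        scale = fit_dosage_scale(obs, gcn, exclude=outliers)
        with np.errstate(invalid="ignore", divide="ignore"):
            index = np.log2(obs / (scale * gcn))
    if observed_sem is not None:
        sem = np.asarray(observed_sem, dtype=float) / (np.abs(obs) * _LN2)
    else:
        sem = np.full_like(index, np.nan)
    with np.errstate(invalid="ignore"):
        flagged = np.abs(index) > 2.0 * sem
    flagged = np.where(np.isfinite(sem), flagged, False).astype(bool)
    return index, sem, flagged


def phase_table(results: GrowthCurveResults, eps_alpha_sem_flag: bool = True) -> pd.DataFrame:
    """Aggregate per-well phase-landmark concentrations into a tidy table.

    Each well contributes its concentration linearly interpolated at
    t_exp / t_entry / t_stat; wells are then pooled per
    (site_label, medium, temperature, phase) into mean, SEM and n.
    Absent landmarks leave the phase cell out (never imputed).
    """
    meta = {w.well_id: w for w in results.model.plate.samples()}
    per_well = []
    for wid, lm in results.landmarks.items():
        p = results.profiles[wid]
        w = meta[wid]
        for phase, t in zip(PHASES, (lm.t_exp, lm.t_entry, lm.t_stat)):
            if t is None:
                continue
            c = sample_series(p.times, p.conc, t)
            if not np.isfinite(c):
                continue
            per_well.append(
                {
                    "well_id": wid,
                    "site_label": w.site_label,
                    "medium": w.medium,
                    "temperature": w.temperature,
                    "replicate": w.replicate_id,
                    "phase": phase,
                    "conc": c,
                }
            )
    pw = pd.DataFrame(per_well)
    if pw.empty:
        return pd.DataFrame(
            columns=["site_label", "medium", "temperature", "phase", "mean", "sem", "n", "single_replicate"]
        )
    rows = []
    for key, grp in pw.groupby(["site_label", "medium", "temperature", "phase"], dropna=False):
        st = aggregate_replicates(grp["conc"])
        rows.append(
            dict(
                zip(["site_label", "medium", "temperature", "phase"], key),
                mean=st.mean,
                sem=st.sem,
                n=st.n,
                single_replicate=st.single_replicate,
            )
        )
    return pd.DataFrame(rows)


class PositionEffectModel:
    """Position-effect analysis across reporter insertion sites.

    Parameters
    ----------
    growth_results : GrowthCurveResults
        Fitted growth/reporter kinetics (provides concentrations,
        landmarks and the measured growth rates).
    sites : pd.DataFrame
        Columns ``site_label`` and ``m_prime`` (relative map position;
        see `nucleopos.genome.relative_position`).
    replication : ReplicationParams
        C and D periods for the copy-number model.
    reference : str, optional
        Site label used for ratio normalisation (e.g. the terminal
        site); skipped when None.
    tau : float, optional
        Doubling time (minutes) for the dosage model.  By default it is
        measured from the data: ln2 / median alpha_max over the wells of
        each (medium, temperature) condition.
    """

    def __init__(
        self,
        growth_results: GrowthCurveResults,
        sites: pd.DataFrame,
        replication: ReplicationParams,
        reference: str | None = None,
        tau: float | None = None,
        exclude_threshold: float = 0.5,
    ) -> None:
        self.growth_results = growth_results
        self.sites = sites
        self.replication = replication
        self.reference = reference
        self.tau = tau
        self.exclude_threshold = exclude_threshold

    def _measured_tau(self, medium, temperature) -> float:
        meta = {w.well_id: w for w in self.growth_results.model.plate.samples()}
        amax = [
            lm.alpha_max
            for wid, lm in self.growth_results.landmarks.items()
            if lm.alpha_max is not None
            and meta[wid].medium == medium
            and (meta[wid].temperature == temperature or (pd.isna(temperature) and meta[wid].temperature is None))
        ]
        amax = [a for a in amax if a and a > 0]
        if not amax:
            raise ValueError(f"no growth-rate estimate for condition ({medium}, {temperature})")
        return _LN2 / float(np.median(amax))

    def fit(self) -> "PositionEffectResults":
        table = phase_table(self.growth_results)
        if self.reference is not None and not table.empty:
            table = normalize_to_reference(table, self.reference)
        m_map = dict(zip(self.sites["site_label"], self.sites["m_prime"]))

        table["m_prime"] = table["site_label"].map(m_map)
        table["tau_min"] = np.nan
        table["gcn"] = np.nan
        table["dosage_corrected"] = np.nan
        table["repression_index"] = np.nan
        table["repression_index_sem"] = np.nan
        table["repressed_flag"] = False

        conditions = {}
        for (medium, temperature), grp in table.groupby(["medium", "temperature"], dropna=False):
            tau = self.tau if self.tau is not None else self._measured_tau(medium, temperature)
            conditions[(medium, temperature)] = tau
            idx = grp.index
            m = table.loc[idx, "m_prime"].to_numpy(float)
            gcn = gene_copy_number(np.clip(m, 0, 1), tau, self.replication)
            table.loc[idx, "tau_min"] = tau
            table.loc[idx, "gcn"] = gcn
            table.loc[idx, "dosage_corrected"] = table.loc[idx, "mean"] / gcn
            # repression index per phase within the condition
            for phase, pgrp in grp.groupby("phase"):
                pidx = pgrp.index
                obs = table.loc[pidx, "mean"].to_numpy(float)
                mm = table.loc[pidx, "m_prime"].to_numpy(float)
                sem = table.loc[pidx, "sem"].to_numpy(float)
                if len(pidx) < 2 or not np.all(np.isfinite(mm)):
                    continue
                ri, ri_sem, flagged = repression_index(
                    obs, mm, tau, self.replication,
                    observed_sem=sem, exclude_threshold=self.exclude_threshold,
                )
                table.loc[pidx, "repression_index"] = ri
                table.loc[pidx, "repression_index_sem"] = ri_sem
                table.loc[pidx, "repressed_flag"] = flagged & (ri < 0)
        return PositionEffectResults(model=self, table=table, tau_by_condition=conditions)


@dataclass
class PositionEffectResults:
    model: PositionEffectModel
    table: pd.DataFrame
    tau_by_condition: dict

    def summary(self) -> str:
        lines = ["Position-effect analysis", "=" * 60]
        for (medium, temp), tau in self.tau_by_condition.items():
            lines.append(f"condition medium={medium!r} T={temp}: tau = {tau:.1f} min")
        cols = [
            "site_label", "medium", "phase", "mean", "sem", "n",
            "gcn", "dosage_corrected", "repression_index",
        ]
        cols = [c for c in cols if c in self.table.columns]
        if "ratio_to_reference" in self.table.columns:
            cols.append("ratio_to_reference")
        with pd.option_context("display.width", 200, "display.max_columns", 50):
            lines.append(self.table[cols].round(4).to_string(index=False))
        return "\n".join(lines)

    def repression(self, phase: str = "exp") -> pd.DataFrame:
        """Per-site repression index in one growth phase."""
        sub = self.table[self.table["phase"] == phase]
        return sub[
            ["site_label", "medium", "temperature", "m_prime", "repression_index",
             "repression_index_sem", "repressed_flag"]
        ].reset_index(drop=True)

    def plot_dosage_curve(self, phase: str = "exp", ax=None):
        """Observed concentration vs m' with the dosage-expectation curve."""
        import matplotlib.pyplot as plt

        from .dosage import dosage_expected_curve, fit_dosage_scale

        sub = self.table[(self.table["phase"] == phase) & np.isfinite(self.table["m_prime"])]
        if ax is None:
            _, ax = plt.subplots()
        for (medium, temp), grp in sub.groupby(["medium", "temperature"], dropna=False):
            tau = self.tau_by_condition[(medium, temp)]
            ax.errorbar(grp["m_prime"], grp["mean"], yerr=grp["sem"], fmt="o", label=f"{medium}")
            scale = fit_dosage_scale(grp["mean"].to_numpy(), grp["gcn"].to_numpy())
            mgrid = np.linspace(0, 1, 101)
            curve = dosage_expected_curve(mgrid, tau, self.model.replication, 0.0, 1.0)
            ax.plot(mgrid, scale * curve.gcn, "k:")
        ax.set_xlabel("relative position m' (0 = oriC, 1 = ter)")
        ax.set_ylabel("concentration (fluorescence / OD)")
        ax.legend()
        return ax
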