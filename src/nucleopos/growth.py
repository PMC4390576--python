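"""Growth and reporter kinetics from plate-reader time series.

Raw per-well OD600 and fluorescence series are turned into:

* blanked OD (medium-only blank subtracted, floored at a detection
  floor) and background-subtracted fluorescence (non-fluorescent strain
  in the same medium subtracted);
* reporter concentration  c(t) = F(t) / OD(t)   (fluorescence per OD,
  a proxy for protein per cell mass);
* instantaneous growth rate  alpha(t) = d(OD)/dt / OD, estimated as the
  slope of a centred local least-squares line fitted to ln(OD) -- exact
  for exponential growth and noise-robust (Savitzky-Golay, degree 1);
* doubling time  tau = ln(2) / alpha;
* promoter activity  (dF/dt) / OD  with dF/dt from the same local-slope
  estimator applied to the fluorescence on a linear scale;
* growth-phase landmarks: t_exp (maximum growth rate), t_entry (first
  downward crossing of half-maximal growth rate), t_stat (growth rate
  effectively zero).

The model/results pair (`GrowthCurveModel` -> `GrowthCurveResults`)
runs the whole pipeline for every sample well of a plate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate import PlateTimeSeries

__all__ = [
    "GrowthProfile",
    "PhaseLandmarks",
    "GrowthCurveModel",
    "GrowthCurveResults",
    "blank_od",
    "subtract_background_fluorescence",
    "concentration",
    "growth_rate",
    "doubling_time",
    "promoter_activity",
    "phase_landmarks",
    "sample_series",
]

_LN2 = float(np.log(2.0))


@dataclass
class GrowthProfile:
    """Derived per-well series on the plate's time grid.

    All series are NaN where undefined; ``valid_mask`` is False wherever
    the blanked OD is at or below the detection floor.
    """

    well_id: str
    times: np.ndarray
    od: np.ndarray
    fl: np.ndarray
    conc: np.ndarray
    alpha: np.ndarray
    alpha_se: np.ndarray
    tau: np.ndarray
    activity: np.ndarray
    valid_mask: np.ndarray
    flags: list[str] = field(default_factory=list)


@dataclass
class PhaseLandmarks:
    """Growth-phase landmark times (minutes) for one well.

    t_exp    : time of maximum (smoothed) growth rate.
    t_entry  : first downward crossing of alpha_max / 2 after t_exp
               (linearly interpolated between bracketing samples);
               marks entry into stationary phase.
    t_stat   : first sample after t_entry where the growth rate has
               fallen to <= eps_alpha * alpha_max (stationary phase).
    Landmarks that do not exist in the observed window are None, with an
    explanatory flag -- they are never extrapolated.
    """

    t_exp: float | None
    t_entry: float | None
    t_stat: float | None
    alpha_max: float | None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# local least-squares slope (shared derivative estimator)


def _local_slope(y: np.ndarray, times: np.ndarray, window: int, valid: np.ndarray):
    """Centred local least-squares slope of y(t) over ``window`` points.

    Returns (slope, standard error) arrays, NaN at the window edges and
    wherever any point of the centred window is invalid.  The SE is the
    usual residual-based slope SE of the local fit (w - 2 dof); it is
    used downstream for precision weighting, not for inference.
    """
    n = len(y)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    slope = np.full(n, np.nan)
    se = np.full(n, np.nan)
    if n < window:
        return slope, se
    h = window // 2
    ok = valid & np.isfinite(y)
    yw = np.lib.stride_tricks.sliding_window_view(y, window)
    tw = np.lib.stride_tricks.sliding_window_view(times, window)
    okw = np.lib.stride_tricks.sliding_window_view(ok, window).all(axis=1)
    tbar = tw.mean(axis=1, keepdims=True)
    ybar = yw.mean(axis=1, keepdims=True)
    dt = tw - tbar
    dy = yw - ybar
    sxx = np.sum(dt * dt, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.sum(dt * dy, axis=1) / sxx
        resid = dy - b[:, None] * dt
        s2 = np.sum(resid * resid, axis=1) / (window - 2)
        b_se = np.sqrt(s2 / sxx)
    b = np.where(okw, b, np.nan)
    b_se = np.where(okw, b_se, np.nan)
    slope[h : n - h] = b
    se[h : n - h] = b_se
    sxx_full = np.full(n, np.nan)
    sxx_full[h : n - h] = sxx
    return slope, se, sxx_full


def _robust_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD from second differences (MAD-based).

    For a smooth signal sampled densely, second differences are
    dominated by measurement noise with variance 6 * sigma^2.
    """
    x = x[np.isfinite(x)]
    if len(x) < 4:
        return 0.0
    d2 = np.diff(x, 2)
    return 1.4826 * float(np.median(np.abs(d2))) / np.sqrt(6.0)


# ---------------------------------------------------------------------------
# operations


def blank_od(
    plate: PlateTimeSeries,
    eps_od_min: float = 1e-4,
    blank_warn_fraction: float = 0.1,
):
    """Subtract the medium-only blank from every non-blank well's OD.

    Returns ``(od, blank_sd, floor, flags)`` where ``od`` maps well_id to
    the blanked OD series floored at the per-timepoint detection floor
    ``max(eps_od_min, 3 * blank_sd)``, and ``flags`` maps well_id to any
    warnings raised.  A well is below detection wherever its raw signal
    minus the blank does not exceed the floor.
    """
    blanks = plate.blanks()
    if not blanks:
        raise ValueError("no blank (medium-only) wells on the plate; cannot blank OD")
    blank_stack = np.vstack([w.od_raw for w in blanks])
    blank_mean = blank_stack.mean(axis=0)
    blank_sd = blank_stack.std(axis=0, ddof=1) if len(blanks) > 1 else np.zeros_like(blank_mean)
    floor = np.maximum(eps_od_min, 3.0 * blank_sd)

    out: dict[str, np.ndarray] = {}
    flags: dict[str, list[str]] = {}
    sample_medians = [np.median(w.od_raw - blank_mean) for w in plate.samples()]
    median_od = float(np.median(sample_medians)) if sample_medians else np.nan
    noisy_blank = np.isfinite(median_od) and median_od > 0 and np.nanmax(blank_sd) > blank_warn_fraction * median_od
    for w in plate.wells:
        if w.is_blank:
            continue
        net = w.od_raw - blank_mean
        out[w.well_id] = np.maximum(net, floor)
        flags[w.well_id] = ["noisy_blank"] if noisy_blank else []
    if noisy_blank:
        warnings.warn("blank OD scatter exceeds the configured fraction of the median sample OD")
    return out, blank_sd, floor, flags


def subtract_background_fluorescence(plate: PlateTimeSeries):
    """Subtract the matched non-fluorescent (background-strain) wells.

    Background wells are matched by growth medium.  Negative net values
    are retained (clipping would bias averages near zero) but flagged.
    Returns ``(fl, flags)`` keyed by well_id, covering sample wells only.
    """
    out: dict[str, np.ndarray] = {}
    flags: dict[str, list[str]] = {}
    for w in plate.samples():
        bg = plate.backgrounds(medium=w.medium)
        if not bg:
            raise ValueError(
                f"no background (non-fluorescent) well grown in medium {w.medium!r} "
                f"to correct well {w.well_id}"
            )
        bg_mean = np.vstack([b.fl_raw for b in bg]).mean(axis=0)
        net = w.fl_raw - bg_mean
        out[w.well_id] = net
        flags[w.well_id] = ["negative_fluorescence"] if np.any(net < 0) else []
    return out, flags


def concentration(od: np.ndarray, fl: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Reporter concentration F/OD, NaN where OD is below detection."""
    conc = np.full_like(np.asarray(od, dtype=float), np.nan)
    v = np.asarray(valid, dtype=bool)
    conc[v] = np.asarray(fl, dtype=float)[v] / np.asarray(od, dtype=float)[v]
    return conc


def growth_rate(od: np.ndarray, times: np.ndarray, window: int = 5, valid: np.ndarray | None = None):
    """Instantaneous growth rate alpha(t) = d ln(OD)/dt (per minute).

    Slope of a centred ``window``-point least-squares line on ln(OD);
    exact for exponential growth.  Returns (alpha, alpha_se).
    """
    od = np.asarray(od, dtype=float)
    if valid is None:
        valid = np.isfinite(od) & (od > 0)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(od) & (od > 0)
    if valid.sum() < window:
        warnings.warn("fewer valid points than the smoothing window; growth rate fully masked")
        return np.full(len(od), np.nan), np.full(len(od), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        lnod = np.where(valid, np.log(np.where(od > 0, od, np.nan)), np.nan)
    alpha, se_resid, sxx = _local_slope(lnod, np.asarray(times, dtype=float), window, valid)
    # noise-floor SE: ln(OD) noise is ~sigma_od/OD, so even a window whose
    # residuals happen to be small cannot claim better precision than the
    # plate's measured OD noise allows
    sigma_od = _robust_noise_sd(np.where(valid, od, np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        se_floor = sigma_od / (od * np.sqrt(sxx))
    se = np.where(np.isfinite(alpha), np.fmax(se_resid, se_floor), np.nan)
    return alpha, se


def doubling_time(alpha: np.ndarray, alpha_floor: float = 0.0) -> np.ndarray:
    """Doubling time tau = ln(2)/alpha, NaN where alpha <= alpha_floor."""
    a = np.asarray(alpha, dtype=float)
    tau = np.full_like(a, np.nan)
    pos = np.isfinite(a) & (a > alpha_floor)
    tau[pos] = _LN2 / a[pos]
    return tau


def promoter_activity(
    od: np.ndarray,
    fl: np.ndarray,
    times: np.ndarray,
    window: int = 5,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Promoter activity (dF/dt)/OD: reporter synthesis rate per biomass.

    dF/dt uses the same local-slope estimator as the growth rate but on
    the linear fluorescence scale.
    """
    od = np.asarray(od, dtype=float)
    fl = np.asarray(fl, dtype=float)
    if valid is None:
        valid = np.isfinite(od) & (od > 0)
    else:
        valid = np.asarray(valid, dtype=bool)
    ok = valid & np.isfinite(fl)
    if ok.sum() < window:
        warnings.warn("fewer valid points than the smoothing window; activity fully masked")
        return np.full(len(od), np.nan)
    dfdt, _, _ = _local_slope(np.where(ok, fl, np.nan), np.asarray(times, dtype=float), window, ok)
    with np.errstate(invalid="ignore", divide="ignore"):
        act = dfdt / od
    act[~valid] = np.nan
    return act


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware rolling median with edge-shrinking windows."""
    n = len(x)
    h = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        chunk = x[max(0, i - h) : min(n, i + h + 1)]
        chunk = chunk[np.isfinite(chunk)]
        if chunk.size:
            out[i] = np.median(chunk)
    return out


def _smooth_weighted(alpha, se, window):
    """Windowed weighted moving average of alpha (weights 1/se^2).

    The per-point slope SEs are first stabilised by a rolling median so
    that a window whose residuals are small by chance cannot dominate.
    Partial windows shrink at the edges so no points are lost; invalid
    points carry zero weight.  With ``window=1`` the series is returned
    unchanged (geometric landmark definitions then apply exactly).

    Returns ``(smoothed, smoothed_se)`` where ``smoothed_se`` is the
    nominal SE of the weighted mean (None when no SEs were supplied).
    """
    a = np.asarray(alpha, dtype=float)
    n = len(a)
    ok = np.isfinite(a)
    if window <= 1:
        return a.copy(), None
    if se is not None:
        se_stab = _rolling_median(np.asarray(se, dtype=float), window)
        good = np.isfinite(se_stab) & (se_stab > 0)
        floor = np.min(se_stab[good]) if good.any() else 1.0
        w = np.where(ok & good, 1.0 / np.maximum(se_stab, max(floor, 1e-300)) ** 2, 0.0)
    else:
        w = ok.astype(float)
    h = window // 2
    out = np.full(n, np.nan)
    out_se = np.full(n, np.nan)
    aw = np.where(ok, a, 0.0) * w
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        denom = w[lo:hi].sum()
        if denom > 0:
            out[i] = aw[lo:hi].sum() / denom
            out_se[i] = 1.0 / np.sqrt(denom)
    return out, (out_se if se is not None else None)


def phase_landmarks(
    alpha: np.ndarray,
    times: np.ndarray,
    alpha_se: np.ndarray | None = None,
    smooth_window: int = 1,
    eps_alpha: float = 0.02,
    lcb_z: float = 3.0,
) -> PhaseLandmarks:
    """Locate the growth-phase landmarks on a growth-rate series.

    ``smooth_window`` > 1 first smooths alpha with a precision-weighted
    moving average (weights 1/alpha_se**2 when SEs are available), which
    keeps the very noisy low-OD estimates from dominating the maximum.
    When SEs are available, t_exp maximises the lower confidence bound
    ``smoothed - lcb_z * SE`` rather than the noisy value itself: an
    estimate whose uncertainty is comparable to its value cannot claim
    the maximum merely by fluctuating high (the maximum of raw noisy
    growth rates is severely biased upward at low OD).
    Ties break to the earliest timepoint; crossings are found by linear
    interpolation; t_stat is reported at the sample (not interpolated).
    """
    times = np.asarray(times, dtype=float)
    sm, sm_se = _smooth_weighted(alpha, alpha_se, smooth_window)
    ok = np.isfinite(sm)
    flags: list[str] = []
    if not ok.any():
        return PhaseLandmarks(None, None, None, None, flags=["no_valid_growth_rate"])
    candidates = ok.copy()
    score = sm.copy()
    if sm_se is not None and (ok & np.isfinite(sm_se)).any():
        finite = ok & np.isfinite(sm_se)
        # reference growth rate from the best-measured decile of points,
        # then admit only points whose SE is small against that reference:
        # this keeps edge-of-detection estimates (whose SEs are themselves
        # unreliable) out of the competition entirely
        se_ref = np.nanpercentile(sm_se[finite], 10)
        ref_pts = finite & (sm_se <= 2.0 * se_ref)
        alpha_ref = float(np.max(sm[ref_pts])) if ref_pts.any() else 0.0
        gate = finite & (sm_se <= alpha_ref / 3.0) if alpha_ref > 0 else finite
        if gate.any():
            candidates = gate
        else:
            candidates = finite
            flags.append("low_snr_growth_rate")
        score = np.where(candidates, sm - lcb_z * sm_se, -np.inf)
    else:
        score = np.where(ok, score, -np.inf)
    i_exp = int(np.argmax(score))  # np.argmax returns the earliest maximum
    alpha_max = float(sm[i_exp])
    t_exp = float(times[i_exp])

    t_entry = None
    t_stat = None
    if alpha_max <= 0:
        flags.append("nonpositive_alpha_max")
        return PhaseLandmarks(t_exp, None, None, alpha_max, flags=flags)

    half = alpha_max / 2.0
    i_entry = None
    prev = i_exp
    for i in range(i_exp + 1, len(sm)):
        if not ok[i]:
            continue
        if sm[i] < half and sm[prev] >= half:
            frac = (sm[prev] - half) / (sm[prev] - sm[i])
            t_entry = float(times[prev] + frac * (times[i] - times[prev]))
            i_entry = i
            break
        prev = i
    if t_entry is None:
        flags.append("still_exponential")
        return PhaseLandmarks(t_exp, None, None, alpha_max, flags=flags)

    thresh = eps_alpha * alpha_max
    for i in range(i_entry, len(sm)):
        if ok[i] and sm[i] <= thresh:
            t_stat = float(times[i])
            break
    if t_stat is None:
        flags.append("no_stationary_phase")
    return PhaseLandmarks(t_exp, t_entry, t_stat, alpha_max, flags=flags)


def sample_series(times, values, t: float) -> float:
    """Linearly interpolate a (possibly masked) series at time ``t``."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if not ok.any():
        return float("nan")
    tt, vv = times[ok], values[ok]
    if t < tt[0] or t > tt[-1]:
        return float("nan")
    return float(np.interp(t, tt, vv))


# ---------------------------------------------------------------------------
# model / results


class GrowthCurveModel:
    """Plate-reader growth and reporter kinetics for every sample well.

    Parameters
    ----------
    plate : PlateTimeSeries
        Raw plate run with blank and background-strain wells annotated.
    window : int, odd, default 5
        Points in the centred local least-squares derivative window
        (5 points = 25 min at 5-min sampling).
    eps_alpha : float, default 0.02
        Stationary-phase threshold as a fraction of alpha_max (a literal
        zero growth rate is never reached in noisy data).
    eps_od_min : float, default 1e-4
        Hard lower bound of the OD detection floor; the effective floor
        is ``max(eps_od_min, 3 * blank SD)`` per timepoint.
    landmark_smooth : int, odd, default 9
        Window of the precision-weighted smoothing applied to alpha
        before landmark detection (1 disables smoothing).
    """

    def __init__(
        self,
        plate: PlateTimeSeries,
        window: int = 5,
        eps_alpha: float = 0.02,
        eps_od_min: float = 1e-4,
        landmark_smooth: int = 9,
        blank_warn_fraction: float = 0.1,
    ) -> None:
        self.plate = plate
        self.window = int(window)
        self.eps_alpha = float(eps_alpha)
        self.eps_od_min = float(eps_od_min)
        self.landmark_smooth = int(landmark_smooth)
        self.blank_warn_fraction = float(blank_warn_fraction)

    def fit(self) -> "GrowthCurveResults":
        plate = self.plate
        od_map, blank_sd, floor, od_flags = blank_od(
            plate, eps_od_min=self.eps_od_min, blank_warn_fraction=self.blank_warn_fraction
        )
        fl_map, fl_flags = subtract_background_fluorescence(plate)

        profiles: dict[str, GrowthProfile] = {}
        landmarks: dict[str, PhaseLandmarks] = {}
        for w in plate.samples():
            od = od_map[w.well_id]
            fl = fl_map[w.well_id]
            valid = od > floor
            conc = concentration(od, fl, valid)
            alpha, alpha_se = growth_rate(od, plate.times, window=self.window, valid=valid)
            tau = doubling_time(alpha)
            act = promoter_activity(od, fl, plate.times, window=self.window, valid=valid)
            profiles[w.well_id] = GrowthProfile(
                well_id=w.well_id,
                times=plate.times,
                od=od,
                fl=fl,
                conc=conc,
                alpha=alpha,
                alpha_se=alpha_se,
                tau=tau,
                activity=act,
                valid_mask=valid,
                flags=sorted(set(od_flags[w.well_id]) | set(fl_flags[w.well_id])),
            )
            landmarks[w.well_id] = phase_landmarks(
                alpha,
                plate.times,
                alpha_se=alpha_se,
                smooth_window=self.landmark_smooth,
                eps_alpha=self.eps_alpha,
            )
        return GrowthCurveResults(
            model=self,
            profiles=profiles,
            landmarks=landmarks,
            blank_sd=blank_sd,
            detection_floor=floor,
        )


@dataclass
class GrowthCurveResults:
    model: GrowthCurveModel
    profiles: dict[str, GrowthProfile]
    landmarks: dict[str, PhaseLandmarks]
    blank_sd: np.ndarray
    detection_floor: np.ndarray

    def derived_frame(self) -> pd.DataFrame:
        """Long frame of all derived series (one row per well-timepoint)."""
        frames = []
        for wid, p in self.profiles.items():
            frames.append(
                pd.DataFrame(
                    {
                        "well_id": wid,
                        "time_min": p.times,
                        "od": p.od,
                        "fl": p.fl,
                        "conc": p.conc,
                        "alpha": p.alpha,
                        "tau": p.tau,
                        "activity": p.activity,
                        "valid": p.valid_mask.astype(int),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def landmarks_frame(self) -> pd.DataFrame:
        rows = []
        for wid, lm in self.landmarks.items():
            rows.append(
                {
                    "well_id": wid,
                    "t_exp": lm.t_exp,
                    "t_entry": lm.t_entry,
                    "t_stat": lm.t_stat,
                    "alpha_max": lm.alpha_max,
                    "flags": ";".join(lm.flags),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Per-well summary: growth parameters, landmarks, concentration at t_exp."""
        meta = {w.well_id: w for w in self.model.plate.samples()}
        rows = []
        for wid, lm in self.landmarks.items():
            p = self.profiles[wid]
            w = meta[wid]
            conc_exp = sample_series(p.times, p.conc, lm.t_exp) if lm.t_exp is not None else np.nan
            rows.append(
                {
                    "well_id": wid,
                    "site_label": w.site_label,
                    "medium": w.medium,
                    "replicate": w.replicate_id,
                    "alpha_max_per_min": lm.alpha_max,
                    "tau_min": (_LN2 / lm.alpha_max) if (lm.alpha_max or 0) > 0 else np.nan,
                    "t_exp_min": lm.t_exp,
                    "t_entry_min": lm.t_entry,
                    "t_stat_min": lm.t_stat,
                    "conc_at_t_exp": conc_exp,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.derived_frame().to_csv(os.path.join(outdir, "derived_series.csv"), index=False)
        self.landmarks_frame().to_csv(os.path.join(outdir, "landmarks.csv"), index=False)
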