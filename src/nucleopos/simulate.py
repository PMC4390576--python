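"""Synthetic data with known ground truth for every analysis input.

Generators (all pure functions of their config, seed included):

* ``simulate_plate`` -- a plate-reader run: lag-logistic growth, a
  reporter whose synthesis rate is production-rate x phase-dependent
  repression x gene copy number x biomass, plus medium blanks and a
  non-fluorescent background strain, with additive measurement noise;
* ``simulate_genome`` -- a circular genome with AT-rich islands planted
  in a uniform background plus phase-resolved occupancy tracks placed
  over the islands;
* ``simulate_cytometry`` -- log-normal scatter clouds with per-cell
  reporter fluorescence proportional to a planted expression factor.

Growth model: OD obeys dOD/dt = alpha(t) * OD with

    alpha(t) = alpha_max * s(t - lag) * (1 - OD / capacity)

where ``s`` is a logistic switch of width ``transition_sharpness``.
This lag-logistic has the closed-form solution

    OD(t) = K * od0 * E(t) / (K + od0 * (E(t) - 1)),
    E(t) = exp(alpha_max * S(t)),   S(t) = integral of s,

so the sampled OD is exact (no ODE solver error) and the true alpha(t)
is known analytically.

Reporter model: dF/dt = a * rho(phase(t)) * gcn(m', tau(t)) * OD(t),
with the quasi-static copy number gcn = 2**((C(1-m')+D) * alpha / ln2)
(which tends to 1 as growth stops).  In balanced exponential growth the
concentration F/OD plateaus at a * rho * gcn / alpha -- the
production/dilution balance used as an internal oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .cytometry import CytometryEvents
from .dosage import ReplicationParams
from .genome import GenomeLayout, IntervalSet
from .growth import PhaseLandmarks
from .plate import PlateTimeSeries, WellRecord

__all__ = [
    "GrowthParams",
    "NoiseParams",
    "SiteSpec",
    "PlateSimConfig",
    "GroundTruth",
    "IslandSpec",
    "GenomeSimConfig",
    "CytometrySimConfig",
    "simulate_growth",
    "simulate_reporter",
    "simulate_plate",
    "simulate_genome",
    "simulate_cytometry",
    "default_plate_config",
]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class GrowthParams:
    """Lag-logistic growth-curve parameters.

    Defaults emulate an overnight culture diluted 1:10,000 into minimal
    medium in a microplate: initial OD 3e-4, doubling time 60 min,
    90 min lag, saturation around OD 0.45.
    """

    od0: float = 3e-4
    alpha_max: float = _LN2 / 60.0  # per minute
    lag_min: float = 90.0
    capacity_od: float = 0.45
    transition_sharpness_min: float = 15.0

    def __post_init__(self) -> None:
        if min(self.od0, self.alpha_max, self.capacity_od, self.transition_sharpness_min) <= 0:
            raise ValueError("growth parameters must be positive")
        if self.lag_min < 0:
            raise ValueError("lag must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model: additive Gaussian on the readings.

    od_sd ~ 0.002 matches typical microplate OD600 replicate scatter;
    blank_offset_od is the optical signal of medium + plasticware.
    Autofluorescence scales with biomass.
    """

    od_sd: float = 0.002
    fl_sd: float = 20.0
    blank_offset_od: float = 0.04
    autofluorescence_per_od: float = 150.0
    media_fl_offset: float = 50.0


@dataclass(frozen=True)
class SiteSpec:
    """One reporter insertion site in the simulation.

    ``repression`` maps growth phase ('exp', 'entry', 'stat') to the
    fraction of full promoter activity retained there (1 = unrepressed).
    """

    label: str
    m_prime: float
    production_rate: float = 400.0  # fluorescence units per copy per OD per min
    repression: dict = field(default_factory=lambda: {"exp": 1.0, "entry": 1.0, "stat": 1.0})
    # optional growth-rate coupling of the repression: the effective factor is
    # rho * (tau_ref / tau(t)) ** rho_tau_coupling, capped at 1 -- repression
    # deepens as growth slows, emulating a nucleoid protein whose free pool
    # (and hence silencing) grows when DNA content and dilution drop.
    # coupling 1 makes the repressed site's concentration growth-rate
    # independent (the stronger repression cancels the slower dilution).
    rho_tau_coupling: float = 0.0
    tau_ref_min: float = 60.0

    def __post_init__(self) -> None:
        if not (0 <= self.m_prime <= 1):
            raise ValueError("m_prime must be in [0, 1]")
        if self.production_rate < 0:
            raise ValueError("production rate must be >= 0")
        for ph, r in self.repression.items():
            if not (0 < r <= 1):
                raise ValueError(f"repression factor for {ph} must be in (0, 1]")


@dataclass(frozen=True)
class PlateSimConfig:
    seed: int
    sites: tuple
    replicates: int = 3
    n_blanks: int = 3
    n_background: int = 3
    interval_min: float = 5.0
    duration_min: float = 1200.0  # 20 h: overnight run reaching stationary phase
    growth: GrowthParams = GrowthParams()
    noise: NoiseParams = NoiseParams()
    replication: ReplicationParams = ReplicationParams(C=42.0, D=23.0)
    medium: str = "caa02"
    temperature: float = 30.0


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    times: np.ndarray
    od_true: np.ndarray  # noise-free OD (shared by all growing wells)
    alpha_true: np.ndarray  # per minute, on the sampling grid
    landmarks: PhaseLandmarks  # from the analytic alpha on a fine grid
    sites: dict  # label -> SiteSpec
    fl_true: dict  # label -> noise-free reporter signal F(t)
    conc_true: dict  # label -> F(t)/OD(t)
    gcn_true: dict  # label -> quasi-static copy number series
    config: PlateSimConfig | None = None


# ---------------------------------------------------------------------------
# growth


def _switch_integral(t: np.ndarray, lag: float, k: float) -> np.ndarray:
    """S(t) = integral_0^t 1/(1+exp(-(u-lag)/k)) du, numerically stable."""
    return k * (np.logaddexp(0.0, (t - lag) / k) - np.logaddexp(0.0, -lag / k))


def simulate_growth(growth: GrowthParams, times: np.ndarray):
    """Noise-free OD(t) and true alpha(t) of the lag-logistic model."""
    t = np.asarray(times, dtype=float)
    k = growth.transition_sharpness_min
    if growth.lag_min == 0:
        # no lag: the switch is fully on from t = 0
        s = np.ones_like(t)
        S = t
    else:
        s = 1.0 / (1.0 + np.exp(-(t - growth.lag_min) / k))
        S = _switch_integral(t, growth.lag_min, k)
    K = growth.capacity_od
    if np.isinf(K):
        od = growth.od0 * np.exp(growth.alpha_max * S)
        alpha = growth.alpha_max * s
        return od, alpha
    E = np.exp(growth.alpha_max * S)
    od = K * growth.od0 * E / (K + growth.od0 * (E - 1.0))
    alpha = growth.alpha_max * s * (1.0 - od / K)
    return od, alpha


def _true_landmarks(growth: GrowthParams, duration: float, eps_alpha: float = 0.02) -> PhaseLandmarks:
    """Landmarks of the analytic alpha(t), located on a 0.1-min grid."""
    tfine = np.arange(0.0, duration + 0.05, 0.1)
    _, a = simulate_growth(growth, tfine)
    amax = float(a.max())
    i_exp = int(np.argmax(a))
    t_exp = float(tfine[i_exp])
    half = amax / 2.0
    t_entry = None
    below = np.flatnonzero(a[i_exp + 1 :] < half)
    flags = []
    if below.size:
        j = i_exp + 1 + below[0]
        frac = (a[j - 1] - half) / (a[j - 1] - a[j])
        t_entry = float(tfine[j - 1] + frac * (tfine[j] - tfine[j - 1]))
        low = np.flatnonzero((tfine > t_entry) & (a <= eps_alpha * amax))
        t_stat = float(tfine[low[0]]) if low.size else None
        if t_stat is None:
            flags.append("no_stationary_phase")
    else:
        t_stat = None
        flags.append("still_exponential")
    return PhaseLandmarks(t_exp=t_exp, t_entry=t_entry, t_stat=t_stat, alpha_max=amax, flags=flags)


# ---------------------------------------------------------------------------
# reporter


def _phase_of(times: np.ndarray, lm: PhaseLandmarks) -> np.ndarray:
    """'exp' before t_entry, 'entry' between t_entry and t_stat, 'stat' after."""
    phase = np.full(len(times), "exp", dtype=object)
    if lm.t_entry is not None:
        phase[times >= lm.t_entry] = "entry"
    if lm.t_stat is not None:
        phase[times >= lm.t_stat] = "stat"
    return phase


def quasi_static_gcn(m_prime: float, alpha: np.ndarray, params: ReplicationParams) -> np.ndarray:
    """Copy number at instantaneous growth rate; tends to 1 as alpha -> 0."""
    a = np.clip(np.asarray(alpha, dtype=float), 0.0, None)
    return 2.0 ** ((params.C * (1.0 - m_prime) + params.D) * a / _LN2)


def simulate_reporter(
    od: np.ndarray,
    alpha: np.ndarray,
    times: np.ndarray,
    site: SiteSpec,
    replication: ReplicationParams,
    landmarks: PhaseLandmarks,
):
    """Noise-free reporter signal F(t) for one site.

    dF/dt = a * rho(phase(t)) * gcn(m', alpha(t)) * OD(t), integrated by
    the trapezoidal rule on the sampling grid, F(0) = 0.
    Returns (F, gcn series).
    """
    phase = _phase_of(np.asarray(times, dtype=float), landmarks)
    rho = np.array([site.repression.get(p, 1.0) for p in phase], dtype=float)
    gcn = quasi_static_gcn(site.m_prime, alpha, replication)
    if site.rho_tau_coupling:
        # repression deepens as growth slows, by exactly the factor that
        # cancels dilution and dosage: with coupling 1 the site's steady
        # concentration a*rho*gcn/alpha becomes growth-rate independent
        # (the planted terminal-site phenotype)
        a = np.clip(np.asarray(alpha, dtype=float), 0.0, None)
        gcn_ref = 2.0 ** (
            (replication.C * (1.0 - site.m_prime) + replication.D) / site.tau_ref_min
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            boost = (a * site.tau_ref_min / _LN2) * gcn_ref / gcn
        rho = np.clip(rho * boost**site.rho_tau_coupling, 0.0, 1.0)
    rate = site.production_rate * rho * gcn * np.asarray(od, dtype=float)
    F = cumulative_trapezoid(rate, times, initial=0.0)
    return F, gcn


# ---------------------------------------------------------------------------
# plate assembly


def default_plate_config(seed: int, repressed: dict | None = None) -> PlateSimConfig:
    """The default simulated experiment: nine reporter sites spanning the
    origin-terminus axis, three replicates, with the terminal-region
    site 'LT' repressed two-fold in every phase and 'RO' conditionally
    repressed at entry into stationary phase (the qualitative pattern
    the real reporter strains show).

    ``repressed`` optionally overrides the per-site repression maps.
    """
    from .sites import reporter_sites_frame

    df = reporter_sites_frame()
    repression = {label: {"exp": 1.0, "entry": 1.0, "stat": 1.0} for label in df["site_label"]}
    if repressed is None:
        repression["LT"] = {"exp": 0.5, "entry": 0.5, "stat": 0.5}
        repression["RO"] = {"exp": 1.0, "entry": 0.7, "stat": 0.85}
    else:
        for label, rho in repressed.items():
            repression[label] = dict(rho)
    sites = tuple(
        SiteSpec(label=row.site_label, m_prime=row.m_prime, repression=repression[row.site_label])
        for row in df.itertuples()
    )
    return PlateSimConfig(seed=seed, sites=sites)


def simulate_plate(config: PlateSimConfig) -> tuple[PlateTimeSeries, GroundTruth]:
    """Assemble a full simulated plate run; bit-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.duration_min + config.interval_min / 2, config.interval_min)
    od_true, alpha_true = simulate_growth(config.growth, times)
    lm = _true_landmarks(config.growth, config.duration_min)
    noise = config.noise

    wells: list[WellRecord] = []
    truth = GroundTruth(
        times=times,
        od_true=od_true,
        alpha_true=alpha_true,
        landmarks=lm,
        sites={s.label: s for s in config.sites},
        fl_true={},
        conc_true={},
        gcn_true={},
        config=config,
    )

    def measured_od(od_clean: np.ndarray) -> np.ndarray:
        return od_clean + noise.blank_offset_od + rng.normal(0.0, noise.od_sd, len(times))

    def measured_fl(fl_clean: np.ndarray) -> np.ndarray:
        return fl_clean + noise.media_fl_offset + rng.normal(0.0, noise.fl_sd, len(times))

    for i in range(config.n_blanks):
        wells.append(
            WellRecord(
                well_id=f"BLK{i + 1}",
                od_raw=measured_od(np.zeros(len(times))),
                fl_raw=measured_fl(np.zeros(len(times))),
                medium=config.medium,
                is_blank=True,
                temperature=config.temperature,
            )
        )
    for i in range(config.n_background):
        wells.append(
            WellRecord(
                well_id=f"BG{i + 1}",
                od_raw=measured_od(od_true),
                fl_raw=measured_fl(noise.autofluorescence_per_od * od_true),
                medium=config.medium,
                is_background=True,
                temperature=config.temperature,
            )
        )
    for site in config.sites:
        F, gcn = simulate_reporter(od_true, alpha_true, times, site, config.replication, lm)
        truth.fl_true[site.label] = F
        truth.gcn_true[site.label] = gcn
        with np.errstate(divide="ignore"):
            truth.conc_true[site.label] = np.where(od_true > 0, F / od_true, np.nan)
        for r in range(1, config.replicates + 1):
            wells.append(
                WellRecord(
                    well_id=f"{site.label}_r{r}",
                    od_raw=measured_od(od_true),
                    fl_raw=measured_fl(F + noise.autofluorescence_per_od * od_true),
                    site_label=site.label,
                    medium=config.medium,
                    replicate_id=r,
                    temperature=config.temperature,
                )
            )
    return PlateTimeSeries(times=times, wells=wells), truth


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class IslandSpec:
    """An AT-rich island planted into the background sequence."""

    center: int
    length: int
    at_fraction: float = 0.70


@dataclass(frozen=True)
class GenomeSimConfig:
    seed: int
    length: int = 200_000
    oriC: int = 1
    at_background: float = 0.50
    islands: tuple = ()
    occupancy_phases: tuple = ("HNS_EE", "HNS_ME", "HNS_TS", "HNS_S")
    occupancy_growth: float = 0.3  # fractional widening of H-NS regions per phase step
    tsepod_islands: tuple = (0,)  # indices of islands that also carry a tsEPOD


def _island_bounds(isl: IslandSpec, L: int) -> tuple[int, int]:
    half = isl.length // 2
    start = isl.center - half
    end = start + isl.length - 1
    if start < 1 or end > L:
        raise ValueError(f"island at {isl.center} (length {isl.length}) outside genome")
    return start, end


def simulate_genome(config: GenomeSimConfig):
    """Synthetic circular genome + occupancy tracks + ground truth.

    Background bases are i.i.d. at the configured AT fraction; islands
    overwrite their span at an elevated AT fraction.  H-NS occupancy
    intervals are centred on each island and widen phase by phase
    (early exponential -> stationary), emulating the spread of
    nucleoid-protein binding as growth slows; tsEPODs sit on designated
    islands.  Returns ``(sequence, tracks, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.length
    bounds = [_island_bounds(isl, L) for isl in config.islands]
    for (s1, e1), (s2, e2) in zip(sorted(bounds), sorted(bounds)[1:]):
        if e1 >= s2:
            raise ValueError("islands overlap; specify disjoint islands")

    def draw(n: int, at: float) -> np.ndarray:
        return rng.choice(
            np.frombuffer(b"ATCG", dtype=np.uint8),
            size=n,
            p=[at / 2, at / 2, (1 - at) / 2, (1 - at) / 2],
        )

    arr = draw(L, config.at_background)
    for isl, (s, e) in zip(config.islands, bounds):
        arr[s - 1 : e] = draw(e - s + 1, isl.at_fraction)
    sequence = arr.tobytes().decode("ascii")

    tracks: dict[str, IntervalSet] = {}
    for step, phase in enumerate(config.occupancy_phases):
        widen = 1.0 + config.occupancy_growth * step
        intervals = []
        for isl, (s, e) in zip(config.islands, bounds):
            half = int(isl.length * widen) // 2
            intervals.append((max(1, isl.center - half), min(L, isl.center + half)))
        tracks[phase] = IntervalSet(name=phase, intervals=intervals).validate()
    tsepod = [bounds[i] for i in config.tsepod_islands if i < len(bounds)]
    tracks["tsEPOD"] = IntervalSet(name="tsEPOD", intervals=tsepod).validate()

    truth = {
        "islands": bounds,
        "island_at": [isl.at_fraction for isl in config.islands],
        "tracks": {name: list(t.intervals) for name, t in tracks.items()},
        "layout": GenomeLayout(length=L, oriC=config.oriC),
    }
    return sequence, tracks, truth


# ---------------------------------------------------------------------------
# cytometry


@dataclass(frozen=True)
class CytometrySimConfig:
    seed: int
    n_events: int = 20_000
    expression_factor: float = 1.0
    expression_mean: float = 300.0
    extrinsic_cv: float = 0.25
    fl1_background_mean: float = 100.0
    fl1_background_sd: float = 20.0
    fsc_log_mean: float = np.log(500.0)
    fsc_log_sd: float = 0.25
    ssc_log_mean: float = np.log(300.0)
    ssc_log_sd: float = 0.30
    sample_label: str = "sample"


def simulate_cytometry(config: CytometrySimConfig) -> CytometryEvents:
    """Log-normal scatter cloud with FL1 = background + planted expression.

    The per-cell expression term is expression_factor * expression_mean
    times a unit-mean log-normal (extrinsic noise), so the net mean FL1
    above background equals expression_factor * expression_mean.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    fsc = rng.lognormal(config.fsc_log_mean, config.fsc_log_sd, n)
    ssc = rng.lognormal(config.ssc_log_mean, config.ssc_log_sd, n)
    sigma = np.sqrt(np.log1p(config.extrinsic_cv**2))
    unit_lognormal = rng.lognormal(-(sigma**2) / 2.0, sigma, n)
    fl1 = (
        rng.normal(config.fl1_background_mean, config.fl1_background_sd, n)
        + config.expression_factor * config.expression_mean * unit_lognormal
    )
    return CytometryEvents(fsc=fsc, ssc=ssc, fl1=fl1, sample_label=config.sample_label)
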