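"""Plate-reader kinetics: blanking, rates, activity, landmarks."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleopos import (
    GrowthCurveModel,
    PlateTimeSeries,
    WellRecord,
    blank_od,
    concentration,
    doubling_time,
    growth_rate,
    phase_landmarks,
    promoter_activity,
    subtract_background_fluorescence,
)
from nucleopos.simulate import (
    GrowthParams,
    NoiseParams,
    PlateSimConfig,
    SiteSpec,
    simulate_plate,
)

T = np.arange(0.0, 300.0, 5.0)


def _plate(wells):
    return PlateTimeSeries(times=T, wells=wells)


def _well(well_id, od, fl, **kw):
    return WellRecord(well_id=well_id, od_raw=od, fl_raw=fl, **kw)


# ---------------------------------------------------------------------------
# blanking / background


def test_blank_subtraction_constant_offset_and_self():
    blank = 0.04 * np.ones_like(T)
    sample = blank + 0.3
    plate = _plate(
        [
            _well("B", blank, np.zeros_like(T), is_blank=True),
            _well("S", sample, np.zeros_like(T), site_label="X"),
            _well("Z", blank.copy(), np.zeros_like(T), site_label="Y"),
        ]
    )
    od, blank_sd, floor, _ = blank_od(plate)
    assert np.allclose(od["S"], 0.3)
    # a well identical to the blank is floored at the detection floor
    assert np.allclose(od["Z"], floor)
    assert np.all(blank_sd == 0)


def test_blank_requires_blank_well():
    plate = _plate([_well("S", np.ones_like(T), np.zeros_like(T), site_label="X")])
    with pytest.raises(ValueError, match="blank"):
        blank_od(plate)


def test_background_subtraction_matched_by_medium():
    bg = 500.0 * np.ones_like(T)
    plate = _plate(
        [
            _well("W", np.ones_like(T), bg, is_background=True, medium="caa02"),
            _well("S", np.ones_like(T), bg + 1000.0, site_label="X", medium="caa02"),
            _well("R", np.ones_like(T), bg.copy(), site_label="Y", medium="caa02"),
        ]
    )
    fl, flags = subtract_background_fluorescence(plate)
    assert np.allclose(fl["S"], 1000.0)
    assert np.allclose(fl["R"], 0.0)
    assert flags["S"] == []


def test_background_missing_medium_named_in_error():
    plate = _plate(
        [
            _well("W", np.ones_like(T), np.zeros_like(T), is_background=True, medium="caa02"),
            _well("S", np.ones_like(T), np.zeros_like(T), site_label="X", medium="glu04"),
        ]
    )
    with pytest.raises(ValueError, match="glu04"):
        subtract_background_fluorescence(plate)


def test_negative_net_fluorescence_retained_and_flagged():
    plate = _plate(
        [
            _well("W", np.ones_like(T), 100.0 * np.ones_like(T), is_background=True, medium="m"),
            _well("S", np.ones_like(T), 90.0 * np.ones_like(T), site_label="X", medium="m"),
        ]
    )
    fl, flags = subtract_background_fluorescence(plate)
    assert np.allclose(fl["S"], -10.0)
    assert "negative_fluorescence" in flags["S"]


# ---------------------------------------------------------------------------
# concentration


def test_concentration_trivia():
    od = np.linspace(0.1, 0.5, len(T))
    valid = np.ones_like(T, bool)
    assert np.allclose(concentration(od, np.zeros_like(T), valid), 0.0)
    assert np.allclose(concentration(od, 3.0 * od, valid), 3.0)
    masked = concentration(od, od, np.zeros_like(T, bool))
    assert np.all(np.isnan(masked))


# ---------------------------------------------------------------------------
# growth rate / doubling time


def test_growth_rate_exact_on_exponential():
    od = 0.01 * np.exp(0.01 * T)
    alpha, _ = growth_rate(od, T)
    interior = np.isfinite(alpha)
    assert interior.sum() == len(T) - 4  # two masked points at each edge
    assert np.nanmax(np.abs(alpha[interior] - 0.01)) / 0.01 < 1e-6


def test_growth_rate_constant_od_is_zero():
    alpha, _ = growth_rate(np.full_like(T, 0.2), T)
    assert np.allclose(alpha[np.isfinite(alpha)], 0.0, atol=1e-15)


def test_growth_rate_scale_equivariance(rng):
    od = 0.01 * np.exp(0.008 * T) * np.exp(rng.normal(0, 0.01, len(T)))
    a1, _ = growth_rate(od, T)
    a2, _ = growth_rate(10.0 * od, T)
    assert np.allclose(a1[np.isfinite(a1)], a2[np.isfinite(a2)])


def test_growth_rate_too_few_points_warns_and_masks():
    with pytest.warns(UserWarning):
        alpha, _ = growth_rate(np.array([0.1, 0.2, 0.3]), np.array([0.0, 5.0, 10.0]), window=5)
    assert np.all(np.isnan(alpha))


@settings(max_examples=40, derandomize=True)
@given(st.lists(st.floats(1e-4, 1.0), min_size=3, max_size=10))
def test_doubling_time_round_trip(alphas):
    tau = doubling_time(np.asarray(alphas))
    back = np.log(2.0) / tau
    assert np.allclose(back, alphas, rtol=1e-12)


def test_doubling_time_masks_nonpositive():
    tau = doubling_time(np.array([np.log(2) / 60.0, 0.0, -0.01]))
    assert tau[0] == pytest.approx(60.0)
    assert np.isnan(tau[1]) and np.isnan(tau[2])


# ---------------------------------------------------------------------------
# promoter activity


def test_activity_zero_for_constant_fluorescence():
    od = 0.01 * np.exp(0.01 * T)
    act = promoter_activity(od, np.full_like(T, 500.0), T)
    assert np.allclose(act[np.isfinite(act)], 0.0, atol=1e-10)


def test_activity_recovers_constant_production_rate():
    """F = ag * int(OD dt) in exponential growth gives activity = ag."""
    alpha, ag = 0.01, 250.0
    od = 0.01 * np.exp(alpha * T)
    F = ag * (od - od[0]) / alpha  # exact integral of a*g*OD
    act = promoter_activity(od, F, T)
    interior = np.isfinite(act)
    # the 5-point linear slope of a convex exponential has a small known bias
    assert np.nanmax(np.abs(act[interior] - ag)) / ag < 0.01


def test_activity_scale_equivariance():
    od = 0.01 * np.exp(0.01 * T)
    F = 100.0 * (od - od[0])
    a1 = promoter_activity(od, F, T)
    a2 = promoter_activity(od, 7.0 * F, T)
    ok = np.isfinite(a1)
    assert np.allclose(a2[ok], 7.0 * a1[ok])


def test_activity_step_down_located_near_transition():
    """A planted production-rate step down at the stationary transition is
    located by the activity series within a couple of window widths."""
    cfg = PlateSimConfig(
        seed=17,
        sites=(SiteSpec("S", 0.5, repression={"exp": 1.0, "entry": 1.0, "stat": 0.2}),),
        replicates=1,
    )
    plate, truth = simulate_plate(cfg)
    res = GrowthCurveModel(plate).fit()
    p = res.profiles["S_r1"]
    ok = np.isfinite(p.activity)
    t_step = truth.landmarks.t_stat
    before = ok & (p.times > t_step - 120) & (p.times < t_step - 30)
    after = ok & (p.times > t_step + 30) & (p.times < t_step + 150)
    a_before = np.nanmedian(p.activity[before])
    a_after = np.nanmedian(p.activity[after])
    assert a_after < 0.4 * a_before
    # first crossing of the halfway level sits near the planted step
    half = (a_before + a_after) / 2.0
    idx = np.flatnonzero(ok & (p.times > t_step - 120) & (p.activity < half))
    t_detected = p.times[idx[0]]
    assert abs(t_detected - t_step) <= 50.0  # two window widths


# ---------------------------------------------------------------------------
# landmarks


def test_landmarks_triangular_ramp_geometry():
    tt = np.arange(0.0, 201.0, 5.0)
    A = 0.02
    alpha = A * (1.0 - np.abs(tt - 100.0) / 100.0)
    lm = phase_landmarks(alpha, tt)
    assert lm.t_exp == 100.0
    assert lm.t_entry == pytest.approx(150.0)  # interpolated half-max crossing
    # first sample at or below 0.02*A on the descending limb
    assert lm.t_stat == tt[np.flatnonzero((tt > 100) & (alpha <= 0.02 * A))[0]]
    assert lm.alpha_max == pytest.approx(A)


def test_landmarks_constant_alpha_absent_crossings():
    alpha = np.full(40, 0.01)
    tt = np.arange(40) * 5.0
    lm = phase_landmarks(alpha, tt)
    assert lm.t_exp == 0.0  # earliest tie wins
    assert lm.t_entry is None and lm.t_stat is None
    assert "still_exponential" in lm.flags


def test_landmarks_ordering_invariant(rng):
    for _ in range(25):
        tt = np.arange(0.0, 500.0, 5.0)
        peak = rng.uniform(50, 300)
        width = rng.uniform(40, 150)
        alpha = np.exp(-0.5 * ((tt - peak) / width) ** 2) * rng.uniform(0.005, 0.03)
        lm = phase_landmarks(alpha, tt)
        if lm.t_entry is not None:
            assert lm.t_exp <= lm.t_entry
            if lm.t_stat is not None:
                assert lm.t_entry <= lm.t_stat


# ---------------------------------------------------------------------------
# integrated model on synthetic data


def test_noise_free_plate_recovers_truth():
    cfg = PlateSimConfig(
        seed=1,
        sites=(SiteSpec("A", 0.2), SiteSpec("B", 0.8)),
        replicates=1,
        noise=NoiseParams(od_sd=0.0, fl_sd=0.0),
    )
    plate, truth = simulate_plate(cfg)
    res = GrowthCurveModel(plate).fit()
    p = res.profiles["A_r1"]
    ok = np.isfinite(p.alpha)
    assert np.allclose(p.od[p.valid_mask], truth.od_true[p.valid_mask], rtol=1e-9)
    # local linear slope on the smooth lag-logistic: small curvature bias only
    assert np.nanmax(np.abs(p.alpha[ok] - truth.alpha_true[ok])) < 1e-2 * truth.landmarks.alpha_max
    cmp = p.valid_mask & (truth.conc_true["A"] > 0)  # F(0)=0: skip the start
    conc_err = np.abs(p.conc[cmp] - truth.conc_true["A"][cmp])
    assert np.nanmax(conc_err / truth.conc_true["A"][cmp]) < 0.02


def test_blanked_od_within_noise_of_truth(fitted_default):
    res, truth = fitted_default
    sd = truth.config.noise.od_sd
    for wid in ("LO_r1", "LT_r2"):
        p = res.profiles[wid]
        err = np.abs(p.od[p.valid_mask] - truth.od_true[p.valid_mask])
        # blank-mean subtraction adds sd/sqrt(3); the max over ~240
        # timepoints of a Gaussian error sits near 3 combined SDs
        assert np.max(err) < 4.5 * sd * np.sqrt(1 + 1 / 3)


def test_fluorescence_within_noise_of_truth(fitted_default):
    res, truth = fitted_default
    sd = truth.config.noise.fl_sd
    p = res.profiles["RT_r1"]
    err = np.abs(p.fl - truth.fl_true["RT"])
    # autofluorescence is removed by the background wells up to their own
    # noise and the od-noise-scaled autofluorescence term
    auto = truth.config.noise.autofluorescence_per_od * truth.config.noise.od_sd
    assert np.max(err) < 4.5 * np.sqrt(sd**2 * (1 + 1 / 3) + auto**2)


def test_masking_monotone_under_noise():
    """Adding noise never unmasks points invalid in the noise-free run."""
    base = dict(sites=(SiteSpec("A", 0.5),), replicates=1)
    clean_plate, _ = simulate_plate(PlateSimConfig(seed=2, noise=NoiseParams(od_sd=0.0, fl_sd=0.0), **base))
    noisy_plate, _ = simulate_plate(PlateSimConfig(seed=2, **base))
    clean = GrowthCurveModel(clean_plate).fit().profiles["A_r1"]
    noisy = GrowthCurveModel(noisy_plate).fit().profiles["A_r1"]
    # noise raises the detection floor, so the noisy valid set is a subset
    assert not np.any(noisy.valid_mask & ~clean.valid_mask)


def test_steady_state_concentration_matches_production_over_dilution():
    """Balanced exponential growth: conc plateau = a * gcn / alpha."""
    alpha = np.log(2) / 60.0
    cfg = PlateSimConfig(
        seed=5,
        sites=(SiteSpec("S", 0.3),),
        replicates=1,
        growth=GrowthParams(od0=1e-4, alpha_max=alpha, lag_min=0.0, capacity_od=np.inf),
        duration_min=800.0,
        noise=NoiseParams(od_sd=0.0005, fl_sd=5.0),
    )
    plate, truth = simulate_plate(cfg)
    res = GrowthCurveModel(plate).fit()
    p = res.profiles["S_r1"]
    gcn = 2.0 ** ((truth.config.replication.C * 0.7 + truth.config.replication.D) * alpha / np.log(2))
    predicted = 400.0 * gcn / alpha
    late = np.where(np.isfinite(p.conc))[0][-20:]
    assert np.nanmean(p.conc[late]) == pytest.approx(predicted, rel=0.05)
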