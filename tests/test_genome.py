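"""Circular-genome arithmetic, AT windows, overlap and binning oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleopos import (
    ECOLI_K12_LAYOUT,
    GenomeLayout,
    IntervalSet,
    at_content_windows,
    binned_counts,
    circular_distance,
    occupancy_overlap,
    read_bed,
    relative_position,
    write_bed,
)
from nucleopos.simulate import GenomeSimConfig, IslandSpec, simulate_genome

SMALL = GenomeLayout(length=1000, oriC=1, circular=True)


# ---------------------------------------------------------------------------
# circular distance


def test_circular_distance_basics():
    assert circular_distance(500, 500, SMALL) == 0
    assert circular_distance(1, 1000, SMALL) == 1  # wrap
    linear = GenomeLayout(length=1000, oriC=1, circular=False)
    assert circular_distance(1, 1000, linear) == 999
    with pytest.raises(ValueError):
        circular_distance(0, 5, SMALL)


def test_reporter_site_separations_match_published_values():
    """LT/LT1, LT/LT2 and RT/RT1 sit ~18, ~135 and ~66 kb apart."""
    assert round(circular_distance(2_185_400, 2_167_700, ECOLI_K12_LAYOUT), -3) == 18_000
    assert round(circular_distance(2_185_400, 2_050_100, ECOLI_K12_LAYOUT), -3) == 135_000
    assert round(circular_distance(1_027_600, 1_093_500, ECOLI_K12_LAYOUT), -3) == 66_000


@settings(max_examples=80, derandomize=True)
@given(st.integers(1, 1000), st.integers(1, 1000), st.integers(1, 1000))
def test_circular_distance_is_a_metric(a, b, c):
    d_ab = circular_distance(a, b, SMALL)
    assert d_ab == circular_distance(b, a, SMALL)
    assert d_ab == 0 if a == b else d_ab > 0
    assert d_ab <= circular_distance(a, c, SMALL) + circular_distance(c, b, SMALL)


# ---------------------------------------------------------------------------
# relative position


def test_relative_position_endpoints_and_symmetry():
    layout = GenomeLayout(length=1000, oriC=1)  # ter defaults to 501
    assert relative_position(1, layout) == 0.0
    assert relative_position(501, layout) == 1.0
    assert relative_position(251, layout) == pytest.approx(0.5)  # quarter genome
    assert relative_position(751, layout) == pytest.approx(0.5)  # other replichore


@settings(max_examples=80, derandomize=True)
@given(st.integers(1, 4_641_652))
def test_relative_position_bounded(pos):
    m = relative_position(pos, ECOLI_K12_LAYOUT)
    assert 0.0 <= m <= 1.0


def test_relative_position_continuous_across_origin_wrap():
    layout = GenomeLayout(length=1000, oriC=900)  # replichore spans the wrap
    m = np.array([relative_position(p, layout) for p in range(890, 911)])
    assert np.all(np.abs(np.diff(m)) < 0.01)


# ---------------------------------------------------------------------------
# AT content


def test_at_windows_constant_sequences():
    prof_a = at_content_windows("A" * 500, 50, 10)
    assert np.allclose(prof_a.at_fraction, 1.0)
    prof_g = at_content_windows("G" * 500, 50, 10)
    assert np.allclose(prof_g.at_fraction, 0.0)


def test_at_windows_ambiguous_bases_excluded():
    seq = "A" * 30 + "N" * 10 + "G" * 20
    prof = at_content_windows(seq, 10, 10, GenomeLayout(length=60, oriC=1, circular=False))
    assert prof.at_fraction[0] == 1.0
    assert np.isnan(prof.at_fraction[3])  # all-N window masked
    assert prof.at_fraction[5] == 0.0


def test_at_windows_wrap_matches_doubled_sequence_oracle(rng):
    """Circular profile equals a linear scan of the doubled sequence."""
    seq = "".join(rng.choice(list("ACGT"), 600))
    layout = GenomeLayout(length=600, oriC=1)
    circ = at_content_windows(seq, 80, 20, layout)
    lin = at_content_windows(seq + seq, 80, 20, GenomeLayout(length=1200, oriC=1, circular=False))
    n = len(circ.at_fraction)
    assert np.allclose(circ.at_fraction, lin.at_fraction[:n])


def test_at_windows_reverse_complement_invariant(rng):
    """A+T counting is strand-symmetric: revcomp mirrors the profile."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    seq = "".join(rng.choice(list("ACGT"), 1000))
    rc = "".join(comp[b] for b in reversed(seq))
    p1 = at_content_windows(seq, 40, 10)
    p2 = at_content_windows(rc, 40, 10)
    assert np.allclose(np.sort(p1.at_fraction), np.sort(p2.at_fraction))


def test_at_windows_find_planted_island():
    cfg = GenomeSimConfig(seed=11, length=120_000, islands=(IslandSpec(center=40_000, length=10_000, at_fraction=0.72),))
    seq, _, truth = simulate_genome(cfg)
    layout = truth["layout"]
    prof = at_content_windows(seq, 4_000, 500, layout)
    peak_center = prof.centers[np.nanargmax(prof.at_fraction)]
    assert abs(peak_center - 40_000) < 5_000
    # island windows near 0.72, background near 0.50 (binomial error ~0.008)
    assert np.nanmax(prof.at_fraction) == pytest.approx(0.72, abs=0.03)
    far = np.abs(prof.centers - 40_000) > 15_000
    assert np.nanmean(prof.at_fraction[far]) == pytest.approx(0.50, abs=0.01)


# ---------------------------------------------------------------------------
# occupancy overlap


def _brute_force_overlap(pos, flank, intervals, layout):
    """Independent per-basepair scan of the flanked site window."""
    L = layout.length
    covered = 0
    for off in range(-flank, flank + 1):
        p = (pos + off - 1) % L + 1
        if any(s <= p <= e for s, e in intervals):
            covered += 1
    if covered > 0:
        return True, covered, 0
    if not intervals:
        return False, 0, None
    dist = min(
        0 if s <= pos <= e else min(circular_distance(pos, s, layout), circular_distance(pos, e, layout))
        for s, e in intervals
    )
    return False, 0, dist


def test_overlap_trivial_cases():
    layout = GenomeLayout(length=10_000, oriC=1)
    inside = IntervalSet("trk", [(100, 200)])
    rep = occupancy_overlap(150, [inside], 0, layout)["trk"]
    assert rep.overlaps and rep.nearest_distance == 0 and rep.overlap_bp == 1
    empty = occupancy_overlap(150, [IntervalSet("none", [])], 50, layout)["none"]
    assert not empty.overlaps and empty.nearest_distance is None


def test_overlap_matches_brute_force_on_random_instances(rng):
    layout = GenomeLayout(length=5_000, oriC=1)
    for _ in range(200):
        n_iv = rng.integers(0, 6)
        intervals = []
        for _ in range(n_iv):
            s = int(rng.integers(1, 4_900))
            intervals.append((s, int(rng.integers(s, min(5_000, s + 400)))))
        track = IntervalSet("t", intervals)
        pos = int(rng.integers(1, 5_001))
        flank = int(rng.integers(0, 60))
        rep = occupancy_overlap(pos, [track], flank, layout)["t"]
        exp_overlaps, exp_bp, exp_dist = _brute_force_overlap(pos, flank, intervals, layout)
        assert rep.overlaps == exp_overlaps
        assert rep.overlap_bp == exp_bp
        assert rep.nearest_distance == exp_dist


# ---------------------------------------------------------------------------
# binned counts


def test_binned_counts_conservation_and_trivia(rng):
    layout = GenomeLayout(length=32_000, oriC=1)
    one = IntervalSet("f", [(100, 300)])
    counts = binned_counts(one, 32, layout)
    assert counts.sum() == 1 and counts[0] == 1
    assert binned_counts(one, 1, layout)[0] == 1
    feats = IntervalSet("f", [(int(p), int(p)) for p in rng.integers(1, 32_001, 500)])
    counts = binned_counts(feats, 32, layout)
    assert counts.sum() == 500


def test_binned_counts_uniform_features_within_multinomial_bound(rng):
    layout = GenomeLayout(length=100_000, oriC=1)
    n, bins = 6_400, 32
    feats = IntervalSet("f", [(int(p), int(p)) for p in rng.integers(1, 100_001, n)])
    counts = binned_counts(feats, bins, layout)
    expected = n / bins
    sd = np.sqrt(n * (1 / bins) * (1 - 1 / bins))
    assert np.all(np.abs(counts - expected) < 4 * sd)


# ---------------------------------------------------------------------------
# BED round trip


def test_bed_round_trip(tmp_path):
    track = IntervalSet("HNS_EE", [(1, 100), (2_000, 2_500)])
    path = tmp_path / "hns_ee.bed"
    write_bed(track, path)
    back = read_bed(path)
    assert back.intervals == track.intervals
    assert back.name == "hns_ee"
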