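"""Bound-segment extraction, bound fraction and the N_min rule."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from smtrack import (AcquisitionConfig, BoundStats, ClassifierParams,
                     KineticParams, Track, choose_nmin,
                     classify_bound_segments, compute_bound_stats,
                     link_tracks, simulate_trajectories)
from smtrack.classify import brownian_step_pass_probability

PX = 106.7
INTERVAL = 0.2


def _track_from_steps(steps_nm, track_id=0):
    """Build a straight-line track from frame-to-frame step lengths (nm)."""
    x = np.concatenate([[0.0], np.cumsum(steps_nm)]) / PX
    n = len(x)
    return Track(track_id, np.arange(n), x, np.zeros(n), np.zeros(n, bool))


def _enumerate_maximal_runs(track, params):
    """Oracle: all maximal index runs satisfying both displacement rules."""
    step = track.step_displacements_nm(PX)
    two = track.two_frame_displacements_nm(PX)

    def valid(a, b):
        if b - a < 1:
            return False
        if np.any(step[a:b] > params.r_max1_nm):
            return False
        inner = two[a:b - 1] if b - a >= 2 else np.array([])
        return not np.any(inner > params.r_max2_nm)

    runs = [(a, b) for a in range(len(track)) for b in range(a + 1, len(track))
            if valid(a, b)]
    maximal = [(a, b) for (a, b) in runs
               if not any((c <= a and b <= d) and (c, d) != (a, b)
                          for (c, d) in runs)]
    return [(a, b) for (a, b) in maximal if b - a + 1 >= params.n_min]


def test_stationary_track_is_one_censored_segment():
    t = _track_from_steps([0.0] * 9)
    segs = classify_bound_segments(t, ClassifierParams(n_min=3), INTERVAL, PX)
    assert len(segs) == 1
    seg = segs[0]
    assert seg.n_frames == 10
    assert seg.dwell_s == pytest.approx(9 * INTERVAL)
    assert seg.censored


def test_fast_track_yields_no_segments():
    t = _track_from_steps([400.0] * 10)
    assert classify_bound_segments(t, ClassifierParams(n_min=3), INTERVAL, PX) == []


def test_toy_track_matches_exhaustive_enumeration():
    """A mixed-mobility reference step sequence, checked against brute force."""
    steps = [50, 60, 300, 40, 50, 55, 45, 400, 30, 35, 40]
    t = _track_from_steps(steps)
    params = ClassifierParams(n_min=3)
    segs = classify_bound_segments(t, params, INTERVAL, PX)
    got = [(s.start_frame, s.end_frame) for s in segs]
    assert got == _enumerate_maximal_runs(t, params)
    assert [s.n_frames for s in segs] == [3, 5, 4]
    # interior segment is not censored, the trailing one is
    assert [s.censored for s in segs] == [False, False, True]


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st_h.integers(min_value=0, max_value=10_000))
def test_segment_extraction_equals_oracle_on_random_walks(seed):
    """Greedy scan equals maximal-run enumeration whenever breaks are hard.

    Random mixed-mobility tracks whose sub-threshold stretches are separated
    by unambiguous large steps (the generic case in data, where a diffusing
    molecule moves many hundreds of nm between binding events).
    """
    rng = np.random.default_rng(seed)
    steps = []
    for _ in range(4):
        # bound-like stretches: steps small enough that no interior
        # two-frame displacement can break a run on a straight-line track
        steps.extend(rng.uniform(0, 130, rng.integers(0, 6)))
        steps.extend(rng.uniform(400, 900, rng.integers(1, 3)))
    t = _track_from_steps(steps)
    params = ClassifierParams(n_min=2)
    got = [(s.start_frame, s.end_frame)
           for s in classify_bound_segments(t, params, INTERVAL, PX)]
    assert got == _enumerate_maximal_runs(t, params)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st_h.integers(min_value=0, max_value=10_000))
def test_segment_count_monotone_in_nmin(seed):
    rng = np.random.default_rng(seed)
    steps = rng.uniform(0, 500, 40)
    t = _track_from_steps(steps)
    counts = [len(classify_bound_segments(t, ClassifierParams(n_min=n),
                                          INTERVAL, PX))
              for n in range(2, 8)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_bound_fraction_arithmetic():
    t = _track_from_steps([0.0] * 39)
    segs = classify_bound_segments(t, ClassifierParams(n_min=3), INTERVAL, PX)
    stats = compute_bound_stats(segs, [t], n_total_detections=200)
    assert stats.n_bound == 40
    assert stats.bound_fraction == pytest.approx(0.2)
    full = compute_bound_stats(segs, [t], n_total_detections=40)
    assert full.bound_fraction == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compute_bound_stats(segs, [t], n_total_detections=0)


def test_pie_fractions_sum_exactly_to_one():
    stats = BoundStats(n_bound=137, n_total=1043)
    for f_ns in (None, 0.0, 0.37, 1.0):
        unbound, fast, slow = stats.pie_fractions(f_ns)
        assert unbound + fast + slow == 1.0
        assert min(unbound, fast, slow) >= 0.0


def test_bound_fraction_recovers_truth_occupancy():
    """Pipeline B matches exhaustive counting on perfectly-tracked truth.

    The oracle enumerates maximal displacement-qualifying runs on each
    molecule's true positions (no linking), so any disagreement isolates
    linking and bookkeeping errors.
    """
    acq = AcquisitionConfig(image_shape=(512, 512), n_frames=150)
    params = dataclasses.replace(KineticParams(), p_miss=0.0,
                                 bleach_k1=0.0, bleach_k2=0.0)
    truth = simulate_trajectories(params, acq, 60, seed=21)
    n_min = choose_nmin(acq.interval_time, params.D_free)
    cp = ClassifierParams(n_min=n_min)

    run_lengths = []
    for mid, g in truth.frames.groupby("molecule_id"):
        g = g.sort_values("frame")
        t = Track(int(mid), g["frame"].to_numpy(),
                  g["x_px"].to_numpy(), g["y_px"].to_numpy(),
                  np.zeros(len(g), bool))
        run_lengths.extend(b - a + 1 for a, b in _enumerate_maximal_runs(t, cp))
    n_total = len(truth.frames)
    # a free molecule at D = 2 um^2/s steps ~10 px per 200 ms, far beyond the
    # 4-px linking radius, so tracks are bound episodes: segments shorter
    # than the 6-frame track minimum are lost.  The two ground-truth counts
    # bracket the pipeline's bound fraction.
    b_upper = sum(n for n in run_lengths if n >= n_min) / n_total
    b_lower = sum(n for n in run_lengths if n >= 6) / n_total

    locs = truth.to_localizations(seed=22)
    tracks = link_tracks(locs)
    segs = []
    for t in tracks:
        segs.extend(classify_bound_segments(t, cp, acq.interval_time,
                                            acq.pixel_size_nm))
    stats = compute_bound_stats(segs, tracks, len(locs))
    se = np.sqrt(b_upper * (1 - b_upper) / n_total)
    assert b_lower - 3 * se <= stats.bound_fraction <= b_upper + 3 * se


def test_choose_nmin_reference_values():
    p = brownian_step_pass_probability(0.2, 2.0, 220.0)
    assert p == pytest.approx(1.0 - np.exp(-0.0484 / 1.6), rel=1e-12)
    assert p == pytest.approx(0.0298, abs=2e-4)
    assert choose_nmin(0.2, 2.0) == 3          # two steps: ~0.09% < 1%
    assert choose_nmin(0.2, 2.0, ClassifierParams(r_max1_nm=1e-6)) == 2
    with pytest.raises(ValueError):
        choose_nmin(0.2, d_free=0.0)


def test_choose_nmin_monte_carlo_cross_check():
    """10^5 Brownian walkers: the chosen N_min keeps the pass rate < 1%."""
    interval, d = 0.2, 2.0
    n_min = choose_nmin(interval, d)
    rng = np.random.default_rng(23)
    sd_px = np.sqrt(2 * d * interval) * 1000.0 / PX
    steps = rng.normal(0, sd_px, size=(100_000, n_min - 1, 2))
    pos = np.concatenate([np.zeros((100_000, 1, 2)), np.cumsum(steps, axis=1)],
                         axis=1)
    step_nm = np.hypot(*np.moveaxis(np.diff(pos, axis=1), 2, 0)) * PX
    passed = np.all(step_nm <= 220.0, axis=1)
    if n_min >= 3:
        two_nm = np.hypot(*np.moveaxis(pos[:, 2:] - pos[:, :-2], 2, 0)) * PX
        passed &= np.all(two_nm <= 270.0, axis=1)
    assert passed.mean() < 0.01
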