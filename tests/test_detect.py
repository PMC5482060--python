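"""Spot detection, deduplication and sub-pixel Gaussian localization."""

import dataclasses

import numpy as np
import pytest
from scipy.special import erf

from smtrack import (AcquisitionConfig, KineticParams, detect_candidates,
                     localize_frame, localize_gaussian, preprocess_frame,
                     render_movie, suggest_threshold)
from smtrack.simulate import GroundTruth

import pandas as pd


def _spot_image(x0, y0, size=21, photons=500.0, sigma=1.2, background=0.0):
    """Integrated-Gaussian spot plus uniform background (expected counts)."""
    cols = np.arange(size)
    s2 = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((cols + 0.5 - x0) / s2) - erf((cols - 0.5 - x0) / s2))
    fy = 0.5 * (erf((cols + 0.5 - y0) / s2) - erf((cols - 0.5 - y0) / s2))
    return photons * np.outer(fy, fx) + background


def test_flat_field_maps_to_zero():
    out = preprocess_frame(np.full((64, 64), 37.0))
    assert out.shape == (64, 64)
    assert np.allclose(out, 0.0)


def test_preprocess_rejects_bad_input():
    with pytest.raises(ValueError):
        preprocess_frame(np.zeros((4, 4, 4)))
    bad = np.zeros((16, 16))
    bad[3, 3] = np.nan
    with pytest.raises(ValueError):
        preprocess_frame(bad)


def test_illumination_gradient_invariance():
    """Spot-to-background contrast is within 5% of the gradient-free case."""
    rng = np.random.default_rng(0)
    base = _spot_image(32.0, 32.0, size=65, photons=500.0, background=10.0)
    noise = rng.poisson(base).astype(float) - base  # shared noise realization
    cols = np.linspace(0.0, 20.0, 65)
    gradient = np.broadcast_to(cols, (65, 65))

    def contrast(img):
        filt = preprocess_frame(img)
        return filt[30:35, 30:35].max() / max(np.median(filt), 1e-6)

    c_flat = contrast(base + noise)
    c_grad = contrast(base + gradient + noise)
    assert abs(c_grad - c_flat) / c_flat < 0.05


def test_speckle_attenuated_spot_preserved():
    """The band-pass attenuates a hot pixel several-fold while passing an
    equal-peak 5-px-area spot nearly intact; whatever speckle remains above
    threshold is rejected by the Gaussian width gate at the fit stage."""
    rng = np.random.default_rng(1)
    bg = rng.poisson(10.0, (64, 64)).astype(float)
    peak = 60.0
    img = bg.copy()
    img[20, 20] += peak                                   # single-pixel speckle
    img += _spot_image(45.0, 45.0, size=64,
                       photons=peak * 2 * np.pi * 1.2 ** 2)  # same peak height
    filt = preprocess_frame(img)
    speckle_response = filt[20, 20]
    spot_response = filt[43:48, 43:48].max()
    assert speckle_response < 0.25 * peak                 # strongly attenuated
    assert spot_response > 2.0 * speckle_response         # spot wins clearly
    assert spot_response > suggest_threshold(filt)
    # the localizer refuses the sub-PSF-width speckle but accepts the spot
    assert localize_gaussian(img, (20, 20)) is None
    loc = localize_gaussian(img, (45, 45))
    assert loc is not None and abs(loc.x - 45.0) < 0.5


def test_blank_frame_yields_no_candidates():
    filt = preprocess_frame(np.random.default_rng(2).poisson(10, (64, 64)).astype(float))
    cands = detect_candidates(filt, threshold=1e9)
    assert len(cands) == 0


def test_dedup_keeps_brighter_of_close_pair():
    img = np.zeros((32, 32))
    img[10, 10] = 100.0
    img[10, 15] = 80.0   # 5 px away: inside the 7-px dedup radius
    img[25, 25] = 60.0   # far away: kept
    cands = detect_candidates(img, threshold=10.0)
    kept = {tuple(c) for c in cands}
    assert kept == {(10, 10), (25, 25)}
    # surviving pairs are all >= 7 px apart
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            assert np.hypot(*(cands[i] - cands[j])) >= 7.0


def test_candidates_recover_isolated_rendered_spots():
    """20 spots >= 15 px apart at SNR ~10: exactly 20 seeds within 1 px."""
    rng = np.random.default_rng(3)
    size = 128
    grid = [(16 + 24 * i, 16 + 24 * j) for i in range(5) for j in range(4)]
    truth_pos = [(x + rng.uniform(-2, 2), y + rng.uniform(-2, 2)) for y, x in grid]
    scene = np.full((size, size), 10.0)
    for x, y in truth_pos:
        scene += _spot_image(x, y, size=size, photons=300.0)
    img = rng.poisson(scene).astype(float)
    filt = preprocess_frame(img)
    cands = detect_candidates(filt, suggest_threshold(filt))
    assert len(cands) == 20
    for x, y in truth_pos:
        d = np.hypot(cands[:, 0] - y, cands[:, 1] - x)
        assert d.min() <= 1.0


def test_noiseless_localization_subpixel_exact():
    img = _spot_image(10.30, 7.60, size=21)
    loc = localize_gaussian(img, (8, 10))
    assert loc is not None
    assert abs(loc.x - 10.30) < 0.01
    assert abs(loc.y - 7.60) < 0.01


def test_background_only_seed_discarded():
    rng = np.random.default_rng(4)
    rejected = sum(
        localize_gaussian(rng.poisson(10.0, (11, 11)).astype(float), (5, 5)) is None
        for _ in range(50)
    )
    assert rejected >= 48


def test_localization_precision_below_diffraction_limit():
    """RMS error at 500 photons / 10 bg stays below the ~200 nm limit."""
    from smtrack.validation import localization_rms_error_nm

    rms = localization_rms_error_nm(n_spots=300, photons=500.0, background=10.0,
                                    psf_sigma_px=1.2, pixel_size_nm=106.7, seed=0)
    assert rms <= 200.0


def test_precision_improves_with_photon_count():
    from smtrack.validation import localization_rms_error_nm

    rms = [localization_rms_error_nm(n_spots=200, photons=p, seed=1)
           for p in (150.0, 500.0, 2000.0)]
    assert rms[0] > rms[1] > rms[2]


def test_localization_count_bounded_by_candidates():
    rng = np.random.default_rng(5)
    scene = np.full((96, 96), 10.0)
    for k in range(8):
        scene += _spot_image(12 + 10 * k % 70, 12 + 9 * k, size=96, photons=300.0)
    img = rng.poisson(scene).astype(float)
    filt = preprocess_frame(img)
    cands = detect_candidates(filt, suggest_threshold(filt))
    locs = localize_frame(img)
    assert len(locs) <= len(cands)


def test_detection_recovers_rendered_ground_truth():
    """>=95% of rendered molecule positions are re-found within 1 px."""
    acq = AcquisitionConfig(image_shape=(256, 256), n_frames=4)
    params = KineticParams()
    rows = []
    rng = np.random.default_rng(6)
    # isolated spots (>= ~20 px apart): recovery probes detectability, and
    # the 7-px deduplication would legitimately merge crowded molecules
    grid = [(24 + 30 * i, 24 + 30 * j) for i in range(8) for j in range(8)]
    pos = np.array(grid[:50], dtype=float) + rng.uniform(-4, 4, size=(50, 2))
    for f in range(acq.n_frames):
        for m, (x, y) in enumerate(pos):
            rows.append((m, f, x, y, "bound_s", 0))
    frames = pd.DataFrame(rows, columns=["molecule_id", "frame", "x_px", "y_px",
                                         "state", "event_id"])
    truth = GroundTruth(frames=frames, events=pd.DataFrame(), acquisition=acq,
                        kinetics=params)
    stack = render_movie(truth, seed=7)
    found = 0
    total = 0
    for f in range(acq.n_frames):
        locs = localize_frame(stack[f], frame=f)
        lx = np.array([l.x for l in locs])
        ly = np.array([l.y for l in locs])
        for x, y in pos:
            total += 1
            if len(lx) and np.hypot(lx - x, ly - y).min() <= 1.0:
                found += 1
    assert found / total >= 0.95
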