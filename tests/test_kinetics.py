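"""Bleach models, survival curves, mixture fits, selection and splitting."""

import dataclasses
import warnings

import numpy as np
import pytest

from smtrack import (BleachModel, ExpMixtureFit, KineticParams, SurvivalCurve,
                     build_selection_curve, build_survival, fit_bleach_model,
                     fit_exp_mixture, sample_dwell_times, select_model,
                     split_populations)


def test_bleach_fit_recovers_exact_single_exponential():
    f = np.arange(600)
    counts = 80.0 * np.exp(-0.01 * f)
    model = fit_bleach_model(counts)
    assert np.max(np.abs(model.survival(f) - np.exp(-0.01 * f))) < 1e-6


def test_bleach_fit_biexponential_with_poisson_noise():
    rng = np.random.default_rng(0)
    f = np.arange(600)
    expected = 80.0 * (0.6 * np.exp(-0.02 * f) + 0.4 * np.exp(-0.002 * f))
    counts = rng.poisson(expected)
    model = fit_bleach_model(counts)
    truth = expected / expected[0]
    assert np.max(np.abs(model.survival(f) - truth)) < 0.05


def test_bleach_fit_constant_counts_gives_identity_correction():
    model = fit_bleach_model(np.full(100, 50.0))
    assert np.allclose(model.survival(np.arange(100)), 1.0, atol=1e-6)


def test_bleach_fit_rejects_empty_counts():
    with pytest.raises(ValueError):
        fit_bleach_model(np.zeros(100))


def test_identity_correction_is_noop():
    dwells = np.array([0.2, 0.2, 0.4, 0.6, 0.6, 0.6, 1.0, 1.4])
    curve = build_survival(dwells, B=8.0, bleach=BleachModel.identity(),
                           interval=0.2)
    assert np.array_equal(curve.values, curve.raw)
    assert np.all(np.diff(curve.raw) <= 0)


def test_single_dwell_gives_step_at_bound_fraction():
    curve = build_survival([1.0], B=0.3, bleach=BleachModel.identity(),
                           interval=0.2)
    assert curve.values[0] == pytest.approx(0.3)
    assert curve.times[0] == pytest.approx(1.0)


def test_underflowing_bleach_survival_truncates_with_warning():
    dwells = np.linspace(0.2, 40.0, 300)
    strong = BleachModel(amp=1.0, lam1=0.2, lam2=0.2)
    with pytest.warns(RuntimeWarning, match="truncated"):
        curve = build_survival(dwells, 1.0, strong, 0.2)
    assert curve.times[-1] < 40.0


def test_bleach_corrected_fit_recovers_truncated_lifetime():
    """min(binding, bleaching) oracle: uncorrected fit biased low, corrected
    fit within 10% of the true 5 s residence time."""
    rng = np.random.default_rng(1)
    interval = 0.2
    n = 20_000
    binding = rng.exponential(5.0, n)
    mean_frames = 4.0 / interval           # trackable lifetime 4 s
    bleach_frames = np.floor(rng.exponential(mean_frames, n)).astype(int) + 1
    frames = np.minimum(np.floor(binding / interval).astype(int) + 1,
                        bleach_frames)
    obs = (frames[frames >= 3] - 1) * interval

    model = BleachModel(amp=1.0, lam1=1.0 / mean_frames, lam2=0.0)
    uncorrected = fit_exp_mixture(
        build_survival(obs, 1.0, BleachModel.identity(), interval), 1)
    corrected = fit_exp_mixture(build_survival(obs, 1.0, model, interval), 1)
    assert uncorrected.T_s < 5.0
    assert abs(corrected.T_s - 5.0) / 5.0 < 0.10


def _curve(times, values, interval=0.2, B=None):
    return SurvivalCurve(times=times, raw=np.linspace(100, 1, len(times)),
                         values=values, B=B if B is not None else values[0],
                         interval=interval, n_dwells=100)


def test_exact_single_exponential_fit():
    t = np.arange(1, 150) * 0.2
    fit = fit_exp_mixture(_curve(t, np.exp(-t / 2.0)), 1)
    assert fit.order == 1
    assert fit.T_s == pytest.approx(2.0, abs=1e-6)


def test_exact_two_component_fit_recovers_all_parameters():
    t = np.arange(1, 150) * 0.2
    y = 0.03 * (0.85 * np.exp(-t / 0.6) + 0.15 * np.exp(-t / 8.0))
    fit = fit_exp_mixture(_curve(t, y, B=0.03), 2)
    assert fit.B == pytest.approx(0.03, rel=1e-4)
    assert fit.F_ns == pytest.approx(0.85, rel=1e-4)
    assert fit.T_ns == pytest.approx(0.6, rel=1e-4)
    assert fit.T_s == pytest.approx(8.0, rel=1e-4)


def test_sampled_mixture_fit_recovery(kinetics):
    dwells, _ = sample_dwell_times(kinetics, 50_000, seed=2)
    obs = (np.floor(dwells / 0.2).astype(int)) * 0.2
    obs = obs[obs >= 0.2]
    fit = fit_exp_mixture(build_survival(obs, 1.0, BleachModel.identity(), 0.2), 2)
    assert abs(fit.T_s - kinetics.T_s) / kinetics.T_s < 0.05
    assert abs(fit.F_ns - kinetics.p_ns) < 0.02


def test_rss_is_weakly_decreasing_in_model_order():
    rng = np.random.default_rng(3)
    t = np.arange(1, 80) * 0.2
    for _ in range(3):
        y = np.exp(-t / rng.uniform(1, 6)) + rng.normal(0, 0.01, len(t))
        curve = _curve(t, np.clip(y, 1e-6, None))
        rss = [fit_exp_mixture(curve, k).rss for k in (1, 2, 3)]
        assert rss[0] >= rss[1] - 1e-9
        assert rss[1] >= rss[2] - 1e-9


def test_fit_requires_enough_points():
    t = np.arange(1, 4) * 0.2
    with pytest.raises(ValueError):
        fit_exp_mixture(_curve(t, np.exp(-t)), 3)


def test_identical_rss_gives_f_zero_and_order_one():
    t = np.arange(1, 60) * 0.2
    fit1 = fit_exp_mixture(_curve(t, np.exp(-t / 2.0)), 1)
    fit2 = ExpMixtureFit(order=2, B=fit1.B, fractions=(0.5, 0.5),
                         rates=(fit1.rates[0], fit1.rates[0]),
                         rss=fit1.rss, n_points=fit1.n_points)
    sel = select_model(fit1, fit2, None)
    assert sel.f_12 == 0.0
    assert sel.order == 1


def test_selection_is_two_iff_order2_significant_and_order3_not():
    t = np.arange(1, 100) * 0.2
    y = 0.5 * np.exp(-t / 0.8) + 0.5 * np.exp(-t / 6.0)
    rng = np.random.default_rng(4)
    curve = _curve(t, y + rng.normal(0, 1e-4, len(t)))
    fits = {k: fit_exp_mixture(curve, k) for k in (1, 2, 3)}
    sel = select_model(fits[1], fits[2], fits[3])
    assert sel.order == 2
    assert sel.p_12 < 0.05 <= sel.p_23


def test_split_populations_rules(kinetics):
    dwells = np.arange(1.0, 11.0)
    fit = ExpMixtureFit(order=2, B=1.0, fractions=(0.8, 0.2),
                        rates=(2.0, 0.2), rss=0.0, n_points=50)
    split = split_populations(dwells, fit)
    assert len(split.slow) == round(0.2 * 10)
    assert set(split.slow) == {9.0, 10.0}
    assert split.slow.min() >= split.fast.max()
    assert len(split.fast) + len(split.slow) == 10

    all_fast = ExpMixtureFit(order=2, B=1.0, fractions=(1.0, 0.0),
                             rates=(2.0, 0.2), rss=0.0, n_points=50)
    assert len(split_populations(dwells, all_fast).slow) == 0

    single = ExpMixtureFit(order=1, B=1.0, fractions=(1.0,), rates=(0.5,),
                           rss=0.0, n_points=50)
    s = split_populations(dwells, single)
    assert s.single and len(s.slow) == 10 and len(s.fast) == 0


def test_split_recovers_specific_population_median(kinetics):
    dwells, classes = sample_dwell_times(kinetics, 20_000, seed=5)
    fit = ExpMixtureFit(order=2, B=1.0,
                        fractions=(kinetics.p_ns, kinetics.p_s),
                        rates=(1 / kinetics.T_ns, 1 / kinetics.T_s),
                        rss=0.0, n_points=50)
    split = split_populations(dwells, fit)
    true_slow_median = np.median(dwells[classes == "s"])
    assert abs(np.median(split.slow) - true_slow_median) / true_slow_median < 0.15


def test_selection_curve_uses_disjoint_subsamples(kinetics):
    dwells, _ = sample_dwell_times(kinetics, 5000, seed=6)
    obs = np.maximum(np.round(dwells / 0.2), 1) * 0.2
    curve = build_selection_curve(obs, 1.0, BleachModel.identity(), 0.2)
    assert 3 <= len(curve.times) <= 13
    assert np.all(np.diff(curve.times) > 0)
    assert curve.values[0] == pytest.approx(1.0)
    # full-sample reference counts stay monotone even though the
    # split-sample values need not be
    assert np.all(np.diff(curve.raw) <= 0)
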