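# smtrack

Single-molecule tracking (SMT) analysis of transcription-factor chromatin
binding: spot detection and sub-pixel localization, nearest-neighbour
trajectory linking, displacement-threshold bound-state classification, and
photobleach-corrected residence-time analysis with nested
exponential-mixture model selection — plus a ground-truth simulator so
every stage is verifiable by parameter recovery without a microscope.

## The problem

In live-cell SMT, a sparsely labelled nuclear factor appears as
diffraction-limited spots in a time-lapse movie.  Stationary spots are
chromatin-bound molecules; the distribution of how long they stay
stationary carries the binding kinetics.  Getting from movie to kinetics
requires a chain of steps, each with a failure mode: localization noise
mimics motion, diffusing molecules occasionally masquerade as bound, dyes
photobleach before slow binders unbind, and the acquisition interval
itself biases the apparent residence time.  `smtrack` implements the
full chain and quantifies each failure mode on synthetic data with known
truth.

## The model

Bound-molecule dwell times are modelled as a two-exponential mixture.  The
survival distribution S(t) (number of bound segments lasting ≥ t),
corrected for photobleaching and normalized to the bound fraction *B*, is
fitted to

    S(t) = B [ F_ns e^(−k_ns t) + (1 − F_ns) e^(−k_s t) ],

where `F_ns` is the fraction of non-specific (short-lived) binding events
and `T_ns = 1/k_ns`, `T_s = 1/k_s` are the fast and slow residence times.
Single- and three-component models are fitted as well, and a nested F-test
decides whether the extra components are justified.  Photobleaching is
characterized per movie by fitting the frame-dependent number of
detections to a bi-exponential decay, and S(t) is divided by that
survival before fitting.  Molecules count as bound while frame-to-frame
displacements stay ≤ 220 nm and two-frame displacements ≤ 270 nm, for at
least N_min consecutive frames, with N_min chosen per frame rate so that
free diffusion contributes < 1% of the survival histogram.

See `docs/methods.md` for the full model, defaults, and numerical choices.

## Worked example

Simulate a movie with known kinetics and analyse it end to end:

```python
import numpy as np
from smtrack import (AcquisitionConfig, KineticParams, analyze_movie,
                     render_movie, simulate_trajectories)

acq = AcquisitionConfig(image_shape=(256, 256), n_frames=400)   # 200 ms interval
params = KineticParams()           # F_ns 0.8, T_ns 0.5 s, T_s 5 s
rng = np.random.default_rng(7)
truth = simulate_trajectories(params, acq, 50, rng)
stack = render_movie(truth, seed=rng)

result = analyze_movie(stack, acq)
unbound, fast, slow = result.pie_fractions()
fit = result.fits[2]
print(f"order {result.selection.order}: "
      f"T_ns = {fit.T_ns:.2f} s, T_s = {fit.T_s:.2f} s, F_ns = {fit.F_ns:.2f}")
print(f"unbound {unbound:.1%} | fast {fast:.1%} | slow {slow:.1%}")
```

Output (one 400-frame movie, seed 7):

```
order 2: T_ns = 0.75 s, T_s = 4.78 s, F_ns = 0.67
unbound 87.7% | fast 8.3% | slow 4.0%
```

A single small movie yields only ~65 dwell times, so the fitted `T_s` of
4.78 s scatters around the true 5 s; pooling three such movies (as
`tests/test_pipeline_cli.py` does) gives T_s = 4.86 s.  The pie triple is
the standard presentation: most detections are freely diffusing
molecules, and the bound share splits into the fast (non-specific) and
slow (specific) populations by the fitted F_ns.

The same pipeline is scriptable from the shell (`smtrack simulate`,
`detect`, `track`, `classify`, `fit`, `compare`, `sweep`); the numbered
drivers under `analysis/` run the package's standard experiments and
write their tables to `results/`:

```
01_simulate_reference_movie.py   ground truth + bleach curve for the reference condition
02_localization_precision.py     RMS localization error vs photon budget
03_residence_time_recovery.py    bleach-corrected parameter recovery + F-test selection
04_interval_sweep.py             apparent kinetics vs acquisition interval
05_condition_comparison.py       two simulated conditions, KS + t-test
```

For instance, `analysis/04_interval_sweep.py` prints the sampling-bias
table: apparent T_s grows from ≈2 s to ≈16 s as the interval stretches
from 30 ms to 2.5 s while the true value stays 10 s — acquisition
settings, not biology.

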