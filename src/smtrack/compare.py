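"""Cross-condition statistics and the interval-time sweep harness.

Two conditions are compared the way tracking studies report them: the full
dwell-time distributions of the slow (long-lived) populations with a
two-sample Kolmogorov–Smirnov test, and the per-cell long-lived fractions
with a Student's t-test (Welch by default).

The interval sweep re-runs the whole simulate → link → classify → fit
pipeline at a series of frame intervals with the exposure held at 10 ms,
quantifying how the apparent residence time depends on the acquisition
rate when photobleaching is exposure-limited.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (BoundStats, choose_nmin, classify_bound_segments,
                       compute_bound_stats)
from .config import AcquisitionConfig, ClassifierParams, KineticParams
from .kinetics import (BleachModel, ExpMixtureFit, ModelSelection,
                       PopulationSplit, _selection_curve, build_pooled_survival,
                       fit_bleach_model, fit_exp_mixture, select_model,
                       split_populations)
from .linking import link_tracks
from .simulate import simulate_trajectories

__all__ = ["ConditionResult", "ks_compare", "ttest_fraction", "interval_sweep"]


def ks_compare(
    slow_dwells_a: Sequence[float],
    slow_dwells_b: Sequence[float],
) -> Tuple[float, float]:
    """Two-sample KS test on the full dwell distributions of two conditions."""
    a = np.asarray(list(slow_dwells_a), dtype=float)
    b = np.asarray(list(slow_dwells_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if min(a.size, b.size) < 5:
        warnings.warn("KS comparison on fewer than 5 dwells is unreliable",
                      RuntimeWarning)
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def ttest_fraction(
    per_cell_fracs_a: Sequence[float],
    per_cell_fracs_b: Sequence[float],
    equal_var: bool = False,
) -> float:
    """Two-sample t-test p-value on per-cell bound-fraction values.

    Welch's unequal-variance form by default; ``equal_var=True`` switches to
    the pooled-variance Student form.
    """
    a = np.asarray(list(per_cell_fracs_a), dtype=float)
    b = np.asarray(list(per_cell_fracs_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 cells per condition")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 1.0
        raise ValueError("zero variance in both conditions; t-test undefined")
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


@dataclass
class ConditionResult:
    """Pooled analysis of one experimental condition (several cells)."""

    label: str
    per_cell_stats: List[BoundStats]
    fits: Dict[int, ExpMixtureFit]
    selection: ModelSelection
    split: PopulationSplit
    dwells: np.ndarray
    n_cells: int
    n_tracks: int

    @property
    def chosen_fit(self) -> ExpMixtureFit:
        return self.fits[self.selection.order]

    @property
    def per_cell_slow_fraction(self) -> List[float]:
        f_ns = self.chosen_fit.F_ns if self.selection.order >= 2 else None
        return [s.pie_fractions(f_ns)[2] for s in self.per_cell_stats]


def analyze_condition(
    label: str,
    cells: Sequence[Tuple[Sequence[float], BleachModel, BoundStats]],
    interval: float,
    n_tracks: int = 0,
    alpha: float = 0.05,
    fit_order3: bool = True,
) -> ConditionResult:
    """Pool per-cell dwell lists into one corrected fit + model selection.

    Each cell contributes ``(dwells, bleach_model, bound_stats)``; dwells
    are pooled after per-movie bleach correction and the pooled curve is
    normalized to the detection-weighted bound fraction.
    """
    per_cell_stats = [c[2] for c in cells]
    n_b = sum(s.n_bound for s in per_cell_stats)
    n_t = sum(s.n_total for s in per_cell_stats)
    B = n_b / n_t
    groups = [(c[0], c[1]) for c in cells if len(c[0])]
    curve = build_pooled_survival(groups, B, interval)
    fits = {1: fit_exp_mixture(curve, 1), 2: fit_exp_mixture(curve, 2)}
    if fit_order3 and len(curve.times) > 6:
        fits[3] = fit_exp_mixture(curve, 3)

    # order selection on independent-point tabulation; the per-movie bleach
    # corrections enter through their dwell-weighted mean survival
    dwells = np.concatenate([np.asarray(list(c[0]), dtype=float) for c in cells])
    weights = np.array([len(g[0]) for g in groups], dtype=float)
    weights /= weights.sum()
    models = [g[1] for g in groups]

    def pooled_survival(frames):
        return sum(w * m.survival(frames) for w, m in zip(weights, models))

    sel_curve = _selection_curve(dwells, B, pooled_survival, interval)
    s1 = fit_exp_mixture(sel_curve, 1)
    s2 = fit_exp_mixture(sel_curve, 2)
    s3 = (fit_exp_mixture(sel_curve, 3)
          if fit_order3 and len(sel_curve.times) > 6 else None)
    selection = select_model(s1, s2, s3, alpha=alpha)
    split = split_populations(dwells, fits[min(selection.order, 2)])
    return ConditionResult(label=label, per_cell_stats=per_cell_stats, fits=fits,
                           selection=selection, split=split, dwells=dwells,
                           n_cells=len(cells), n_tracks=n_tracks)


def _analyze_cell(
    params: KineticParams,
    acq: AcquisitionConfig,
    classifier: ClassifierParams,
    n_molecules: int,
    rng: np.random.Generator,
    localization_error_nm: float,
):
    """One simulated cell, analysed from ground-truth localizations."""
    truth = simulate_trajectories(params, acq, n_molecules, rng)
    locs = truth.to_localizations(rng, localization_error_nm=localization_error_nm)
    tracks = link_tracks(locs)
    segments = []
    for t in tracks:
        segments.extend(classify_bound_segments(t, classifier, acq.interval_time,
                                                acq.pixel_size_nm))
    dwells = [s.dwell_s for s in segments]
    if segments:
        bstats = compute_bound_stats(segments, tracks, len(locs))
    else:
        bstats = BoundStats(n_bound=0, n_total=max(len(locs), 1))
    counts = np.bincount(locs["frame"].to_numpy(dtype=int), minlength=acq.n_frames)
    bleach = fit_bleach_model(counts)
    return dwells, bleach, bstats, len(tracks)


def interval_sweep(
    params: KineticParams,
    acq_template: AcquisitionConfig,
    intervals: Sequence[float],
    n_cells: int = 6,
    n_molecules: int = 60,
    seed: int = 0,
    localization_error_nm: float = 20.0,
    alpha: float = 0.05,
    fixed_duration_s: Optional[float] = None,
) -> pd.DataFrame:
    """Full-pipeline sweep over frame intervals at fixed 10 ms exposure.

    For each interval: simulate ``n_cells`` nuclei, link ground-truth
    localizations into tracks, classify bound segments with the
    interval-appropriate N_min, bleach-correct per cell, fit mixture orders
    1–3 and select by F-test.  Returns one row per interval with the
    apparent residence times, tracks per cell and the chosen order.

    Movies have fixed wall-clock duration (default: the template's), so the
    frame count scales inversely with the interval — per-cell track counts
    are then comparable across acquisition rates.
    """
    if list(intervals) != sorted(intervals):
        raise ValueError("intervals must be sorted ascending")
    duration = fixed_duration_s or acq_template.duration
    rows = []
    for i, interval in enumerate(intervals):
        rng = np.random.default_rng((seed, i))
        n_frames = max(int(round(duration / interval)), 24)
        acq = dataclasses.replace(acq_template, interval_time=float(interval),
                                  n_frames=n_frames)
        n_min = choose_nmin(interval, params.D_free)
        classifier = ClassifierParams(n_min=n_min)
        cells = []
        n_tracks = 0
        for _ in range(n_cells):
            dwells, bleach, bstats, nt = _analyze_cell(
                params, acq, classifier, n_molecules, rng, localization_error_nm)
            cells.append((dwells, bleach, bstats))
            n_tracks += nt
        res = analyze_condition(f"interval={interval}", cells, interval,
                                n_tracks=n_tracks, alpha=alpha)
        fit = res.chosen_fit
        rows.append({
            "interval_s": interval,
            "n_min": n_min,
            "tracks_per_cell": n_tracks / n_cells,
            "n_dwells": int(len(res.dwells)),
            "order": res.selection.order,
            "T_ns_s": fit.T_ns if fit.order >= 2 else np.nan,
            "T_s_s": fit.T_s,
            "F_ns": fit.F_ns if fit.order >= 2 else np.nan,
            "p_12": res.selection.p_12,
            "p_23": res.selection.p_23,
        })
    return pd.DataFrame(rows)
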