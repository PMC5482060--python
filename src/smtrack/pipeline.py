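"""End-to-end analysis: localization table (or movie) in, kinetics out."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .classify import (BoundStats, choose_nmin, classify_bound_segments,
                       compute_bound_stats)
from .config import AcquisitionConfig, ClassifierParams
from .detect import detect_movie
from .kinetics import (BleachModel, ExpMixtureFit, ModelSelection,
                       PopulationSplit, fit_and_select, fit_bleach_model,
                       split_populations)
from .linking import Track, link_tracks

__all__ = ["MovieAnalysis", "analyze_localizations", "analyze_movie"]


@dataclass
class MovieAnalysis:
    """Everything the pipeline derives from one movie."""

    tracks: List[Track]
    segments: list
    dwells: np.ndarray
    stats: BoundStats
    bleach: BleachModel
    fits: Dict[int, ExpMixtureFit]
    selection: ModelSelection
    split: PopulationSplit
    n_min: int

    @property
    def chosen_fit(self) -> ExpMixtureFit:
        return self.fits[self.selection.order]

    def pie_fractions(self):
        """(unbound, fast, slow) shares of all detections, summing to 1."""
        f_ns = self.chosen_fit.F_ns if self.selection.order >= 2 else None
        return self.stats.pie_fractions(f_ns)


def analyze_localizations(
    locs: pd.DataFrame,
    acq: AcquisitionConfig,
    classifier: Optional[ClassifierParams] = None,
    d_free: float = 2.0,
    alpha: float = 0.05,
    max_disp_px: float = 4.0,
    min_track_len: int = 6,
    fit_order3: bool = True,
) -> MovieAnalysis:
    """Link, classify, bleach-correct and fit one movie's localizations.

    ``d_free`` (um^2/s) sets N_min when the classifier does not fix it.
    """
    classifier = classifier or ClassifierParams()
    if classifier.n_min is None:
        n_min = choose_nmin(acq.interval_time, d_free, classifier)
        classifier = dataclasses.replace(classifier, n_min=n_min)
    tracks = link_tracks(locs, max_disp_px=max_disp_px, min_length=min_track_len)
    segments = []
    for t in tracks:
        segments.extend(classify_bound_segments(t, classifier, acq.interval_time,
                                                acq.pixel_size_nm))
    if not segments:
        raise RuntimeError("no bound segments found; cannot fit residence times")
    dwells = np.array([s.dwell_s for s in segments])
    stats = compute_bound_stats(segments, tracks, len(locs))
    counts = np.bincount(locs["frame"].to_numpy(dtype=int), minlength=acq.n_frames)
    bleach = fit_bleach_model(counts)
    fits, selection = fit_and_select(dwells, stats.bound_fraction, bleach,
                                     acq.interval_time, alpha=alpha,
                                     fit_order3=fit_order3)
    split = split_populations(dwells, fits[min(selection.order, 2)])
    return MovieAnalysis(tracks=tracks, segments=segments, dwells=dwells,
                         stats=stats, bleach=bleach, fits=fits,
                         selection=selection, split=split,
                         n_min=classifier.n_min)


def analyze_movie(stack: np.ndarray, acq: AcquisitionConfig, **kwargs) -> MovieAnalysis:
    """Detect spots in an image stack, then run :func:`analyze_localizations`."""
    locs = detect_movie(stack)
    return analyze_localizations(locs, acq, **kwargs)
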