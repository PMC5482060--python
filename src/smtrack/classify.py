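"""Bound/unbound classification of tracks and dwell-time extraction.

A molecule counts as chromatin-bound while every frame-to-frame
displacement stays within ``r_max1`` (220 nm) and every two-frame
displacement within ``r_max2`` (270 nm); the two-frame test is applied
where both neighbours lie inside the segment.  Because a freely diffusing
molecule occasionally satisfies these thresholds by chance, a segment must
additionally contain at least ``N_min`` localizations, with ``N_min``
chosen per frame interval so that fewer than 1% of pure-diffusion
localizations leak into the survival histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import ClassifierParams
from .linking import Track

__all__ = [
    "BoundSegment",
    "BoundStats",
    "classify_bound_segments",
    "compute_bound_stats",
    "choose_nmin",
    "brownian_step_pass_probability",
]


@dataclass
class BoundSegment:
    """A maximal stationary stretch of one track."""

    track_id: int
    start_frame: int
    end_frame: int
    n_frames: int
    dwell_s: float           # (n_frames - 1) * interval
    censored: bool           # segment touches the end of its track

    def __post_init__(self):
        if self.dwell_s <= 0:
            raise ValueError("dwell_s must be positive")


@dataclass
class BoundStats:
    """Bound-fraction bookkeeping for one movie or condition."""

    n_bound: int      # localizations inside bound segments (N_B)
    n_total: int      # all detected particles incl. single-frame detections

    @property
    def bound_fraction(self) -> float:
        return self.n_bound / self.n_total

    def pie_fractions(self, f_ns: Optional[float]) -> Tuple[float, float, float]:
        """(unbound, fast, slow) fractions, summing to 1 exactly.

        ``f_ns`` is the non-specific share from the survival fit; ``None``
        (single-component fit) puts the whole bound share in ``slow``.
        """
        b = self.bound_fraction
        if f_ns is None:
            fast = 0.0
        else:
            fast = b * f_ns
        slow = b - fast
        return (1.0 - b, fast, slow)


def classify_bound_segments(
    track: Track,
    params: ClassifierParams,
    interval_s: float,
    pixel_size_nm: float,
) -> List[BoundSegment]:
    """Extract maximal bound runs of a track that pass both thresholds.

    Scans left to right, extending a run while the next point keeps all
    frame-to-frame displacements <= r_max1 and all interior two-frame
    displacements <= r_max2; runs shorter than ``n_min`` localizations are
    dropped.  A run that reaches the last point of the track is flagged
    censored (the binding event may have outlived the track).
    """
    if params.n_min is None:
        raise ValueError("ClassifierParams.n_min must be set (see choose_nmin)")
    step = track.step_displacements_nm(pixel_size_nm)
    two = track.two_frame_displacements_nm(pixel_size_nm)
    ok1 = step <= params.r_max1_nm
    ok2 = two <= params.r_max2_nm
    n = len(track)
    segments: List[BoundSegment] = []
    i = 0
    while i < n - 1:
        if not ok1[i]:
            i += 1
            continue
        j = i + 1
        while j < n - 1 and ok1[j] and (j - 1 < i or ok2[j - 1]):
            j += 1
        n_pts = j - i + 1
        if n_pts >= params.n_min:
            segments.append(BoundSegment(
                track_id=track.track_id,
                start_frame=int(track.frames[i]),
                end_frame=int(track.frames[j]),
                n_frames=n_pts,
                dwell_s=(n_pts - 1) * interval_s,
                censored=bool(j == n - 1),
            ))
        i = j + 1
    return segments


def compute_bound_stats(
    segments: Sequence[BoundSegment],
    tracks: Sequence[Track],
    n_total_detections: int,
) -> BoundStats:
    """Count bound localizations and form B = N_B / N_total.

    ``n_total_detections`` must include every detected particle, also the
    single-frame detections that never entered a track.  Gap-filled points
    are positions in the trajectory, not detections, so they are excluded
    from both numerator and denominator.
    """
    if n_total_detections <= 0:
        raise ValueError("n_total_detections must be > 0")
    by_id = {t.track_id: t for t in tracks}
    n_bound = 0
    for seg in segments:
        t = by_id[seg.track_id]
        inside = (t.frames >= seg.start_frame) & (t.frames <= seg.end_frame)
        n_bound += int(np.sum(inside & ~t.gap_filled))
    return BoundStats(n_bound=n_bound, n_total=int(n_total_detections))


def brownian_step_pass_probability(
    interval_s: float, d_free: float, r_max1_nm: float
) -> float:
    """P(|step| <= r) for a 2D Brownian step: 1 - exp(-r^2 / (4 D dt))."""
    r_um = r_max1_nm / 1000.0
    return 1.0 - np.exp(-(r_um ** 2) / (4.0 * d_free * interval_s))


def choose_nmin(
    interval_s: float,
    d_free: float = 2.0,
    params: Optional[ClassifierParams] = None,
    max_contamination: float = 0.01,
) -> int:
    """Smallest N_min keeping diffusing molecules below ``max_contamination``.

    Uses the closed-form per-step pass probability
    ``p = 1 - exp(-r_max1^2 / (4 D dt))``; a segment of N localizations
    requires N-1 consecutive independent passing steps, so N_min is the
    smallest N >= 2 with ``p**(N-1) < max_contamination``.
    """
    if d_free <= 0:
        raise ValueError(f"d_free must be > 0, got {d_free}")
    r = (params or ClassifierParams()).r_max1_nm
    p = brownian_step_pass_probability(interval_s, d_free, r)
    if p <= 0.0:
        return 2
    n_min = 2
    while p ** (n_min - 1) >= max_contamination:
        n_min += 1
        if n_min > 1000:
            raise RuntimeError(
                "no practical N_min suppresses diffusing molecules below "
                f"{max_contamination}: per-step pass probability {p:.4f}"
            )
    return n_min
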