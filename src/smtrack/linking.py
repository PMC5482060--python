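"""Nearest-neighbour trajectory linking with single-frame gap closing.

Localizations in consecutive frames are matched greedily in order of
ascending distance among all pairs closer than ``max_disp_px`` (4 px by
default).  A track that misses one frame may reclaim a localization in the
next frame within a wider gap radius; the missing position is then filled
with the mean of the flanking frames and flagged.  Gaps of two or more
frames terminate the track, and only tracks of at least ``min_length``
localizations (gap-filled points included) are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["Track", "link_tracks", "fill_gaps", "tracks_to_table"]


@dataclass(eq=False)
class Track:
    """Time-ordered localizations of one molecule."""

    track_id: int
    frames: np.ndarray       # int, strictly increasing
    x: np.ndarray            # px (column)
    y: np.ndarray            # px (row)
    gap_filled: np.ndarray   # bool
    intensity: np.ndarray = None

    def __post_init__(self):
        if self.intensity is None:
            self.intensity = np.full(len(self.frames), np.nan)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def step_displacements_nm(self, pixel_size_nm: float) -> np.ndarray:
        """Frame-to-frame displacements in nm (length len-1)."""
        return np.hypot(np.diff(self.x), np.diff(self.y)) * pixel_size_nm

    def two_frame_displacements_nm(self, pixel_size_nm: float) -> np.ndarray:
        """Displacements over two frames in nm (length len-2)."""
        return np.hypot(self.x[2:] - self.x[:-2], self.y[2:] - self.y[:-2]) * pixel_size_nm


def _greedy_match(
    ax: np.ndarray, ay: np.ndarray, bx: np.ndarray, by: np.ndarray, r: float
) -> List[Tuple[int, int]]:
    """Conflict-free (i, j) pairs accepted in ascending-distance order."""
    if len(ax) == 0 or len(bx) == 0:
        return []
    d = np.hypot(ax[:, None] - bx[None, :], ay[:, None] - by[None, :])
    ii, jj = np.nonzero(d <= r)
    if ii.size == 0:
        return []
    order = np.lexsort((jj, ii, d[ii, jj]))
    used_a = set()
    used_b = set()
    pairs = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


class _OpenTrack:
    __slots__ = ("frames", "x", "y", "intensity", "gap", "misses")

    def __init__(self, frame, x, y, intensity):
        self.frames = [frame]
        self.x = [x]
        self.y = [y]
        self.intensity = [intensity]
        self.gap = []      # frame indices later marked gap-filled
        self.misses = 0

    def append(self, frame, x, y, intensity):
        # a single-frame gap is closed with the mean of the flanking frames
        if frame - self.frames[-1] == 2:
            self.frames.append(frame - 1)
            self.x.append(0.5 * (self.x[-1] + x))
            self.y.append(0.5 * (self.y[-1] + y))
            self.intensity.append(np.nan)
            self.gap.append(frame - 1)
        self.frames.append(frame)
        self.x.append(x)
        self.y.append(y)
        self.intensity.append(intensity)
        self.misses = 0


def link_tracks(
    localizations: pd.DataFrame,
    max_disp_px: float = 4.0,
    min_length: int = 6,
    gap_radius_factor: float = 2.0,
    fill: bool = True,
) -> List[Track]:
    """Link a localization table into tracks.

    ``localizations`` needs columns frame, x_px, y_px (intensity optional).
    Matching is greedy nearest-neighbour within ``max_disp_px``; a track
    unmatched in one frame may close a single-frame gap within
    ``gap_radius_factor * max_disp_px`` of its last position.  When
    ``fill=False`` the gap positions are left out (frames then step by 2
    across a gap) for callers that want to interpolate separately with
    :func:`fill_gaps`.
    """
    for col in ("frame", "x_px", "y_px"):
        if col not in localizations.columns:
            raise ValueError(f"localization table is missing column '{col}'")
    df = localizations.sort_values("frame", kind="stable")
    frames = df["frame"].to_numpy(dtype=int)
    xs = df["x_px"].to_numpy(dtype=float)
    ys = df["y_px"].to_numpy(dtype=float)
    intens = (df["intensity"].to_numpy(dtype=float)
              if "intensity" in df.columns else np.full(len(df), np.nan))

    open_tracks: List[_OpenTrack] = []
    done: List[_OpenTrack] = []
    if len(frames) == 0:
        return []

    f_min, f_max = int(frames.min()), int(frames.max())
    start = 0
    by_frame = {}
    for f in range(f_min, f_max + 1):
        stop = start
        while stop < len(frames) and frames[stop] == f:
            stop += 1
        by_frame[f] = slice(start, stop)
        start = stop

    for f in range(f_min, f_max + 1):
        sl = by_frame[f]
        lx, ly, li = xs[sl], ys[sl], intens[sl]
        unmatched = np.ones(len(lx), dtype=bool)

        # pass 1: tracks seen in the previous frame
        cur = [t for t in open_tracks if t.misses == 0]
        pairs = _greedy_match(
            np.array([t.x[-1] for t in cur]), np.array([t.y[-1] for t in cur]),
            lx, ly, max_disp_px,
        ) if cur else []
        matched_tracks = set()
        for i, j in pairs:
            cur[i].append(f, lx[j], ly[j], li[j])
            matched_tracks.add(id(cur[i]))
            unmatched[j] = False

        # pass 2: tracks with one missed frame close a single-frame gap
        gap = [t for t in open_tracks if t.misses == 1 and id(t) not in matched_tracks]
        rem = np.nonzero(unmatched)[0]
        pairs = _greedy_match(
            np.array([t.x[-1] for t in gap]), np.array([t.y[-1] for t in gap]),
            lx[rem], ly[rem], gap_radius_factor * max_disp_px,
        ) if gap and rem.size else []
        for i, j in pairs:
            gap[i].append(f, lx[rem[j]], ly[rem[j]], li[rem[j]])
            matched_tracks.add(id(gap[i]))
            unmatched[rem[j]] = False

        # bookkeeping: retire twice-missed tracks, open new ones
        still_open = []
        for t in open_tracks:
            if id(t) in matched_tracks:
                still_open.append(t)
            else:
                t.misses += 1
                if t.misses >= 2:
                    done.append(t)
                else:
                    still_open.append(t)
        open_tracks = still_open
        for j in np.nonzero(unmatched)[0]:
            open_tracks.append(_OpenTrack(f, lx[j], ly[j], li[j]))
    done.extend(open_tracks)

    tracks: List[Track] = []
    tid = 0
    for t in done:
        if len(t.frames) < min_length:
            continue
        fr = np.array(t.frames, dtype=int)
        gf = np.isin(fr, t.gap)
        if not fill and gf.any():
            keep = ~gf
            fr, xa, ya, ia = fr[keep], np.array(t.x)[keep], np.array(t.y)[keep], np.array(t.intensity)[keep]
            gf = np.zeros(len(fr), dtype=bool)
        else:
            xa, ya, ia = np.array(t.x), np.array(t.y), np.array(t.intensity)
        tracks.append(Track(tid, fr, xa, ya, gf, ia))
        tid += 1
    return tracks


def fill_gaps(tracks: Sequence[Track]) -> List[Track]:
    """Interpolate single-frame gaps with the mean of the flanking positions.

    Tracks without gaps are returned unchanged.  Gaps of two or more frames
    are not closed here — linking already terminates such tracks — so any
    remaining multi-frame jump splits the track, keeping pieces of at least
    two points for the caller to re-filter by length.
    """
    out: List[Track] = []
    next_id = max((t.track_id for t in tracks), default=-1) + 1
    for t in tracks:
        steps = np.diff(t.frames)
        if np.all(steps == 1):
            out.append(t)
            continue
        pieces = np.split(np.arange(len(t.frames)), np.nonzero(steps > 2)[0] + 1)
        for p_i, idx in enumerate(pieces):
            fr, xa, ya = t.frames[idx], t.x[idx], t.y[idx]
            ia, gf = t.intensity[idx], t.gap_filled[idx]
            ins = np.nonzero(np.diff(fr) == 2)[0]
            for k in ins[::-1]:
                fr = np.insert(fr, k + 1, fr[k] + 1)
                xa = np.insert(xa, k + 1, 0.5 * (xa[k] + xa[k + 1]))
                ya = np.insert(ya, k + 1, 0.5 * (ya[k] + ya[k + 1]))
                ia = np.insert(ia, k + 1, np.nan)
                gf = np.insert(gf, k + 1, True)
            tid = t.track_id if p_i == 0 else next_id
            if p_i > 0:
                next_id += 1
            out.append(Track(tid, fr, xa, ya, gf, ia))
    return out


def tracks_to_table(tracks: Sequence[Track], pixel_size_nm: float) -> pd.DataFrame:
    """Flatten tracks into a tidy table with nm coordinates alongside px."""
    rows = []
    for t in tracks:
        for i in range(len(t)):
            rows.append((t.track_id, int(t.frames[i]), t.x[i], t.y[i],
                         t.x[i] * pixel_size_nm, t.y[i] * pixel_size_nm,
                         bool(t.gap_filled[i])))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px",
                                       "x_nm", "y_nm", "gap_filled"])
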