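"""Ground-truth simulator for single-molecule tracking experiments.

Three fidelity levels, each feeding a different stage of the analysis:

1. :func:`sample_dwell_times` — raw dwell-time draws from the two-class
   exponential mixture (oracle for the survival fitting);
2. :func:`simulate_trajectories` — per-frame state/position trajectories of
   molecules switching between free diffusion and chromatin binding, with
   photobleaching applied during exposure windows only (oracle for linking
   and bound classification);
3. :func:`render_movie` — 16-bit image stacks with a Gaussian PSF and
   Poisson photon statistics (oracle for detection and localization).

The molecule model is a three-state continuous-time chain: a free molecule
binds at rate ``k_bind``; the event is non-specific (mean dwell ``T_ns``)
with probability ``p_ns`` and specific (mean dwell ``T_s``) otherwise; an
unbinding molecule resumes free diffusion and may rebind.  Photobleaching
only proceeds while the laser is on, so the number of *exposures* a dye
survives is interval-independent — the mechanism by which longer intervals
extend the trackable lifetime in wall-clock seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import AcquisitionConfig, KineticParams

__all__ = [
    "GroundTruth",
    "sample_dwell_times",
    "sample_bleach_exposures",
    "simulate_trajectories",
    "brownian_tracks",
    "render_movie",
]

STATE_FREE = "free"
STATE_NS = "bound_ns"
STATE_S = "bound_s"


def _as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_dwell_times(
    params: KineticParams,
    n: int,
    seed: Union[int, np.random.Generator, None] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` binding-event dwell times from the two-class mixture.

    Returns ``(dwells_s, classes)`` where ``classes`` contains ``"ns"`` or
    ``"s"``.  Each dwell is exponential with mean ``T_ns`` (probability
    ``p_ns``) or ``T_s``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(seed)
    is_ns = rng.random(n) < params.p_ns
    means = np.where(is_ns, params.T_ns, params.T_s)
    dwells = rng.exponential(means)
    classes = np.where(is_ns, "ns", "s")
    return dwells, classes


def mixture_survival(t: np.ndarray, params: KineticParams) -> np.ndarray:
    """Closed-form survival of the dwell mixture, P(dwell >= t)."""
    t = np.asarray(t, dtype=float)
    return params.p_ns * np.exp(-t / params.T_ns) + params.p_s * np.exp(-t / params.T_s)


def sample_bleach_exposures(
    params: KineticParams,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous number of exposures survived before photobleaching.

    Drawn from the bi-exponential survival a*exp(-k1*f) + (1-a)*exp(-k2*f).
    A decay constant of zero means that branch never bleaches.
    """
    fast = rng.random(n) < params.bleach_amp
    out = np.empty(n)
    for flag, k in ((True, params.bleach_k1), (False, params.bleach_k2)):
        sel = fast == flag
        if k > 0:
            out[sel] = rng.exponential(1.0 / k, size=sel.sum())
        else:
            out[sel] = np.inf
    return out


@dataclass
class GroundTruth:
    """Per-frame molecule table plus per-event dwell table.

    ``frames`` columns: molecule_id, frame, x_px, y_px, state, event_id
    (event_id is -1 for free molecules).  Rows exist only while the molecule
    is unbleached; once bleached it never reappears.

    ``events`` columns: molecule_id, event_id, state, t_start_s, dwell_s,
    truncated (dwell clipped by the movie window).
    """

    frames: pd.DataFrame
    events: pd.DataFrame
    acquisition: AcquisitionConfig
    kinetics: KineticParams

    @property
    def n_molecules(self) -> int:
        return int(self.frames["molecule_id"].nunique())

    def detections_per_frame(self) -> np.ndarray:
        """Number of visible molecules in each frame of the movie."""
        counts = np.zeros(self.acquisition.n_frames, dtype=int)
        vc = self.frames["frame"].value_counts()
        counts[vc.index.to_numpy()] = vc.to_numpy()
        return counts

    def to_localizations(
        self,
        seed: Union[int, np.random.Generator, None] = None,
        localization_error_nm: float = 0.0,
    ) -> pd.DataFrame:
        """Ground-truth positions formatted as a localization table.

        Bypasses rendering + detection for pipeline stages that accept
        pre-computed localizations.  Applies the configured per-frame
        detection-failure probability ``p_miss`` and, optionally, isotropic
        Gaussian localization error.
        """
        rng = _as_rng(seed)
        df = self.frames
        keep = np.ones(len(df), dtype=bool)
        if self.kinetics.p_miss > 0:
            keep = rng.random(len(df)) >= self.kinetics.p_miss
        out = df.loc[keep, ["frame", "x_px", "y_px"]].copy()
        if localization_error_nm > 0:
            sd_px = localization_error_nm / self.acquisition.pixel_size_nm
            out["x_px"] = out["x_px"] + rng.normal(0, sd_px, len(out))
            out["y_px"] = out["y_px"] + rng.normal(0, sd_px, len(out))
        out["intensity"] = np.nan
        out["sigma_px"] = np.nan
        out["gap_filled"] = False
        return out.sort_values(["frame", "x_px"], kind="stable").reset_index(drop=True)


def _reflect(x: np.ndarray, hi: float) -> np.ndarray:
    """Reflect coordinates into [0, hi]."""
    period = 2.0 * hi
    x = np.mod(x, period)
    return np.where(x > hi, period - x, x)


def _simulate_state_intervals(
    params: KineticParams,
    total_time: float,
    rng: np.random.Generator,
) -> List[Tuple[float, float, str]]:
    """Event-driven state sequence [(t_start, t_end, state), ...] on [0, T].

    The initial state is drawn from the stationary distribution of the
    chain, so frame-0 occupancies are already at equilibrium; residual
    dwells of in-progress events are exponential by memorylessness.
    """
    occ = params.stationary_occupancy()
    u = rng.random()
    if u < occ["free"]:
        state = STATE_FREE
    elif u < occ["free"] + occ["bound_ns"]:
        state = STATE_NS
    else:
        state = STATE_S

    intervals: List[Tuple[float, float, str]] = []
    t = 0.0
    while t < total_time:
        if state == STATE_FREE:
            dur = rng.exponential(1.0 / params.k_bind) if params.k_bind > 0 else np.inf
            nxt = STATE_NS if rng.random() < params.p_ns else STATE_S
        elif state == STATE_NS:
            dur = rng.exponential(params.T_ns)
            nxt = STATE_FREE
        else:
            dur = rng.exponential(params.T_s)
            nxt = STATE_FREE
        end = min(t + dur, total_time)
        intervals.append((t, end, state))
        t = t + dur
        state = nxt
    return intervals


def simulate_trajectories(
    params: KineticParams,
    acq: AcquisitionConfig,
    n_molecules: int,
    seed: Union[int, np.random.Generator, None] = None,
) -> GroundTruth:
    """Simulate state/position trajectories for ``n_molecules`` molecules.

    State switching happens in continuous time and is sampled at frame
    starts.  Free molecules take Brownian steps with per-axis variance
    ``2 * D_free * interval`` (scaled down when only part of the interval is
    spent free); bound molecules jitter around a fixed anchor with sd
    ``bound_jitter_nm``.  Photobleaching truncates visibility after a
    bi-exponentially distributed number of exposures.
    """
    if n_molecules < 1:
        raise ValueError(f"n_molecules must be >= 1, got {n_molecules}")
    rng = _as_rng(seed)
    dt = acq.interval_time
    n_frames = acq.n_frames
    px = acq.pixel_size_nm
    step_sd_px = np.sqrt(2.0 * params.D_free * dt) * 1000.0 / px  # um -> nm -> px
    jitter_sd_px = params.bound_jitter_nm / px
    hi_r = acq.image_shape[0] - 1.0
    hi_c = acq.image_shape[1] - 1.0

    bleach = sample_bleach_exposures(params, n_molecules, rng)

    if acq.nucleus_mask is not None:
        rows, cols = np.nonzero(acq.nucleus_mask)
    else:
        rows = cols = None

    frame_rows = []
    event_rows = []
    event_counter = 0
    frame_times = np.arange(n_frames) * dt

    for mid in range(n_molecules):
        last_visible = (n_frames - 1 if not np.isfinite(bleach[mid])
                        else min(n_frames - 1, int(np.floor(bleach[mid]))))
        if last_visible < 0:
            continue
        n_vis = last_visible + 1
        intervals = _simulate_state_intervals(params, acq.duration, rng)
        starts = np.array([iv[0] for iv in intervals])
        states = [iv[2] for iv in intervals]

        # event bookkeeping (bound intervals only), over the full movie window
        event_ids = np.full(len(intervals), -1, dtype=int)
        for i, (t0, t1, st) in enumerate(intervals):
            if st == STATE_FREE:
                continue
            event_ids[i] = event_counter
            truncated = t1 >= acq.duration
            event_rows.append(
                (mid, event_counter, st, t0, t1 - t0, truncated)
            )
            event_counter += 1

        t_vis = frame_times[:n_vis]
        idx = np.clip(np.searchsorted(starts, t_vis, side="right") - 1, 0, len(intervals) - 1)
        frame_states = np.array([states[i] for i in idx], dtype=object)
        frame_events = event_ids[idx]

        # positions: iterate over runs of constant state
        if rows is not None:
            k = rng.integers(len(rows))
            pos = np.array([rows[k] + rng.random() - 0.5, cols[k] + rng.random() - 0.5])
        else:
            pos = np.array([rng.uniform(0, hi_r), rng.uniform(0, hi_c)])
        xs = np.empty(n_vis)
        ys = np.empty(n_vis)
        run_start = 0
        while run_start < n_vis:
            run_end = run_start
            while run_end + 1 < n_vis and frame_states[run_end + 1] == frame_states[run_start] \
                    and frame_events[run_end + 1] == frame_events[run_start]:
                run_end += 1
            m = run_end - run_start + 1
            if frame_states[run_start] == STATE_FREE:
                steps = rng.normal(0.0, step_sd_px, size=(m, 2))
                if run_start == 0:
                    steps[0] = 0.0
                traj = pos + np.cumsum(steps, axis=0)
                pos = traj[-1].copy()
            else:
                anchor = pos.copy()
                traj = anchor + rng.normal(0.0, jitter_sd_px, size=(m, 2))
                pos = anchor
            xs[run_start:run_end + 1] = _reflect(traj[:, 1], hi_c)
            ys[run_start:run_end + 1] = _reflect(traj[:, 0], hi_r)
            run_start = run_end + 1

        for f in range(n_vis):
            frame_rows.append(
                (mid, f, xs[f], ys[f], frame_states[f], frame_events[f])
            )

    frames = pd.DataFrame(
        frame_rows,
        columns=["molecule_id", "frame", "x_px", "y_px", "state", "event_id"],
    )
    events = pd.DataFrame(
        event_rows,
        columns=["molecule_id", "event_id", "state", "t_start_s", "dwell_s", "truncated"],
    )
    return GroundTruth(frames=frames, events=events, acquisition=acq, kinetics=params)


def brownian_tracks(
    n_tracks: int,
    n_frames: int,
    d_free: float,
    interval_s: float,
    pixel_size_nm: float = 106.7,
    seed: Union[int, np.random.Generator, None] = None,
) -> List[np.ndarray]:
    """Pure free-diffusion trajectories, unbounded plane.

    Returns a list of (n_frames, 2) pixel-coordinate arrays.  Used to
    measure how often a diffusing molecule slips under the bound-state
    displacement thresholds.
    """
    rng = _as_rng(seed)
    step_sd_px = np.sqrt(2.0 * d_free * interval_s) * 1000.0 / pixel_size_nm
    steps = rng.normal(0.0, step_sd_px, size=(n_tracks, n_frames, 2))
    steps[:, 0, :] = 0.0
    return list(np.cumsum(steps, axis=1))


def _render_spots(
    frame: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    photons: float,
    sigma_px: float,
) -> None:
    """Add integrated-Gaussian spots (expected photons) to ``frame`` in place."""
    from scipy.special import erf

    h, w = frame.shape
    r = max(3, int(np.ceil(4 * sigma_px)))
    s2 = sigma_px * np.sqrt(2.0)
    for x, y in zip(xs, ys):
        c0, c1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
        r0, r1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
        c0, c1 = max(c0, 0), min(c1, w)
        r0, r1 = max(r0, 0), min(r1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        fx = 0.5 * (erf((cols + 0.5 - x) / s2) - erf((cols - 0.5 - x) / s2))
        fy = 0.5 * (erf((rows + 0.5 - y) / s2) - erf((rows - 0.5 - y) / s2))
        frame[r0:r1, c0:c1] += photons * np.outer(fy, fx)


def render_movie(
    truth: GroundTruth,
    params: Optional[KineticParams] = None,
    acq: Optional[AcquisitionConfig] = None,
    seed: Union[int, np.random.Generator, None] = None,
    poisson_noise: bool = True,
    background_gradient: float = 0.4,
) -> np.ndarray:
    """Render a ground truth into a 16-bit image stack.

    Each visible molecule becomes an integrated 2D Gaussian of width
    ``psf_sigma_nm`` carrying ``photons_per_frame`` expected photons; the
    background is uniform plus a linear gradient (relative span
    ``background_gradient`` across the field).  Per-pixel counts are Poisson
    unless ``poisson_noise=False`` (then the expected scene is returned,
    rounded).
    """
    params = params or truth.kinetics
    acq = acq or truth.acquisition
    if params.psf_sigma_nm <= 0:
        raise ValueError(f"psf_sigma_nm must be > 0, got {params.psf_sigma_nm}")
    rng = _as_rng(seed)
    h, w = acq.image_shape
    sigma_px = params.psf_sigma_nm / acq.pixel_size_nm

    cols = np.arange(w) / max(w - 1, 1)
    bg = params.background_rate * (1.0 - background_gradient / 2 + background_gradient * cols)
    bg = np.broadcast_to(bg, (h, w))

    by_frame = dict(tuple(truth.frames.groupby("frame")))
    stack = np.empty((acq.n_frames, h, w), dtype=np.uint16)
    for f in range(acq.n_frames):
        scene = np.array(bg, dtype=float)
        grp = by_frame.get(f)
        if grp is not None and len(grp):
            _render_spots(scene, grp["x_px"].to_numpy(), grp["y_px"].to_numpy(),
                          params.photons_per_frame, sigma_px)
        if poisson_noise:
            frame = rng.poisson(scene)
        else:
            frame = np.round(scene)
        stack[f] = np.clip(frame, 0, 65535).astype(np.uint16)
    return stack
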