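"""Photobleach-corrected survival distributions and exponential-mixture fits.

The survival distribution S(t) counts bound segments with dwell >= t.  Dye
loss removes long dwells, so S(t) is divided by the fluorophore survival
P_bleach(t/interval) — a bi-exponential fitted per movie to the
frame-dependent number of detections — and then renormalized so that the
curve starts at the bound fraction B.  The corrected curve is fitted by
unweighted least squares to nested exponential-mixture models,

    order 1:  S(t) = B exp(-k t)
    order 2:  S(t) = B [F_ns exp(-k_ns t) + (1 - F_ns) exp(-k_s t)]
    order 3:  S(t) = B [F_ns exp(-k_ns t) + F_s1 exp(-k_s1 t)
                        + (1 - F_ns - F_s1) exp(-k_s2 t)]

with residence times T = 1/k, and the orders compared by an F-test on the
residual sums of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "BleachModel",
    "SurvivalCurve",
    "ExpMixtureFit",
    "ModelSelection",
    "PopulationSplit",
    "fit_bleach_model",
    "build_survival",
    "build_pooled_survival",
    "build_selection_curve",
    "fit_and_select",
    "fit_exp_mixture",
    "select_model",
    "split_populations",
]


@dataclass(frozen=True)
class BleachModel:
    """Bi-exponential fluorophore survival over exposures, P(0) = 1."""

    amp: float     # fraction on the fast decay, in [0, 1]
    lam1: float    # per exposure, fast
    lam2: float    # per exposure, slow

    def __post_init__(self):
        if not (0.0 <= self.amp <= 1.0):
            raise ValueError(f"amp must be in [0, 1], got {self.amp}")
        if self.lam1 < 0 or self.lam2 < 0:
            raise ValueError("decay constants must be >= 0")

    def survival(self, frames: np.ndarray) -> np.ndarray:
        f = np.asarray(frames, dtype=float)
        return self.amp * np.exp(-self.lam1 * f) + (1.0 - self.amp) * np.exp(-self.lam2 * f)

    @classmethod
    def identity(cls) -> "BleachModel":
        """No-bleaching model; the correction becomes a no-op."""
        return cls(amp=1.0, lam1=0.0, lam2=0.0)


def fit_bleach_model(detections_per_frame: np.ndarray) -> BleachModel:
    """Fit counts-vs-frame to c0 * [a e^(-l1 f) + (1-a) e^(-l2 f)].

    Characterizes photobleaching for one movie.  Needs at least 10 frames
    with detections; all-zero counts are rejected.
    """
    counts = np.asarray(detections_per_frame, dtype=float)
    if np.count_nonzero(counts) < 10:
        raise ValueError("need detections in at least 10 frames to fit bleaching")
    f = np.arange(len(counts), dtype=float)
    c0_guess = max(counts[:5].mean(), 1.0)

    # crude single-exponential slope as a starting scale
    pos = counts > 0
    slope, _ = np.polyfit(f[pos], np.log(counts[pos]), 1)
    lam_guess = max(-slope, 1e-6)

    def resid(p):
        c0, a, l1, l2 = p
        return c0 * (a * np.exp(-l1 * f) + (1 - a) * np.exp(-l2 * f)) - counts

    best = None
    for l1_0, l2_0, a0 in [
        (lam_guess, lam_guess, 0.5),
        (lam_guess * 5, lam_guess / 5, 0.5),
        (lam_guess * 10, lam_guess, 0.3),
        (1e-9, 1e-9, 0.5),
    ]:
        sol = least_squares(
            resid, [c0_guess, a0, l1_0, l2_0],
            bounds=([0, 0, 0, 0], [np.inf, 1, 10, 10]),
            method="trf", max_nfev=2000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    _, a, l1, l2 = best.x
    if l1 < l2:  # order the decays fast-first
        l1, l2, a = l2, l1, 1.0 - a
    return BleachModel(amp=float(a), lam1=float(l1), lam2=float(l2))


@dataclass
class SurvivalCurve:
    """Bleach-corrected dwell-time survival evaluated on an interval grid."""

    times: np.ndarray      # s, multiples of the interval
    raw: np.ndarray        # S_raw(t): number of dwells >= t
    values: np.ndarray     # corrected and normalized so values[0] = B
    B: float               # bound fraction used for normalization
    interval: float        # s
    n_dwells: int

    def __post_init__(self):
        if np.any(np.diff(self.raw) > 0):
            raise ValueError("raw survival must be non-increasing")


_EPS = 1e-9


def _survival_grid(dwells: np.ndarray, interval: float) -> np.ndarray:
    k_min = int(round(np.min(dwells) / interval))
    k_max = int(round(np.max(dwells) / interval))
    return np.arange(max(k_min, 1), k_max + 1) * interval


def build_survival(
    dwells: Sequence[float],
    B: float,
    bleach: BleachModel,
    interval: float,
    min_bleach_survival: float = 1e-3,
) -> SurvivalCurve:
    """Survival histogram of dwell times, bleach-corrected and normalized.

    Evaluated at every multiple of the interval between the shortest and
    longest observed dwell: S_raw(t) = #dwells >= t, corrected by dividing
    with P_bleach(t/interval), then scaled so the first point equals B.
    The curve is truncated with a warning where the bleach survival drops
    below ``min_bleach_survival`` (the correction would amplify noise
    beyond use there).
    """
    dwells = np.asarray(list(dwells), dtype=float)
    if dwells.size == 0:
        raise ValueError("dwells must be non-empty")
    grid = _survival_grid(dwells, interval)
    raw = np.array([(dwells >= t - _EPS).sum() for t in grid], dtype=float)
    p_bleach = bleach.survival(grid / interval)
    if p_bleach[-1] < min_bleach_survival:
        keep = p_bleach >= min_bleach_survival
        warnings.warn(
            "bleach survival underflows at long dwells; survival curve "
            f"truncated from {len(grid)} to {int(keep.sum())} points",
            RuntimeWarning,
        )
        grid, raw, p_bleach = grid[keep], raw[keep], p_bleach[keep]
    corrected = raw / p_bleach
    values = corrected * (B / corrected[0])
    return SurvivalCurve(times=grid, raw=raw, values=values, B=B,
                         interval=interval, n_dwells=int(dwells.size))


def build_pooled_survival(
    groups: Sequence[Tuple[Sequence[float], BleachModel]],
    B: float,
    interval: float,
    min_bleach_survival: float = 1e-3,
) -> SurvivalCurve:
    """Pool dwells from several movies, each corrected with its own bleach model.

    Per-movie corrected survival counts are summed on a common grid, then
    normalized to B — photobleaching is a property of a movie, the dwell
    distribution of a condition.
    """
    alldw = np.concatenate([np.asarray(list(d), dtype=float) for d, _ in groups])
    if alldw.size == 0:
        raise ValueError("no dwells to pool")
    grid = _survival_grid(alldw, interval)
    total = np.zeros(len(grid))
    raw_total = np.zeros(len(grid))
    valid = np.ones(len(grid), dtype=bool)
    for dwells, bleach in groups:
        dwells = np.asarray(list(dwells), dtype=float)
        raw = np.array([(dwells >= t - _EPS).sum() for t in grid], dtype=float)
        p = bleach.survival(grid / interval)
        valid &= p >= min_bleach_survival
        total += raw / np.maximum(p, min_bleach_survival)
        raw_total += raw
    if not valid.all():
        warnings.warn("bleach survival underflow in at least one movie; "
                      "pooled curve truncated", RuntimeWarning)
        grid, total, raw_total = grid[valid], total[valid], raw_total[valid]
    values = total * (B / total[0])
    return SurvivalCurve(times=grid, raw=raw_total, values=values, B=B,
                         interval=interval, n_dwells=int(alldw.size))


def build_selection_curve(
    dwells: Sequence[float],
    B: float,
    bleach: BleachModel,
    interval: float,
    n_points: int = 13,
) -> SurvivalCurve:
    """Survival curve tabulated for *model comparison* rather than estimation.

    The F-test between nested mixture fits assumes independent residuals,
    which the usual cumulative tabulation violates badly: neighbouring
    survival values share almost all their dwells, and the resulting smooth
    correlated noise is exactly what an extra exponential component absorbs,
    making the test anti-conservative.  Here each of ~``n_points``
    log-spaced time points is evaluated from its own disjoint subsample of
    the dwells (systematic split after sorting, so subsamples are
    distributionally balanced).  Point values are then independent and the
    nested F-test runs near its nominal level.

    ``raw`` holds the full-sample counts on the grid (for reference);
    ``values`` are the split-sample corrected estimates normalized to B.
    """
    return _selection_curve(dwells, B, lambda f: bleach.survival(f),
                            interval, n_points)


def _selection_curve(dwells, B, bleach_survival, interval, n_points=13):
    dwells = np.asarray(list(dwells), dtype=float)
    if dwells.size == 0:
        raise ValueError("dwells must be non-empty")
    n_points = int(min(n_points, max(dwells.size // 8, 3)))
    g = np.geomspace(max(dwells.min(), interval), dwells.max(), n_points)
    kk = np.unique(np.maximum(np.round(g / interval).astype(int), 1))
    grid = kk * interval
    m = len(grid)
    dws = np.sort(dwells)
    groups = [dws[k::m] for k in range(m)]
    frac = np.array([
        (groups[i] >= grid[i] - _EPS).sum() / max(len(groups[i]), 1)
        for i in range(m)
    ])
    corrected = frac / np.asarray(bleach_survival(grid / interval), dtype=float)
    values = corrected * (B / max(corrected[0], 1e-12))
    raw = np.array([(dwells >= t - _EPS).sum() for t in grid], dtype=float)
    return SurvivalCurve(times=grid, raw=raw, values=values, B=B,
                         interval=interval, n_dwells=int(dwells.size))


def fit_and_select(
    dwells: Sequence[float],
    B: float,
    bleach: BleachModel,
    interval: float,
    alpha: float = 0.05,
    fit_order3: bool = True,
) -> Tuple[Dict[int, "ExpMixtureFit"], "ModelSelection"]:
    """Mixture fits on the dense survival curve, order chosen on the selection curve.

    Parameters are estimated from the full-sample curve of
    :func:`build_survival` (lowest-variance estimates); the F-test order
    comparison uses the independent-point curve of
    :func:`build_selection_curve`.  Returns the per-order estimation fits
    and the selection outcome.
    """
    est_curve = build_survival(dwells, B, bleach, interval)
    sel_curve = build_selection_curve(dwells, B, bleach, interval)
    fits = {1: fit_exp_mixture(est_curve, 1), 2: fit_exp_mixture(est_curve, 2)}
    s1 = fit_exp_mixture(sel_curve, 1)
    s2 = fit_exp_mixture(sel_curve, 2)
    s3 = None
    do3 = fit_order3 and len(sel_curve.times) > 6
    if do3:
        s3 = fit_exp_mixture(sel_curve, 3)
        if len(est_curve.times) > 6:
            fits[3] = fit_exp_mixture(est_curve, 3)
    selection = select_model(s1, s2, s3, alpha=alpha)
    return fits, selection


@dataclass
class ExpMixtureFit:
    """A fitted exponential-mixture survival model.

    ``rates`` are sorted descending (fastest first) with matching
    ``fractions`` summing to 1; residence times are their reciprocals, so
    the convention T_ns <= T_s (<= T_s2) holds automatically.
    """

    order: int
    B: float
    fractions: Tuple[float, ...]
    rates: Tuple[float, ...]      # 1/s, descending
    rss: float
    n_points: int

    @property
    def n_params(self) -> int:
        return {1: 2, 2: 4, 3: 6}[self.order]

    @property
    def residence_times(self) -> Tuple[float, ...]:
        """Residence times in seconds, ascending (T_ns first)."""
        return tuple(1.0 / k for k in self.rates)

    @property
    def F_ns(self) -> float:
        """Non-specific (fast) fraction; 0 for a single-component fit."""
        return self.fractions[0] if self.order >= 2 else 0.0

    @property
    def T_ns(self) -> Optional[float]:
        return 1.0 / self.rates[0] if self.order >= 2 else None

    @property
    def T_s(self) -> float:
        """Residence time of the slowest component."""
        return 1.0 / self.rates[-1]

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for frac, k in zip(self.fractions, self.rates):
            out += frac * np.exp(-k * t)
        return self.B * out


def _mixture_model(t, B, fracs, rates):
    out = np.zeros_like(t)
    for f, k in zip(fracs, rates):
        out += f * np.exp(-k * t)
    return B * out


def _unpack(order: int, p: np.ndarray):
    if order == 1:
        return p[0], (1.0,), (p[1],)
    if order == 2:
        return p[0], (p[1], 1.0 - p[1]), (p[2], p[3])
    B, f1, g, k1, k2, k3 = p
    f2 = (1.0 - f1) * g
    return B, (f1, f2, 1.0 - f1 - f2), (k1, k2, k3)


def fit_exp_mixture(
    curve: SurvivalCurve,
    order: int,
    extra_starts: int = 0,
) -> ExpMixtureFit:
    """Least-squares fit of an order-1/2/3 exponential mixture to S(t).

    Multi-start: rate initializations are log-spaced between 1/duration and
    1/interval of the curve, and each order is additionally seeded from the
    best fit of the order below (degenerate split), which guarantees the
    nesting property RSS_k <= RSS_{k-1}.  Amplitudes are bounded positive
    and fractions to [0, 1].
    """
    if order not in (1, 2, 3):
        raise ValueError(f"order must be 1, 2 or 3, got {order}")
    t = curve.times
    y = curve.values
    n_params = {1: 2, 2: 4, 3: 6}[order]
    if len(t) <= n_params:
        raise ValueError(
            f"curve has {len(t)} points; need more than {n_params} for order {order}"
        )
    k_lo = 0.01 / t[-1]
    k_hi = 100.0 / curve.interval
    k_grid = np.geomspace(1.0 / t[-1], 1.0 / curve.interval, 4 + extra_starts)
    B0 = max(y[0], 1e-12)

    def resid_factory(order):
        def resid(p):
            B, fr, ks = _unpack(order, p)
            return _mixture_model(t, B, fr, ks) - y
        return resid

    starts: List[np.ndarray] = []
    if order == 1:
        for k in k_grid:
            starts.append(np.array([B0, k]))
        lo = [0.0, k_lo]
        hi = [np.inf, k_hi]
    elif order == 2:
        sub = fit_exp_mixture(curve, 1, extra_starts)
        k1 = sub.rates[0]
        # F = 1 collapses exactly onto the order-1 optimum, guaranteeing
        # RSS_2 <= RSS_1; the perturbed start escapes the degenerate ridge
        starts.append(np.array([sub.B, 1.0, k1, max(k1 * 0.5, k_lo)]))
        starts.append(np.array([sub.B, 0.999, min(k1 * 1.5, k_hi), k1]))
        for i, ka in enumerate(k_grid):
            for kb in k_grid[:i]:
                for f in (0.3, 0.7):
                    starts.append(np.array([B0, f, ka, kb]))
        lo = [0.0, 0.0, k_lo, k_lo]
        hi = [np.inf, 1.0, k_hi, k_hi]
    else:
        sub = fit_exp_mixture(curve, 2, extra_starts)
        f1 = min(max(sub.fractions[0], 1e-3), 1 - 1e-3)
        ka, kb = sub.rates
        # g = 1 zeroes the third component: exactly the order-2 optimum
        starts.append(np.array([sub.B, f1, 1.0, ka, kb, max(kb * 0.5, k_lo)]))
        starts.append(np.array([sub.B, f1, 0.999, ka, kb, max(kb / 2, k_lo)]))
        starts.append(np.array([sub.B, f1, 0.5, ka, kb, max(kb / 3, k_lo)]))
        for i, k3 in enumerate(k_grid):
            starts.append(np.array([B0, 0.6, 0.5,
                                    k_grid[-1], np.sqrt(k3 * k_grid[-1]), k3]))
        lo = [0.0, 0.0, 0.0, k_lo, k_lo, k_lo]
        hi = [np.inf, 1.0, 1.0, k_hi, k_hi, k_hi]

    resid = resid_factory(order)
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                max_nfev=3000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            f"exponential-mixture fit of order {order} failed to converge "
            f"from {len(starts)} starts on {len(t)} points"
        )
    B, fracs, rates = _unpack(order, best.x)
    idx = np.argsort(rates)[::-1]
    fracs = tuple(float(np.asarray(fracs)[i]) for i in idx)
    rates = tuple(float(max(np.asarray(rates)[i], 1e-12)) for i in idx)
    rss = float(2.0 * best.cost)
    return ExpMixtureFit(order=order, B=float(B), fractions=fracs, rates=rates,
                         rss=rss, n_points=len(t))


@dataclass
class ModelSelection:
    """Outcome of the nested F-test comparison of mixture orders."""

    order: int
    f_12: float
    p_12: float
    f_23: float
    p_23: float
    alpha: float


def _f_test(small: ExpMixtureFit, big: ExpMixtureFit) -> Tuple[float, float]:
    d_rss = max(small.rss - big.rss, 0.0)
    dp = big.n_params - small.n_params
    dof = big.n_points - big.n_params
    if dof <= 0:
        raise ValueError("not enough points for the F-test")
    denom = big.rss / dof
    if denom <= 0:
        # the bigger model is an exact fit; any improvement is "significant"
        return (np.inf, 0.0) if d_rss > 0 else (0.0, 1.0)
    f = (d_rss / dp) / denom
    p = float(stats.f.sf(f, dp, dof))
    return float(f), p


def select_model(
    fit1: ExpMixtureFit,
    fit2: ExpMixtureFit,
    fit3: Optional[ExpMixtureFit] = None,
    alpha: float = 0.05,
) -> ModelSelection:
    """Choose the mixture order by nested F-tests at level ``alpha``.

    Order 2 is adopted only when it improves significantly on order 1 and
    order 3 does not improve significantly on order 2 — guarding against
    both under- and over-fitting.
    """
    f12, p12 = _f_test(fit1, fit2)
    if fit3 is not None:
        f23, p23 = _f_test(fit2, fit3)
    else:
        f23, p23 = 0.0, 1.0
    if p12 >= alpha:
        order = 1
    elif p23 < alpha:
        order = 3
    else:
        order = 2
    return ModelSelection(order=order, f_12=f12, p_12=p12,
                          f_23=f23, p_23=p23, alpha=alpha)


def _box_stats(values: np.ndarray) -> Dict[str, float]:
    if values.size == 0:
        return {"median": np.nan, "q1": np.nan, "q3": np.nan,
                "whisker_lo": np.nan, "whisker_hi": np.nan, "n_outliers": 0}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo) & (values <= hi)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_lo": float(inside.min()), "whisker_hi": float(inside.max()),
        "n_outliers": int(np.sum((values < lo) | (values > hi))),
    }


@dataclass
class PopulationSplit:
    """Individual dwell times divided into fast and slow populations.

    For a two-component fit the round((1-F_ns)*N) largest dwells form the
    slow population and the rest the fast one.  For a single-component fit
    there is one population, stored in ``slow`` with ``single=True`` (it is
    the population that enters cross-condition dwell comparisons).
    """

    fast: np.ndarray
    slow: np.ndarray
    single: bool
    fast_stats: Dict[str, float]
    slow_stats: Dict[str, float]


def split_populations(dwells: Sequence[float], fit: ExpMixtureFit) -> PopulationSplit:
    """Split dwell times by the fitted F_ns : (1 - F_ns) ratio."""
    if fit.order not in (1, 2):
        raise ValueError(f"population split needs an order-1 or order-2 fit, got {fit.order}")
    dwells = np.sort(np.asarray(list(dwells), dtype=float))[::-1]
    if fit.order == 1:
        fast = dwells[:0]
        slow = dwells
        single = True
    else:
        n_slow = int(round((1.0 - fit.F_ns) * len(dwells)))
        slow = dwells[:n_slow]
        fast = dwells[n_slow:]
        single = False
    return PopulationSplit(fast=fast, slow=slow, single=single,
                           fast_stats=_box_stats(fast), slow_stats=_box_stats(slow))
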