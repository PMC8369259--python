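"""Scale-dependent heart-rate features in sliding windows.

Four features are computed per window ``k`` and per integer sample lag
``tau``:

* ``m_k(tau)`` — mean increment over the lag (local trend, bpm),
* ``sigma_k(tau)`` — standard deviation over lag-length intervals (bpm),
* ``R_k(tau)`` — Student ratio ``m/sigma`` (dimensionless),
* ``h_k(tau)`` — entropy rate of order 1, ``H(x_t, x_{t-tau}) - H(x_t)``
  (nats), estimated with a nearest-neighbor differential-entropy estimator
  under temporal (Theiler) neighbor exclusion.

All statistics skip invalid samples: a missing point only reduces the
count entering an average, it is never replaced by a fabricated value.
Windows of length ``T`` are shifted by ``dT`` and the value of window ``k``
is stamped at its center ``t_k = k*dT + T/2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .io import AnalysisConfig, FhrSeries

__all__ = [
    "WindowFeatureGrid",
    "increment_mean_interval",
    "interval_std",
    "interval_student_ratio",
    "window_feature_average",
    "entropy_rate_window",
    "compute_feature_grid",
]

FEATURE_NAMES = ("m", "sigma", "R", "h")


@dataclass
class WindowFeatureGrid:
    """Per-lag feature values of one sliding window."""

    window_index: int
    window_center_time: float
    tau_grid: np.ndarray            # integer sample lags
    m: np.ndarray                   # bpm
    sigma: np.ndarray               # bpm
    R: np.ndarray                   # dimensionless
    h: np.ndarray                   # nats
    valid: dict = field(default_factory=dict)   # feature name -> bool array
    n_intervals: np.ndarray = None  # valid interval count per lag (m/sigma/R)

    def feature(self, name: str) -> np.ndarray:
        return getattr(self, "sigma" if name in ("sigma", "σ") else name)


# ---------------------------------------------------------------------------
# per-interval statistics (reference, scalar forms)
# ---------------------------------------------------------------------------

def _interval_slice(x, valid, t, tau):
    if t < tau:
        raise ValueError("t must be at least tau")
    xs = np.asarray(x, float)[t - tau + 1: t + 1]
    vs = np.asarray(valid, bool)[t - tau + 1: t + 1] & np.isfinite(xs)
    return xs, vs


def increment_mean_interval(x, t: int, tau: int, valid=None,
                            min_valid_fraction: float = 0.5) -> float:
    """Mean increment ``(1/c) sum_{i in (t-tau, t]} (x_i - x_{t-tau})``.

    Requires a valid anchor ``x_{t-tau}`` and at least
    ``max(2, ceil(min_valid_fraction*tau))`` valid samples in the interval;
    otherwise the interval is invalid and NaN is returned.
    """
    x = np.asarray(x, float)
    if valid is None:
        valid = np.isfinite(x)
    xs, vs = _interval_slice(x, valid, t, tau)
    anchor_ok = bool(valid[t - tau]) and np.isfinite(x[t - tau])
    c = int(vs.sum())
    if not anchor_ok or c < max(2, math.ceil(min_valid_fraction * tau)):
        return math.nan
    return float(xs[vs].mean() - x[t - tau])


def interval_std(x, t: int, tau: int, valid=None) -> float:
    """Population standard deviation of the samples in ``(t-tau, t]``."""
    x = np.asarray(x, float)
    if valid is None:
        valid = np.isfinite(x)
    xs, vs = _interval_slice(x, valid, t, tau)
    if vs.sum() < 2:
        return math.nan
    sel = xs[vs]
    return float(np.sqrt(max(np.mean(sel ** 2) - np.mean(sel) ** 2, 0.0)))


def interval_student_ratio(x, t: int, tau: int, valid=None,
                           min_valid_fraction: float = 0.5) -> float:
    """Student ratio ``m_t(tau) / sigma_t(tau)``; NaN when degenerate (sigma = 0)."""
    m = increment_mean_interval(x, t, tau, valid, min_valid_fraction)
    s = interval_std(x, t, tau, valid)
    if not np.isfinite(m) or not np.isfinite(s) or s == 0.0:
        return math.nan
    return m / s


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

def _interval_stats_window(xw: np.ndarray, vw: np.ndarray, tau: int,
                           min_valid_fraction: float):
    """Vectorized per-interval m, sigma, R over the ``floor(Nw/tau)`` intervals.

    Interval ``j`` (1-based) covers samples ``(j-1)*tau + 1 .. j*tau`` with
    anchor ``x[(j-1)*tau]``, all indices window-relative.  The sample at the
    window end (index Nw, reached when tau divides Nw) is treated as absent.
    Returns per-interval arrays (NaN = invalid interval).
    """
    nw = xw.size
    nint = nw // tau
    if nint == 0:
        z = np.empty(0)
        return z, z, z
    # pad one absent sample so interval edges never index out of the window
    xp = np.append(xw, np.nan)
    vp = np.append(vw, False)
    S = xp[1: nint * tau + 1].reshape(nint, tau)
    V = vp[1: nint * tau + 1].reshape(nint, tau) & np.isfinite(S)
    anchors = xp[0: nint * tau: tau]
    anchors_ok = vp[0: nint * tau: tau] & np.isfinite(anchors)
    c = V.sum(axis=1)
    Sz = np.where(V, S, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = Sz.sum(axis=1) / c
        meansq = (Sz ** 2).sum(axis=1) / c
        var = np.maximum(meansq - mean ** 2, 0.0)
    need = max(2, math.ceil(min_valid_fraction * tau))
    m = np.where(anchors_ok & (c >= need), mean - anchors, np.nan)
    sig = np.where(c >= 2, np.sqrt(var), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(np.isfinite(m) & np.isfinite(sig) & (sig > 0), m / sig, np.nan)
    return m, sig, r


def window_feature_average(x_window, tau: int, which: str, valid=None,
                           min_valid_fraction: float = 0.5):
    """Average a per-interval statistic over the window's non-overlapping intervals.

    ``which`` is one of ``m``, ``sigma`` and ``R``.  Returns
    ``(value, n_valid_intervals)``; the value is NaN when fewer than
    ``max(1, floor(min_valid_fraction * floor(Nw/tau)))`` intervals are valid.
    """
    xw = np.asarray(x_window, float)
    vw = np.isfinite(xw) if valid is None else (np.asarray(valid, bool) & np.isfinite(xw))
    if tau > xw.size:
        raise ValueError("tau exceeds the window length")
    m, sig, r = _interval_stats_window(xw, vw, tau, min_valid_fraction)
    stat = {"m": m, "sigma": sig, "σ": sig, "R": r}[which]
    ok = np.isfinite(stat)
    n_valid = int(ok.sum())
    nint = xw.size // tau
    need = max(1, math.floor(min_valid_fraction * nint))
    if n_valid < need:
        return math.nan, n_valid
    return float(stat[ok].mean()), n_valid


# ---------------------------------------------------------------------------
# entropy rate
# ---------------------------------------------------------------------------

def _kl_entropy(points: np.ndarray, times: np.ndarray, k: int, theiler: int):
    """Kozachenko–Leonenko differential entropy, max-norm, natural log.

    Candidate neighbors within ``theiler`` samples in time of the query point
    (including the point itself) are excluded.  Returns ``(H, frac_floor)``
    where ``frac_floor`` is the fraction of points whose k-th neighbor
    distance hit the duplicate-distance floor.
    """
    pts = np.atleast_2d(points)
    if pts.shape[0] < pts.shape[1]:
        pts = pts.T
    n, d = pts.shape
    tree = cKDTree(pts, balanced_tree=False)

    def _kth_allowed(rows, m):
        dist, idx = tree.query(pts[rows], k=m, p=np.inf)
        allowed = np.abs(times[idx] - times[rows, None]) > theiler
        rank = allowed.cumsum(axis=1)
        has_k = rank[:, -1] >= k
        first = np.argmax(rank >= k, axis=1)
        return np.where(has_k, dist[np.arange(len(rows)), first], np.nan), has_k

    # adaptive query: temporal exclusion rarely removes many spatial
    # neighbors, so k + 8 suffices for almost every point; the worst case
    # (all 2*theiler + 1 temporal neighbors also spatially close) is handled
    # by a second query for the few deficient points only.
    all_rows = np.arange(n)
    eps, got = _kth_allowed(all_rows, min(n, k + 8))
    if not got.all():
        rows = all_rows[~got]
        eps[rows], _ = _kth_allowed(rows, min(n, k + 2 * theiler + 2))
    floor_hits = eps <= 0.0
    eps = np.maximum(eps, 1e-300)
    # per-point candidate count after temporal exclusion
    order = np.argsort(times)
    st = times[order]
    lo = np.searchsorted(st, times - theiler, side="left")
    hi = np.searchsorted(st, times + theiler, side="right")
    candidates = n - (hi - lo)
    h = (-digamma(k) + float(np.mean(digamma(candidates + 1))) + d * math.log(2.0)
         + d * float(np.mean(np.log(eps))))
    return h, float(floor_hits.mean())


def entropy_rate_window(x_window, tau: int, neighbors: int = 5,
                        theiler: int | None = None, valid=None,
                        min_pairs: int = 500, return_info: bool = False):
    """Entropy rate of order 1, ``H(x_t, x_{t-tau}) - H(x_t)``, in nats.

    The window is first normalized to zero mean and unit variance over its
    valid samples; both entropies are then estimated on the valid pairs
    ``(x_t, x_{t-tau})`` with the nearest-neighbor estimator (``neighbors``
    neighbors, maximum norm, natural logarithm), excluding candidate
    neighbors closer than ``theiler`` samples in time (default: the lag
    itself).  NaN when fewer than ``min_pairs`` pairs are available, the
    window variance is zero, or the duplicate-distance floor fires for more
    than 1% of points.
    """
    if theiler is None:
        theiler = tau
    xw = np.asarray(x_window, float)
    vw = np.isfinite(xw) if valid is None else (np.asarray(valid, bool) & np.isfinite(xw))
    info = {"n_pairs": 0, "frac_floor": 0.0}
    out = math.nan
    sel = xw[vw]
    if sel.size >= 2:
        mu, sd = sel.mean(), sel.std()
        t_idx = np.arange(tau, xw.size)
        ok = vw[t_idx] & vw[t_idx - tau]
        t_sel = t_idx[ok]
        info["n_pairs"] = int(t_sel.size)
        if sd > 0 and t_sel.size >= max(min_pairs, neighbors + 2 * theiler + 2):
            z = (xw - mu) / sd
            pairs = np.column_stack((z[t_sel], z[t_sel - tau]))
            times = t_sel.astype(float)
            h2, f2 = _kl_entropy(pairs, times, neighbors, theiler)
            h1, f1 = _kl_entropy(z[t_sel][:, None], times, neighbors, theiler)
            info["frac_floor"] = max(f1, f2)
            if info["frac_floor"] <= 0.01:
                out = h2 - h1
    return (out, info) if return_info else out


# ---------------------------------------------------------------------------
# sliding-window driver
# ---------------------------------------------------------------------------

def compute_feature_grid(series: FhrSeries, config: AnalysisConfig | None = None) -> list[WindowFeatureGrid]:
    """All four features on every lag of ``config.tau_grid``, per sliding window.

    Returns one :class:`WindowFeatureGrid` per window ``k = 0, 1, ...`` with
    span ``[k*dT, k*dT + T)``; an empty list when the series is shorter than
    one window.  Deterministic for fixed input.
    """
    if config is None:
        config = AnalysisConfig()
    fs = series.sample_rate
    nw = int(round(config.window_length_T * fs))
    step = int(round(config.window_shift_dT * fs))
    n = len(series)
    if n < nw:
        return []
    taus = np.asarray(config.tau_grid, int)
    theiler = config.theiler_exclusion
    grids: list[WindowFeatureGrid] = []
    n_windows = (n - nw) // step + 1
    for k in range(n_windows):
        s = k * step
        xw = series.values[s: s + nw]
        vw = series.valid_mask[s: s + nw]
        m = np.full(taus.size, np.nan)
        sig = np.full(taus.size, np.nan)
        r = np.full(taus.size, np.nan)
        h = np.full(taus.size, np.nan)
        nint_valid = np.zeros(taus.size, int)
        vw_fin = vw & np.isfinite(xw)
        for j, tau in enumerate(taus):
            if tau > nw:
                continue
            mj, sj, rj = _interval_stats_window(xw, vw_fin, int(tau), config.min_valid_fraction)
            nint = nw // int(tau)
            need = max(1, math.floor(config.min_valid_fraction * nint))
            for arr, stat in ((m, mj), (sig, sj), (r, rj)):
                ok = np.isfinite(stat)
                if ok.sum() >= need:
                    arr[j] = stat[ok].mean()
            nint_valid[j] = int(np.isfinite(mj).sum())
            h[j] = entropy_rate_window(
                xw, int(tau), neighbors=config.entropy_neighbors,
                theiler=theiler if theiler is not None else int(tau),
                valid=vw, min_pairs=config.min_entropy_pairs)
        t_k = series.start_time + k * config.window_shift_dT + config.window_length_T / 2.0
        grids.append(WindowFeatureGrid(
            window_index=k, window_center_time=t_k, tau_grid=taus,
            m=m, sigma=sig, R=r, h=h,
            valid={name: np.isfinite(arr) for name, arr in
                   zip(FEATURE_NAMES, (m, sig, r, h))},
            n_intervals=nint_valid,
        ))
    return grids
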