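"""Dyad-level synchrony features: 4 metrics × 4 signals = 16 scalars.

All four metrics are computed on per-signal series resampled to a common
4 Hz grid over the segment and z-scored within the segment (heart-rate and
respiration-rate series come from detected events; EDA and temperature are
the filtered signals). Without normalization, signals with large absolute
scales (temperature) would dominate the distance-based metrics.

Metrics
-------
dtw
    Classic dynamic-programming time-warping alignment with
    absolute-difference local cost, symmetric match/insert/delete steps and
    no warping-window constraint; the optimal path's total cost divided by
    its length, so values are comparable across signals.
nli
    Symmetrized nonlinear interdependence: both series are delay-embedded;
    for each embedded point the mean squared distance to its k nearest
    neighbours within its own trajectory (R_self) is compared with the mean
    squared distance to the equal-time partners of the *other* trajectory's
    k nearest neighbours (R_cross), excluding temporally adjacent points
    within a Theiler window; the directed index averages R_self/R_cross
    over points, and the feature is the mean of the two directions.
coh
    Magnitude-squared coherence from Welch cross-spectra (60-s windows,
    50% overlap), averaged within signal-specific physiological bands and
    then across a signal's band list.
xcorr
    Zero-lag Pearson correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit
from scipy import signal as sps
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError

__all__ = [
    "SYNCHRONY_FEATURE_NAMES",
    "COHERENCE_BANDS",
    "dtw_distance",
    "nonlinear_interdependence",
    "band_coherence",
    "cross_correlation",
    "prepare_series",
    "extract_synchrony",
]

SYNC_GRID_FS = 4.0

#: physiological coherence bands (Hz) per signal
COHERENCE_BANDS: dict[str, tuple[tuple[float, float], ...]] = {
    "hr": ((0.04, 0.15), (0.15, 0.40)),
    "resp": ((0.05, 0.40),),
    "eda": ((0.01, 0.25),),
    "temp": ((0.003, 0.05),),
}

_METRICS = ("dtw", "nli", "coh", "xcorr")
_SIGNALS = ("hr", "resp", "eda", "temp")

SYNCHRONY_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{m}_{s}" for m in _METRICS for s in _SIGNALS
)


@njit(cache=True)
def _dtw_core(x: np.ndarray, y: np.ndarray) -> float:  # pragma: no cover
    n, m = len(x), len(y)
    big = 1e300
    cost = np.empty((n, m))
    steps = np.empty((n, m))
    cost[0, 0] = abs(x[0] - y[0])
    steps[0, 0] = 1.0
    for j in range(1, m):
        cost[0, j] = cost[0, j - 1] + abs(x[0] - y[j])
        steps[0, j] = steps[0, j - 1] + 1.0
    for i in range(1, n):
        cost[i, 0] = cost[i - 1, 0] + abs(x[i] - y[0])
        steps[i, 0] = steps[i - 1, 0] + 1.0
        for j in range(1, m):
            c = abs(x[i] - y[j])
            # diagonal preferred on ties (shortest path)
            best = cost[i - 1, j - 1]
            bs = steps[i - 1, j - 1]
            if cost[i - 1, j] < best:
                best = cost[i - 1, j]
                bs = steps[i - 1, j]
            if cost[i, j - 1] < best:
                best = cost[i, j - 1]
                bs = steps[i, j - 1]
            cost[i, j] = best + c
            steps[i, j] = bs + 1.0
    return cost[n - 1, m - 1] / steps[n - 1, m - 1]


def dtw_distance(x, y) -> float:
    """Path-length-normalized dynamic-time-warping distance.

    Unconstrained symmetric alignment with |x_i − y_j| local cost; the
    returned value is the minimal total path cost divided by the length of
    the minimizing path (diagonal steps preferred on exact ties).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise InvalidArgumentError("dtw_distance requires length >= 2")
    return float(_dtw_core(x, y))


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    return np.column_stack([x[i * tau : i * tau + n] for i in range(m)])


def _neighbor_indices(
    emb: np.ndarray, k: int, theiler: int
) -> tuple[np.ndarray, np.ndarray]:
    """k nearest neighbours of each embedded point, excluding self and
    points within the Theiler window; returns (indices, squared dists)."""
    n = len(emb)
    tree = cKDTree(emb)
    # querying k + 2*theiler + 2 neighbours guarantees at least k survive
    # the Theiler exclusion (at most 2*theiler + 1 indices are excluded)
    q = min(n, k + 2 * theiler + 2)
    dist, idx = tree.query(emb, k=q)
    rows = np.arange(n)[:, None]
    keep = np.abs(idx - rows) > theiler
    take = keep & (np.cumsum(keep, axis=1) <= k)
    if not np.all(take.sum(axis=1) == k):
        raise InvalidArgumentError(
            "series too short for the Theiler window and neighbour count"
        )
    out_idx = idx[take].reshape(n, k)
    out_d2 = dist[take].reshape(n, k) ** 2
    return out_idx, out_d2


def nonlinear_interdependence(
    x, y, m: int = 3, tau_samples: int = 4, k: int = 5, theiler: int = 8
) -> float:
    """Symmetrized nonlinear interdependence of two series.

    Values near 1 indicate geometrically similar state-space trajectories
    (identical series give exactly 1); weakly coupled systems give values
    toward 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    min_len = (m - 1) * tau_samples + k + 2 * theiler + 2
    if len(x) < min_len or len(y) < min_len or len(x) != len(y):
        raise InvalidArgumentError(
            f"series must have equal length >= {min_len} for these parameters"
        )
    ex, ey = _embed(x, m, tau_samples), _embed(y, m, tau_samples)

    idx_x, d2_x = _neighbor_indices(ex, k, theiler)
    idx_y, d2_y = _neighbor_indices(ey, k, theiler)

    def directed(emb_a, d2_self_a, idx_other):
        # R_self / R_cross per point, averaged
        r_self = d2_self_a.mean(axis=1)
        diff = emb_a[:, None, :] - emb_a[idx_other]
        r_cross = np.mean(np.sum(diff**2, axis=2), axis=1)
        r_cross = np.maximum(r_cross, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(r_cross > 0, r_self / r_cross, 1.0)
        # a point whose self and cross neighbourhoods coincide gives 1
        ratio = np.where((r_self == 0) & (r_cross <= 1e-299), 1.0, ratio)
        return float(ratio.mean())

    s_xy = directed(ex, d2_x, idx_y)  # x judged by y's neighbours
    s_yx = directed(ey, d2_y, idx_x)
    return 0.5 * (s_xy + s_yx)


def band_coherence(
    x, y, fs: float, bands: tuple[tuple[float, float], ...],
    window_s: float = 60.0,
) -> float:
    """Band-averaged magnitude-squared coherence in [0, 1].

    Welch cross-spectral estimation with ``window_s`` windows at 50%
    overlap; coherence is averaged over frequency bins within each band,
    then across bands.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nper = int(round(window_s * fs))
    if len(x) < nper + nper // 2:
        raise InvalidArgumentError("need at least 2 spectral windows")
    f, cxy = sps.coherence(x, y, fs=fs, nperseg=nper)
    vals = []
    for lo, hi in bands:
        m = (f >= lo) & (f <= hi)
        if m.any():
            vals.append(float(cxy[m].mean()))
    if not vals:
        raise InvalidArgumentError("no frequency bins fall in the given bands")
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def cross_correlation(x, y) -> float:
    """Zero-lag Pearson correlation; constant input yields 0 (warned)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidArgumentError("need equal-length series of length >= 3")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant input to cross_correlation; returning 0")
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def prepare_series(values: np.ndarray, t_values: np.ndarray,
                   t_start: float, t_end: float,
                   fs_out: float = SYNC_GRID_FS) -> np.ndarray:
    """Resample onto the common synchrony grid and z-score in-segment.

    Constant series come back as all zeros (the downstream correlation
    handles the degenerate case explicitly).
    """
    n = int(round((t_end - t_start) * fs_out))
    tg = t_start + np.arange(n) / fs_out
    z = np.interp(tg, t_values, values)
    sd = z.std()
    if sd == 0:
        return np.zeros(n)
    return (z - z.mean()) / sd


def extract_synchrony(
    pair_series: dict[str, tuple[np.ndarray, np.ndarray]],
    fs: float = SYNC_GRID_FS,
    nli_params: dict | None = None,
) -> dict[str, float]:
    """The 16 synchrony features for one dyad segment.

    ``pair_series`` maps each signal name (hr, resp, eda, temp) to that
    segment's two prepared (z-scored, common-grid) series.
    """
    nli_params = nli_params or {}
    out: dict[str, float] = {}
    for sig in _SIGNALS:
        a, b = pair_series[sig]
        # 60-s spectral windows, shrunk for segments too short to hold two
        window_s = min(60.0, len(a) / fs / 2.0)
        out[f"dtw_{sig}"] = dtw_distance(a, b)
        out[f"nli_{sig}"] = nonlinear_interdependence(a, b, **nli_params)
        out[f"coh_{sig}"] = band_coherence(a, b, fs, COHERENCE_BANDS[sig],
                                           window_s=window_s)
        out[f"xcorr_{sig}"] = cross_correlation(a, b)
    return {name: out[name] for name in SYNCHRONY_FEATURE_NAMES}
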