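"""Ensemble MSD, apparent diffusion constants, bootstrap and permutation inference.

The MSD is computed per track first (mean over all overlapping frame pairs at
each lag) and then averaged over tracks, so that the quoted uncertainty is the
s.e.m. over molecules — tracks, not displacements, are the independent units.
The apparent diffusion constant is slope/4 of an unweighted OLS line (free
intercept) through the first few MSD points; the intercept absorbs the 4σ²
localization-error offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .track_io import TrackSet

__all__ = [
    "MSDResult",
    "DiffusionEstimate",
    "PermutationResult",
    "GrowthSeries",
    "compute_msd",
    "estimate_diffusion",
    "bootstrap_diffusion",
    "permutation_test",
    "growth_rate_from_length",
]


@dataclass(frozen=True)
class MSDResult:
    """Ensemble MSD per lag with track-level s.e.m. and counts."""

    lags: np.ndarray  # seconds, strictly increasing
    msd: np.ndarray  # μm²
    sem: np.ndarray  # μm², SE over tracks
    n_tracks_per_lag: np.ndarray
    n_pairs_per_lag: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


@dataclass(frozen=True)
class DiffusionEstimate:
    """Apparent diffusion constant (slope/4) with optional bootstrap SD."""

    d_app: float  # μm² s⁻¹
    intercept: float  # μm², houses the 4σ² offset
    n_tracks: int
    boot_sd: float | None = None
    n_boot: int = 0

    def __post_init__(self) -> None:
        if self.n_boot and (self.boot_sd is None or self.boot_sd < 0):
            raise ValueError("boot_sd must be >= 0 when n_boot > 0")


@dataclass(frozen=True)
class PermutationResult:
    stat_observed: float  # difference in d_app (μm² s⁻¹)
    p_value: float
    n_perm: int
    null_stats: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


@dataclass(frozen=True)
class GrowthSeries:
    """Smoothed cell-length series and instantaneous relative growth rate.

    ``smoothed_times``/``smoothed_lengths`` are the centered moving average of
    the input; ``growth_rate = (1/L) dL/dt`` by central differences, defined on
    the interior points of the smoothed series (``growth_times``).
    """

    times: np.ndarray
    lengths: np.ndarray
    smoothed_times: np.ndarray
    smoothed_lengths: np.ndarray
    growth_times: np.ndarray
    growth_rate: np.ndarray


def _per_track_msd(ts: TrackSet, max_lag_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-track mean squared displacement matrix.

    Returns ``(M, P)`` of shape (n_tracks, max_lag_frames): M[i, k-1] is track
    i's mean r² over all overlapping pairs separated by exactly k frames (NaN
    if none), P the pair counts.
    """
    n = ts.n_tracks
    M = np.full((n, max_lag_frames), np.nan)
    P = np.zeros((n, max_lag_frames), dtype=np.int64)
    for i, t in enumerate(ts.tracks):
        frames = t.frames
        pos = t.positions
        contiguous = frames.size >= 2 and frames[-1] - frames[0] == frames.size - 1
        for k in range(1, max_lag_frames + 1):
            if contiguous:
                if frames.size <= k:
                    continue
                d = pos[k:] - pos[:-k]
            else:
                ii, jj = np.nonzero(frames[None, :] - frames[:, None] == k)
                if ii.size == 0:
                    continue
                d = pos[jj] - pos[ii]
            r2 = np.einsum("ij,ij->i", d, d)
            M[i, k - 1] = r2.mean()
            P[i, k - 1] = r2.size
    return M, P


def compute_msd(ts: TrackSet, max_lag_frames: int) -> MSDResult:
    """Ensemble MSD over the first ``max_lag_frames`` lags.

    For each lag k the MSD is the mean over tracks of the per-track mean
    squared displacement at separation k frames; tracks with no pair at a lag
    are excluded from that lag.  Lags no track reaches are dropped with a
    warning rather than reported as NaN.
    """
    if ts.n_tracks == 0:
        raise ValueError("empty TrackSet")
    if max_lag_frames < 1:
        raise ValueError("max_lag_frames must be >= 1")
    M, P = _per_track_msd(ts, max_lag_frames)
    have = ~np.isnan(M)
    n_tracks = have.sum(axis=0)
    populated = n_tracks > 0
    if not populated.all():
        dropped = [k + 1 for k in np.flatnonzero(~populated)]
        warnings.warn(f"dropping lags with no pairs: {dropped}", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        msd = np.nanmean(M, axis=0)
        sd = np.nanstd(M, axis=0, ddof=1)
    sem = np.where(n_tracks > 1, sd / np.sqrt(np.maximum(n_tracks, 1)), 0.0)
    lags = np.arange(1, max_lag_frames + 1) * ts.frame_interval
    return MSDResult(
        lags=lags[populated],
        msd=msd[populated],
        sem=sem[populated],
        n_tracks_per_lag=n_tracks[populated],
        n_pairs_per_lag=P.sum(axis=0)[populated],
    )


def _fit_slope_intercept(lags: np.ndarray, msd: np.ndarray, n_fit_points: int) -> tuple[float, float]:
    x = lags[:n_fit_points]
    y = msd[:n_fit_points]
    xc = x - x.mean()
    slope = (xc @ (y - y.mean())) / (xc @ xc)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def estimate_diffusion(msd: MSDResult, n_fit_points: int = 4) -> DiffusionEstimate:
    """Apparent diffusion constant from an OLS line through the first MSD points.

    ``d_app = slope / 4`` (2D); the free intercept is reported as fitted.
    """
    if n_fit_points < 2:
        raise ValueError("n_fit_points must be >= 2")
    if msd.lags.size < n_fit_points:
        raise ValueError(
            f"MSD has {msd.lags.size} lags, need {n_fit_points} for the fit"
        )
    slope, intercept = _fit_slope_intercept(msd.lags, msd.msd, n_fit_points)
    return DiffusionEstimate(
        d_app=slope / 4.0,
        intercept=intercept,
        n_tracks=int(msd.n_tracks_per_lag[0]),
    )


def _dapp_from_matrix(M: np.ndarray, lag_times: np.ndarray, n_fit_points: int) -> float:
    """d_app from a per-track MSD matrix (nanmean over rows, then OLS slope/4)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        msd = np.nanmean(M[:, :n_fit_points], axis=0)
    if np.any(np.isnan(msd)):
        raise ValueError("a fitted lag has no contributing track")
    slope, _ = _fit_slope_intercept(lag_times, msd, n_fit_points)
    return slope / 4.0


def bootstrap_diffusion(
    ts: TrackSet,
    n_boot: int = 1000,
    seed: int | None = None,
    n_fit_points: int = 4,
) -> DiffusionEstimate:
    """Bootstrap SD of d_app by resampling tracks with replacement.

    The point estimate comes from the unresampled data; ``boot_sd`` is the SD
    of the replicate estimates.  Seeded and reproducible.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if ts.n_tracks < 2:
        raise ValueError("need at least 2 tracks to bootstrap")
    M, _ = _per_track_msd(ts, n_fit_points)
    lag_times = np.arange(1, n_fit_points + 1) * ts.frame_interval
    point = _dapp_from_matrix(M, lag_times, n_fit_points)
    rng = np.random.default_rng(seed)
    n = ts.n_tracks
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps[b] = _dapp_from_matrix(M[idx], lag_times, n_fit_points)
    boot_sd = float(np.std(reps, ddof=1)) if n_boot > 1 else 0.0
    return DiffusionEstimate(
        d_app=point,
        intercept=estimate_diffusion(compute_msd(ts, n_fit_points), n_fit_points).intercept,
        n_tracks=n,
        boot_sd=boot_sd,
        n_boot=n_boot,
    )


def permutation_test(
    ts_a: TrackSet,
    ts_b: TrackSet,
    n_perm: int = 10000,
    seed: int | None = None,
    n_fit_points: int = 4,
    bootstrap_within: bool = False,
    keep_null: bool = False,
) -> PermutationResult:
    """Two-sided permutation test on the difference in apparent diffusion.

    The statistic is ``d_app(a) − d_app(b)``.  The null distribution is built
    by permuting track→condition labels (group sizes preserved); with
    ``bootstrap_within`` each permuted pseudo-group is additionally resampled
    with replacement before computing the statistic.  The p-value uses the
    add-one convention ``(1 + #{|null| ≥ |obs|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if ts_a.n_tracks == 0 or ts_b.n_tracks == 0:
        raise ValueError("both TrackSets must be non-empty")
    if not np.isclose(ts_a.frame_interval, ts_b.frame_interval):
        raise ValueError("TrackSets have differing frame intervals")

    Ma, _ = _per_track_msd(ts_a, n_fit_points)
    Mb, _ = _per_track_msd(ts_b, n_fit_points)
    lag_times = np.arange(1, n_fit_points + 1) * ts_a.frame_interval
    obs = _dapp_from_matrix(Ma, lag_times, n_fit_points) - _dapp_from_matrix(
        Mb, lag_times, n_fit_points
    )

    M = np.vstack([Ma, Mb])
    na, n = ts_a.n_tracks, ts_a.n_tracks + ts_b.n_tracks
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n)
        ga, gb = M[perm[:na]], M[perm[na:]]
        if bootstrap_within:
            ga = ga[rng.integers(0, ga.shape[0], size=ga.shape[0])]
            gb = gb[rng.integers(0, gb.shape[0], size=gb.shape[0])]
        null[p] = _dapp_from_matrix(ga, lag_times, n_fit_points) - _dapp_from_matrix(
            gb, lag_times, n_fit_points
        )
    p_value = (1.0 + np.count_nonzero(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
    return PermutationResult(
        stat_observed=obs,
        p_value=float(p_value),
        n_perm=n_perm,
        null_stats=null if keep_null else None,
    )


def growth_rate_from_length(
    times: Sequence[float],
    lengths: Sequence[float],
    window: int = 10,
) -> GrowthSeries:
    """Instantaneous relative growth rate (1/L)·dL/dt from a length time series.

    The length series is smoothed with a centered moving average of ``window``
    points; dL/dt is taken by central differences on the smoothed series, so
    the rate is defined on its interior points only.
    """
    t = np.asarray(times, dtype=float)
    L = np.asarray(lengths, dtype=float)
    if t.shape != L.shape or t.ndim != 1:
        raise ValueError("times and lengths must be 1-D and equally long")
    if np.any(L <= 0):
        raise ValueError("lengths must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    if t.size < window + 2:
        raise ValueError(f"need at least window+2 = {window + 2} samples")
    kernel = np.full(window, 1.0 / window)
    Ls = np.convolve(L, kernel, mode="valid")
    ts_ = np.convolve(t, kernel, mode="valid")
    dLdt = (Ls[2:] - Ls[:-2]) / (ts_[2:] - ts_[:-2])
    rate = dLdt / Ls[1:-1]
    return GrowthSeries(
        times=t,
        lengths=L,
        smoothed_times=ts_,
        smoothed_lengths=Ls,
        growth_times=ts_[1:-1],
        growth_rate=rate,
    )
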