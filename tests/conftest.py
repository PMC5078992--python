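"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: MSD and
step-size pooling are recomputed with explicit double loops, and model-CDF
samples are drawn by inverse-CDF sampling from the closed-form distributions.
"""

from __future__ import annotations

import numpy as np
import pytest

from sptdiff.track_io import Track, TrackSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(track_id, positions, frames=None, condition="c"):
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    return Track(track_id, condition, np.asarray(frames), positions)


def make_trackset(list_of_positions, frame_interval=0.03, condition="c"):
    tracks = [
        make_track(f"t{i}", pos, condition=condition)
        for i, pos in enumerate(list_of_positions)
    ]
    return TrackSet(tracks, frame_interval)


def random_trackset(rng, n_tracks=5, min_len=2, max_len=12, frame_interval=0.03):
    sets = []
    for i in range(n_tracks):
        n = int(rng.integers(min_len, max_len + 1))
        sets.append(rng.normal(scale=0.1, size=(n, 2)))
    return make_trackset(sets, frame_interval)


# ---------------------------------------------------------------- oracles


def brute_force_msd(ts: TrackSet, max_lag: int):
    """Double-loop per-track-mean-then-ensemble-mean MSD (independent oracle)."""
    per_track = {k: [] for k in range(1, max_lag + 1)}
    pairs = {k: 0 for k in range(1, max_lag + 1)}
    for t in ts.tracks:
        for k in range(1, max_lag + 1):
            vals = []
            for i in range(t.n_points):
                for j in range(t.n_points):
                    if t.frames[j] - t.frames[i] == k:
                        d = t.positions[j] - t.positions[i]
                        vals.append(float(d @ d))
            if vals:
                per_track[k].append(np.mean(vals))
                pairs[k] += len(vals)
    out = {}
    for k in range(1, max_lag + 1):
        if per_track[k]:
            arr = np.array(per_track[k])
            sem = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
            out[k] = (arr.mean(), sem, arr.size, pairs[k])
    return out


def brute_force_steps(ts: TrackSet, lags):
    """Double-loop pooled squared displacements per lag (independent oracle)."""
    pools = {k: [] for k in lags}
    for t in ts.tracks:
        for k in lags:
            for i in range(t.n_points):
                for j in range(t.n_points):
                    if t.frames[j] - t.frames[i] == k:
                        d = t.positions[j] - t.positions[i]
                        pools[k].append(float(d @ d))
    return {k: np.sort(v) for k, v in pools.items() if v}


def sample_squared_steps_one(rng, n, t, D, sigma):
    """Inverse-CDF draws of r² from the one-species model at lag t."""
    scale = 4.0 * D * t + 4.0 * sigma**2
    return -scale * np.log1p(-rng.random(n))


def sample_squared_steps_two(rng, n, t, D1, D2, alpha, sigma):
    """Inverse-CDF draws of r² from the two-species mixture at lag t."""
    fast = rng.random(n) < alpha
    s1 = 4.0 * D1 * t + 4.0 * sigma**2
    s2 = 4.0 * D2 * t + 4.0 * sigma**2
    scale = np.where(fast, s1, s2)
    return -scale * np.log1p(-rng.random(n))
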