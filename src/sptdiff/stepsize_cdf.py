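"""Multi-lag step-size CDF construction and one/two-species mixture fitting.

For a population of freely diffusing molecules observed with per-coordinate
localization error σ, the squared displacement r² over a lag t is
exponentially distributed with scale 4·D·t + 4·σ², giving the CDF

    one species:  P(r² ≤ x) = 1 − exp(−x / (4·D·t + 4·σ²))
    two species:  P(r² ≤ x) = 1 − [α·exp(−x/(4·D₁·t + 4σ²))
                                   + (1−α)·exp(−x/(4·D₂·t + 4σ²))]

with α the mobile (fast) fraction.  Empirical CDFs at several lags are fit
jointly — a single parameter vector across all lags — by bounded nonlinear
least squares on (empirical − model) residuals at every observed r², from a
deterministic multi-start grid.  Note the σ convention: σ is the
per-coordinate localization SD, and a displacement between two noisy
localizations contributes 4σ² to the squared-displacement scale.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .track_io import TrackSet

__all__ = [
    "StepSizeData",
    "CDFFit",
    "ModelComparison",
    "CDFFitError",
    "collect_step_sizes",
    "model_cdf_one",
    "model_cdf_two",
    "fit_cdf",
    "compare_models",
]

DEFAULT_LAGS = (1, 2, 3, 4)

# Deterministic multi-start grid (best final RSS wins, ties by lower BIC then
# lexicographic parameter order).
START_D_GRID = (1e-3, 1e-2, 1e-1, 1.0)  # μm²/s
START_ALPHA_GRID = (0.25, 0.5, 0.75)
START_SIGMA_GRID = (0.02, 0.04)  # μm


class CDFFitError(RuntimeError):
    """Raised when no multi-start attempt converges; carries diagnostics."""

    def __init__(self, message: str, diagnostics: list[dict] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class StepSizeData:
    """Pooled squared displacements per lag.

    ``lag_times`` are seconds (strictly increasing); ``r2[i]`` holds all
    squared displacements observed at ``lag_times[i]`` across tracks.
    """

    lag_times: np.ndarray
    r2: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        lt = np.asarray(self.lag_times, dtype=float)
        object.__setattr__(self, "lag_times", lt)
        object.__setattr__(self, "r2", tuple(np.asarray(a, dtype=float) for a in self.r2))
        if lt.size != len(self.r2):
            raise ValueError("lag_times and r2 must have the same length")
        if lt.size < 2:
            raise ValueError("need at least 2 populated lags")
        if np.any(np.diff(lt) <= 0):
            raise ValueError("lag_times must be strictly increasing")
        for a in self.r2:
            if a.size == 0:
                raise ValueError("every lag must be populated")
            if np.any(a < 0):
                raise ValueError("squared displacements must be >= 0")

    @property
    def n_per_lag(self) -> np.ndarray:
        return np.array([a.size for a in self.r2])

    @property
    def n_total(self) -> int:
        return int(self.n_per_lag.sum())


@dataclass(frozen=True)
class CDFFit:
    """Result of a joint multi-lag CDF fit."""

    model: Literal["one_species", "two_species"]
    params: Mapping[str, float]  # one: D, sigma; two: D1, D2, alpha, sigma
    rss: float
    n_points: int
    bic: float
    n_per_lag: tuple[int, ...]
    n_starts: int = 0
    n_converged: int = 0
    boot_sd: Mapping[str, float] | None = None

    @property
    def n_params(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class ModelComparison:
    chosen: Literal["one_species", "two_species"]
    delta_bic: float  # bic(two) − bic(one); negative favours two species
    rss_one: float
    rss_two: float
    f_stat: float
    f_p_value: float


def collect_step_sizes(
    ts: TrackSet, lags: Sequence[int] = DEFAULT_LAGS
) -> StepSizeData:
    """Pool squared displacements at the given frame lags across all tracks.

    For each lag k, every overlapping pair of localizations separated by
    exactly k frames contributes one r².  Lags with no observation are dropped
    with a warning; it is an error if fewer than two lags remain.
    """
    lags = sorted(set(int(k) for k in lags))
    if any(k < 1 for k in lags):
        raise ValueError("lags must be positive integers")
    if ts.n_tracks == 0:
        raise ValueError("empty TrackSet")
    pools: dict[int, list[np.ndarray]] = {k: [] for k in lags}
    for t in ts.tracks:
        frames, pos = t.frames, t.positions
        contiguous = frames[-1] - frames[0] == frames.size - 1
        for k in lags:
            if contiguous:
                if frames.size <= k:
                    continue
                d = pos[k:] - pos[:-k]
            else:
                ii, jj = np.nonzero(frames[None, :] - frames[:, None] == k)
                if ii.size == 0:
                    continue
                d = pos[jj] - pos[ii]
            pools[k].append(np.einsum("ij,ij->i", d, d))
    kept_lags, arrays = [], []
    for k in lags:
        if pools[k]:
            kept_lags.append(k)
            arrays.append(np.concatenate(pools[k]))
        else:
            warnings.warn(f"no steps observed at lag {k}; dropping it", stacklevel=2)
    if not kept_lags:
        raise ValueError("no track is long enough for the smallest requested lag")
    if len(kept_lags) < 2:
        raise ValueError("fewer than 2 lags populated; cannot build StepSizeData")
    lag_times = np.array(kept_lags, dtype=float) * ts.frame_interval
    return StepSizeData(lag_times, tuple(arrays))


def _scale(D: float, t, sigma: float):
    return 4.0 * D * np.asarray(t, dtype=float) + 4.0 * sigma**2


def model_cdf_one(r2, t, D: float, sigma: float):
    """One-species CDF of the squared displacement: 1 − exp(−r²/(4Dt + 4σ²)).

    Degenerate scale (D = σ = 0) yields the step function at r² = 0.
    """
    r2 = np.asarray(r2, dtype=float)
    s = _scale(D, t, sigma)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        out = np.where(s > 0, -np.expm1(-r2 / np.where(s > 0, s, 1.0)), (r2 >= 0).astype(float))
    return out if out.ndim else float(out)


def model_cdf_two(r2, t, D1: float, D2: float, alpha: float, sigma: float):
    """Two-species mixture CDF with mobile fraction alpha on the D1 component."""
    r2 = np.asarray(r2, dtype=float)
    s1, s2 = _scale(D1, t, sigma), _scale(D2, t, sigma)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        surv1 = np.where(s1 > 0, np.exp(-r2 / np.where(s1 > 0, s1, 1.0)), (r2 <= 0).astype(float))
        surv2 = np.where(s2 > 0, np.exp(-r2 / np.where(s2 > 0, s2, 1.0)), (r2 <= 0).astype(float))
    out = 1.0 - (alpha * surv1 + (1.0 - alpha) * surv2)
    return out if out.ndim else float(out)


def _ecdf_points(r2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted r² values and the empirical CDF evaluated at them (rank/n)."""
    x = np.sort(r2)
    return x, np.arange(1, x.size + 1) / x.size


def _quantile_grid(r2: np.ndarray, n_grid: int) -> tuple[np.ndarray, np.ndarray]:
    q = (np.arange(1, n_grid + 1) - 0.5) / n_grid
    return np.quantile(r2, q), q


def _prepare_targets(
    data: StepSizeData, eval_grid: int | None
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    targets = []
    for t, r2 in zip(data.lag_times, data.r2):
        x, f = _ecdf_points(r2) if eval_grid is None else _quantile_grid(r2, eval_grid)
        targets.append((float(t), x, f))
    return targets


def _log_density(x: np.ndarray, t: np.ndarray, params: Mapping[str, float]) -> np.ndarray:
    """Log density of r² under the fitted model (exponential scale mixture)."""
    floor = 1e-12  # avoids -inf for a degenerate (D = σ = 0) component
    if "D" in params:
        s = np.maximum(_scale(params["D"], t, params["sigma"]), floor)
        return -np.log(s) - x / s
    a = min(max(params["alpha"], 0.0), 1.0)
    s1 = np.maximum(_scale(params["D1"], t, params["sigma"]), floor)
    s2 = np.maximum(_scale(params["D2"], t, params["sigma"]), floor)
    lf1 = -np.log(s1) - x / s1
    lf2 = -np.log(s2) - x / s2
    if a == 1.0:
        return lf1
    if a == 0.0:
        return lf2
    return np.logaddexp(math.log(a) + lf1, math.log(1.0 - a) + lf2)


def _bic(x: np.ndarray, t: np.ndarray, params: Mapping[str, float], k: int) -> float:
    """BIC from the sample log-likelihood of the observed squared displacements.

    The least-squares objective is kept for parameter estimation (matching the
    joint CDF fit), but model comparison scores the data likelihood: BIC on the
    strongly correlated pointwise ECDF residuals would reward the richer model
    at any sample size.
    """
    n = x.size
    ll = float(np.sum(_log_density(x, t, params)))
    return k * math.log(n) - 2.0 * ll


def fit_cdf(
    data: StepSizeData,
    model: Literal["one_species", "two_species"],
    seed: int | None = None,
    eval_grid: int | None = None,
    fix_alpha: float | None = None,
) -> CDFFit:
    """Jointly fit one parameter vector to the empirical CDFs at all lags.

    Residuals are (empirical − model) at every observed r² (or on a fixed
    ``eval_grid`` of quantiles per lag).  All parameters are bounded (≥ 0,
    alpha ∈ [0, 1]); D1 ≥ D2 is enforced by post-fit relabeling.  Starting
    points come from a deterministic grid; the best final RSS wins.  ``seed``
    is accepted for interface symmetry (the start grid is deterministic).

    Raises
    ------
    CDFFitError
        If no start converges; diagnostics list per-start status.
    """
    del seed  # start grid is deterministic; kept for a stable interface
    if model not in ("one_species", "two_species"):
        raise ValueError("model must be 'one_species' or 'two_species'")
    targets = _prepare_targets(data, eval_grid)
    n_points = sum(x.size for _, x, _ in targets)
    ts_arr = np.concatenate([np.full(x.size, t) for t, x, _ in targets])
    x_arr = np.concatenate([x for _, x, _ in targets])
    f_arr = np.concatenate([f for _, _, f in targets])

    floor = 1e-300

    def _comp(D: float, sigma: float):
        """exp(−x/s) and x·exp(−x/s)/s² for one scale component."""
        s = np.maximum(_scale(D, ts_arr, sigma), floor)
        e = np.exp(-x_arr / s)
        return s, e, x_arr * e / (s * s)

    if model == "one_species":
        def residuals(p):
            return model_cdf_one(x_arr, ts_arr, p[0], p[1]) - f_arr

        def jac(p):
            _, _, w = _comp(p[0], p[1])
            return np.column_stack([-4.0 * ts_arr * w, -8.0 * p[1] * w])

        starts = [(d, s) for d in START_D_GRID for s in START_SIGMA_GRID]
        lower, upper = [0.0, 0.0], [np.inf, np.inf]
        k_params = 2
    else:
        if fix_alpha is not None:
            if not (0.0 <= fix_alpha <= 1.0):
                raise ValueError("fix_alpha must lie in [0, 1]")

            def residuals(p):
                return model_cdf_two(x_arr, ts_arr, p[0], p[1], fix_alpha, p[2]) - f_arr

            def jac(p):
                a = fix_alpha
                _, _, w1 = _comp(p[0], p[2])
                _, _, w2 = _comp(p[1], p[2])
                return np.column_stack([
                    -4.0 * ts_arr * a * w1,
                    -4.0 * ts_arr * (1.0 - a) * w2,
                    -8.0 * p[2] * (a * w1 + (1.0 - a) * w2),
                ])

            starts = [
                (d1, d2, s)
                for d1, d2 in itertools.combinations(sorted(START_D_GRID, reverse=True), 2)
                for s in START_SIGMA_GRID
            ]
            lower, upper = [0.0] * 3, [np.inf] * 3
            k_params = 3
        else:
            def residuals(p):
                return model_cdf_two(x_arr, ts_arr, p[0], p[1], p[2], p[3]) - f_arr

            def jac(p):
                a = p[2]
                _, e1, w1 = _comp(p[0], p[3])
                _, e2, w2 = _comp(p[1], p[3])
                return np.column_stack([
                    -4.0 * ts_arr * a * w1,
                    -4.0 * ts_arr * (1.0 - a) * w2,
                    e2 - e1,
                    -8.0 * p[3] * (a * w1 + (1.0 - a) * w2),
                ])

            starts = [
                (d1, d2, a, s)
                for d1, d2 in itertools.combinations(sorted(START_D_GRID, reverse=True), 2)
                for a in START_ALPHA_GRID
                for s in START_SIGMA_GRID
            ]
            lower, upper = [0.0, 0.0, 0.0, 0.0], [np.inf, np.inf, 1.0, np.inf]
            k_params = 4

    best: tuple[float, np.ndarray] | None = None
    diagnostics: list[dict] = []
    n_converged = 0
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals, np.array(x0, dtype=float), jac=jac,
                bounds=(lower, upper), method="trf",
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append({"start": x0, "status": "exception", "message": str(exc)})
            continue
        diagnostics.append({"start": x0, "status": int(sol.status), "cost": float(sol.cost)})
        if sol.status <= 0:
            continue
        n_converged += 1
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol.x.copy())
    if best is None:
        raise CDFFitError(
            f"{model} CDF fit failed to converge from any of {len(starts)} starts",
            diagnostics,
        )
    rss, p = best
    if model == "one_species":
        params = {"D": float(p[0]), "sigma": float(p[1])}
    elif fix_alpha is not None:
        d1, d2 = float(p[0]), float(p[1])
        alpha = float(fix_alpha)
        if d1 < d2:
            d1, d2, alpha = d2, d1, 1.0 - alpha
        params = {"D1": d1, "D2": d2, "alpha": alpha, "sigma": float(p[2])}
    else:
        d1, d2, alpha = float(p[0]), float(p[1]), float(p[2])
        if d1 < d2:  # relabel so D1 is the fast species
            d1, d2, alpha = d2, d1, 1.0 - alpha
        params = {"D1": d1, "D2": d2, "alpha": alpha, "sigma": float(p[3])}
    x_raw = np.concatenate(data.r2)
    t_raw = np.concatenate(
        [np.full(a.size, t) for t, a in zip(data.lag_times, data.r2)]
    )
    return CDFFit(
        model=model,
        params=params,
        rss=rss,
        n_points=n_points,
        bic=_bic(x_raw, t_raw, params, k_params),
        n_per_lag=tuple(int(x.size) for _, x, _ in targets),
        n_starts=len(starts),
        n_converged=n_converged,
    )


def compare_models(fit_one: CDFFit, fit_two: CDFFit) -> ModelComparison:
    """Choose between the one- and two-species fits by BIC (lower wins).

    A nested F-test p-value is reported as a secondary diagnostic.  Both fits
    must be on identical data (same residual count).
    """
    if {fit_one.model, fit_two.model} != {"one_species", "two_species"}:
        raise ValueError("need one one_species and one two_species fit")
    if fit_one.model == "two_species":
        fit_one, fit_two = fit_two, fit_one
    if fit_one.n_points != fit_two.n_points:
        raise ValueError("fits are not on identical data (n_points mismatch)")
    n = fit_one.n_points
    k1, k2 = fit_one.n_params, fit_two.n_params
    delta_bic = fit_two.bic - fit_one.bic
    if fit_two.rss > 0 and n > k2 and k2 > k1:
        f_stat = ((fit_one.rss - fit_two.rss) / (k2 - k1)) / (fit_two.rss / (n - k2))
        f_stat = max(f_stat, 0.0)
        f_p = float(stats.f.sf(f_stat, k2 - k1, n - k2))
    else:  # pragma: no cover - degenerate
        f_stat, f_p = math.inf, 0.0
    chosen = "two_species" if delta_bic < 0 else "one_species"
    return ModelComparison(
        chosen=chosen,
        delta_bic=float(delta_bic),
        rss_one=fit_one.rss,
        rss_two=fit_two.rss,
        f_stat=float(f_stat),
        f_p_value=f_p,
    )


def cdf_table(data: StepSizeData, fit: CDFFit) -> "np.ndarray":
    """Per-lag (lag_time, r2, empirical, model) rows for plotting/export."""
    rows = []
    for t, r2 in zip(data.lag_times, data.r2):
        x, f = _ecdf_points(r2)
        if fit.model == "one_species":
            m = model_cdf_one(x, t, fit.params["D"], fit.params["sigma"])
        else:
            m = model_cdf_two(
                x, t, fit.params["D1"], fit.params["D2"], fit.params["alpha"], fit.params["sigma"]
            )
        rows.append(np.column_stack([np.full(x.size, t), x, f, m]))
    return np.vstack(rows)
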