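"""Synthetic single-molecule tracks on a cylindrical membrane seen through TIRF.

Molecules perform Brownian motion on the lateral surface of a cylinder
(axial coordinate plus arc length around the circumference), switch between a
fast and a slow diffusive state, and are observable only while their height
above the coverslip is within the evanescent-field depth.  Observed positions
are the in-plane projection (axial, chord) with i.i.d. Gaussian localization
noise per coordinate.  Tracks are the first maximal run of consecutive visible
frames, truncated by geometric photobleaching, then length-filtered.

Two generators are exposed:

* :func:`simulate_tracks` — the full cylinder + TIRF + switching model.
* :func:`simulate_planar_tracks` — free planar diffusion with a static
  two-state mixture; the reference generator whose statistics match the
  closed forms (MSD = 4·D·t + 4·σ², exponential step-size CDF) exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .track_io import Track, TrackSet

__all__ = [
    "CellGeometry",
    "DiffusionModel",
    "SimulationConfig",
    "SurfaceState",
    "SimulationResult",
    "EmptySimulationError",
    "step_surface",
    "project_and_observe",
    "simulate_tracks",
    "simulate_planar_tracks",
    "load_simulation_config",
]


class EmptySimulationError(RuntimeError):
    """Raised when a simulation retains zero tracks after filtering."""


@dataclass(frozen=True)
class CellGeometry:
    """Cylindrical cell resting on the coverslip.

    ``tirf_depth`` is the height above the coverslip within which molecules
    are detectable (evanescent-field window, ~0.1–0.15 μm).
    """

    radius: float = 0.5
    length: float = 3.0
    tirf_depth: float = 0.125

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if not (0 < self.tirf_depth <= 2 * self.radius):
            raise ValueError("tirf_depth must lie in (0, 2*radius]")

    @property
    def visibility_half_angle(self) -> float:
        """Largest |angle| from the contact line that is still visible.

        Solves ``radius * (1 - cos(theta)) = tirf_depth``; π when the whole
        circumference is visible.
        """
        c = 1.0 - self.tirf_depth / self.radius
        return math.pi if c <= -1.0 else math.acos(c)


@dataclass(frozen=True)
class DiffusionModel:
    """Generative parameters of the two-state diffusion model.

    ``alpha`` is the stationary fraction of molecules in the fast state.  When
    both switching rates are positive, consistency with the rates
    (``alpha = k_sf / (k_sf + k_fs)``) is enforced at construction; pass
    ``alpha=None`` to derive it from the rates.
    """

    d_fast: float = 0.05
    d_slow: float = 0.0
    alpha: float | None = 0.5
    sigma_loc: float = 0.03
    rate_fast_to_slow: float = 5.0
    rate_slow_to_fast: float = 5.0
    frame_interval: float = 0.03

    def __post_init__(self) -> None:
        if self.d_slow < 0 or self.d_fast < self.d_slow:
            raise ValueError("require d_fast >= d_slow >= 0")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.rate_fast_to_slow < 0 or self.rate_slow_to_fast < 0:
            raise ValueError("switching rates must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        kf, ks = self.rate_fast_to_slow, self.rate_slow_to_fast
        if self.alpha is None:
            if kf + ks == 0:
                raise ValueError("alpha=None requires at least one positive rate")
            object.__setattr__(self, "alpha", ks / (kf + ks))
        else:
            if not (0.0 <= self.alpha <= 1.0):
                raise ValueError("alpha must lie in [0, 1]")
            if kf > 0 and ks > 0:
                stationary = ks / (kf + ks)
                if not math.isclose(self.alpha, stationary, rel_tol=1e-9, abs_tol=1e-9):
                    raise ValueError(
                        f"alpha={self.alpha} inconsistent with stationary fraction "
                        f"{stationary:.6f} implied by the switching rates"
                    )

    def diffusion_of(self, fast: bool) -> float:
        return self.d_fast if fast else self.d_slow


@dataclass(frozen=True)
class SurfaceState:
    """Instantaneous state of one molecule on the cylinder surface.

    ``angle`` is measured from the coverslip contact line and wraps modulo 2π;
    ``axial`` is confined to ``[-length/2, +length/2]`` by reflection.
    """

    axial: float
    angle: float
    motion_state: Literal["fast", "slow"]


@dataclass(frozen=True)
class SimulationConfig:
    geometry: CellGeometry = field(default_factory=CellGeometry)
    model: DiffusionModel = field(default_factory=DiffusionModel)
    n_molecules: int = 1000
    n_frames_max: int = 60
    substeps_per_frame: int = 10
    track_min_points: int = 4
    track_max_points: int = 12
    bleach_survival_per_frame: float = 0.85
    mixture_mode: Literal["kinetic", "static"] = "kinetic"
    seed: int = 0
    condition: str = "sim"

    def __post_init__(self) -> None:
        if not (2 <= self.track_min_points <= self.track_max_points):
            raise ValueError("require 2 <= track_min_points <= track_max_points")
        if self.substeps_per_frame < 1:
            raise ValueError("substeps_per_frame must be >= 1")
        if not (0 < self.bleach_survival_per_frame <= 1):
            raise ValueError("bleach_survival_per_frame must lie in (0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.n_frames_max < self.track_min_points:
            raise ValueError("n_frames_max must be >= track_min_points")
        if self.mixture_mode not in ("kinetic", "static"):
            raise ValueError("mixture_mode must be 'kinetic' or 'static'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationResult:
    """Simulated tracks plus per-frame ground truth.

    ``truth`` has one row per retained localization with columns
    ``track_id, frame, motion_state, axial_um, arc_um, z_um`` where ``arc_um``
    is the unwrapped arc length (radius × cumulative angle), suitable for
    computing the true surface MSD without projection loss.
    """

    tracks: TrackSet
    truth: pd.DataFrame


def _switch_probabilities(model: DiffusionModel, dt: float) -> tuple[float, float]:
    """Exact transition probabilities of the two-state jump chain over dt.

    Returns ``(p_fast_to_slow, p_slow_to_fast)``.
    """
    kf, ks = model.rate_fast_to_slow, model.rate_slow_to_fast
    lam = kf + ks
    if lam == 0:
        return 0.0, 0.0
    decay = 1.0 - math.exp(-lam * dt)
    return (kf / lam) * decay, (ks / lam) * decay


def _reflect(x: np.ndarray | float, half: float) -> np.ndarray | float:
    """Reflect coordinates into [-half, half] (triangle-wave folding)."""
    period = 4.0 * half
    y = np.mod(np.asarray(x) + half, period)
    y = np.where(y > 2.0 * half, period - y, y)
    return y - half


def step_surface(
    state: SurfaceState,
    model: DiffusionModel,
    dt: float,
    rng: np.random.Generator,
    geometry: CellGeometry | None = None,
    kinetic: bool = True,
) -> SurfaceState:
    """Advance one molecule on the cylinder surface by ``dt``.

    Axial and arc-length displacements are independent N(0, 2·D·dt) draws with
    D set by the motion state at the start of the step; the motion state is
    then updated by the exact two-state jump probability over ``dt`` (when
    ``kinetic``).  The axial coordinate reflects at the caps, the angle wraps.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    geometry = geometry or CellGeometry()
    fast = state.motion_state == "fast"
    d = model.diffusion_of(fast)
    sd = math.sqrt(2.0 * d * dt)
    dx, ds = rng.normal(0.0, 1.0, size=2) * sd
    half = geometry.length / 2.0
    axial = state.axial + dx
    if not (-half <= axial <= half):
        axial = float(_reflect(axial, half))
    angle = (state.angle + ds / geometry.radius) % (2.0 * math.pi)
    if kinetic:
        p_fs, p_sf = _switch_probabilities(model, dt)
        u = rng.random()
        if fast and u < p_fs:
            fast = False
        elif not fast and u < p_sf:
            fast = True
    return SurfaceState(axial, angle, "fast" if fast else "slow")


def project_and_observe(
    state: SurfaceState, geometry: CellGeometry
) -> tuple[bool, tuple[float, float]]:
    """Project a surface state to the image plane and test TIRF visibility.

    image x = axial; image y = radius·sin(angle); the height above the
    coverslip is z = radius·(1 − cos(angle)); visible iff z ≤ tirf_depth.
    """
    z = geometry.radius * (1.0 - math.cos(state.angle))
    xy = (state.axial, geometry.radius * math.sin(state.angle))
    return z <= geometry.tirf_depth, xy


def _extract_first_visible_run(visible_row: np.ndarray) -> tuple[int, int]:
    """(start, length) of the first run of consecutive True frames; length 0 if none."""
    idx = np.flatnonzero(visible_row)
    if idx.size == 0:
        return 0, 0
    start = int(idx[0])
    after = visible_row[start:]
    off = np.flatnonzero(~after)
    length = int(off[0]) if off.size else int(after.size)
    return start, length


def simulate_tracks(config: SimulationConfig) -> SimulationResult:
    """Run the full cylinder/TIRF/switching Monte Carlo.

    Each molecule starts at a uniformly random *visible* surface position with
    its motion state drawn Bernoulli(alpha); per frame it takes
    ``substeps_per_frame`` surface steps and is then observed.  The first
    maximal visible run, shortened by geometric bleaching survival, becomes a
    track; tracks shorter than ``track_min_points`` are dropped, longer than
    ``track_max_points`` truncated.  Localization noise is added to the
    projected coordinates only.  Identical config (incl. seed) gives identical
    output.

    Raises
    ------
    EmptySimulationError
        If no track survives the length filter.
    """
    geo, model = config.geometry, config.model
    n = config.n_molecules
    rng = np.random.default_rng(config.seed)

    theta_vis = geo.visibility_half_angle
    angle = rng.uniform(-theta_vis, theta_vis, size=n)  # visible band around contact line
    axial = rng.uniform(-geo.length / 2.0, geo.length / 2.0, size=n)
    fast = rng.random(n) < model.alpha

    n_frames = config.n_frames_max
    dt_sub = model.frame_interval / config.substeps_per_frame
    kinetic = config.mixture_mode == "kinetic"
    p_fs, p_sf = _switch_probabilities(model, dt_sub) if kinetic else (0.0, 0.0)

    axial_rec = np.empty((n_frames, n))
    angle_rec = np.empty((n_frames, n))  # unwrapped
    fast_rec = np.empty((n_frames, n), dtype=bool)

    axial_rec[0], angle_rec[0], fast_rec[0] = axial, angle, fast
    half_len = geo.length / 2.0
    for f in range(1, n_frames):
        for _ in range(config.substeps_per_frame):
            sd = np.sqrt(2.0 * np.where(fast, model.d_fast, model.d_slow) * dt_sub)
            axial = _reflect(axial + rng.normal(size=n) * sd, half_len)
            angle = angle + rng.normal(size=n) * sd / geo.radius
            if kinetic and (p_fs > 0 or p_sf > 0):
                u = rng.random(n)
                fast = np.where(fast, u >= p_fs, u < p_sf)
        axial_rec[f], angle_rec[f], fast_rec[f] = axial, angle, fast

    wrapped = np.mod(angle_rec + math.pi, 2.0 * math.pi) - math.pi
    z = geo.radius * (1.0 - np.cos(wrapped))
    visible = z <= geo.tirf_depth
    x_img = axial_rec
    y_img = geo.radius * np.sin(wrapped)

    if config.bleach_survival_per_frame < 1.0:
        bleach_len = rng.geometric(1.0 - config.bleach_survival_per_frame, size=n)
    else:
        bleach_len = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)

    noise = rng.normal(0.0, 1.0, size=(n_frames, n, 2)) * model.sigma_loc

    tracks: list[Track] = []
    truth_parts: list[pd.DataFrame] = []
    width = len(str(n))
    for m in range(n):
        start, run = _extract_first_visible_run(visible[:, m])
        eff = min(run, int(bleach_len[m]))
        if eff < config.track_min_points:
            continue
        eff = min(eff, config.track_max_points)
        sl = slice(start, start + eff)
        frames = np.arange(start, start + eff, dtype=np.int64)
        pos = np.column_stack([x_img[sl, m], y_img[sl, m]]) + noise[sl, m, :]
        tid = f"sim-{m:0{width}d}"
        tracks.append(Track(tid, config.condition, frames, pos))
        truth_parts.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": frames,
                    "motion_state": np.where(fast_rec[sl, m], "fast", "slow"),
                    "axial_um": axial_rec[sl, m],
                    "arc_um": geo.radius * angle_rec[sl, m],
                    "z_um": z[sl, m],
                }
            )
        )

    if not tracks:
        raise EmptySimulationError(
            f"simulation retained 0 of {n} molecules after the "
            f"[{config.track_min_points}, {config.track_max_points}]-point filter"
        )

    metadata = {
        "generator": "simulate_tracks",
        "config": config.to_dict(),
        "n_molecules": n,
        "n_tracks": len(tracks),
    }
    ts = TrackSet(tracks, model.frame_interval, metadata)
    truth = pd.concat(truth_parts, ignore_index=True)
    return SimulationResult(ts, truth)


def simulate_planar_tracks(
    model: DiffusionModel,
    n_tracks: int,
    seed: int,
    track_min_points: int = 4,
    track_max_points: int = 12,
    condition: str = "sim",
) -> SimulationResult:
    """Free planar Brownian tracks with a static fast/slow mixture.

    Track lengths are uniform integers in ``[track_min_points,
    track_max_points]``; each molecule keeps the state drawn at birth
    (Bernoulli(alpha) fast), so the observed steps follow the two-species
    jump-size model exactly, with per-coordinate localization noise adding
    4σ² to the squared-displacement scale.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if not (2 <= track_min_points <= track_max_points):
        raise ValueError("require 2 <= track_min_points <= track_max_points")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(track_min_points, track_max_points + 1, size=n_tracks)
    fast = rng.random(n_tracks) < model.alpha
    dt = model.frame_interval
    tracks: list[Track] = []
    states: list[str] = []
    width = len(str(n_tracks))
    for m in range(n_tracks):
        L = int(lengths[m])
        d = model.d_fast if fast[m] else model.d_slow
        steps = rng.normal(0.0, math.sqrt(2.0 * d * dt), size=(L - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        pos = pos + rng.normal(0.0, model.sigma_loc, size=(L, 2))
        tracks.append(Track(f"pl-{m:0{width}d}", condition, np.arange(L), pos))
        states.append("fast" if fast[m] else "slow")
    metadata = {
        "generator": "simulate_planar_tracks",
        "seed": seed,
        "n_tracks": n_tracks,
        "d_fast": model.d_fast,
        "d_slow": model.d_slow,
        "alpha": model.alpha,
        "sigma_loc": model.sigma_loc,
    }
    ts = TrackSet(tracks, dt, metadata)
    truth = pd.DataFrame({"track_id": [t.track_id for t in tracks], "motion_state": states})
    return SimulationResult(ts, truth)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Build a SimulationConfig from a JSON or YAML file.

    Nested sections ``geometry`` and ``model`` map onto :class:`CellGeometry`
    and :class:`DiffusionModel`; all other keys are top-level config fields.
    ``seed`` is mandatory.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "seed" not in raw:
        raise ValueError(f"{path}: 'seed' is mandatory in simulation configs")
    geometry = CellGeometry(**raw.pop("geometry", {}))
    model = DiffusionModel(**raw.pop("model", {}))
    return SimulationConfig(geometry=geometry, model=model, **raw)
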