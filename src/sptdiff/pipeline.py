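"""End-to-end runs: simulate/load → filter → MSD + bootstrap → CDF fits → compare.

Every run writes its artifacts (tracks, MSD table, fit JSONs, report) into an
output directory together with the echoed configuration and its hash, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import diffusion_stats, stepsize_cdf, track_io
from .simcell import SimulationConfig, simulate_tracks

log = logging.getLogger("sptdiff")

__all__ = ["RunConfig", "run_single_condition", "run_comparison", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run (one condition)."""

    seed: int
    input_tracks: str | None = None  # CSV path; mutually exclusive with simulation
    simulation: SimulationConfig | None = None
    frame_interval: float = 0.03
    min_points: int = 4
    max_points: int = 12
    msd_max_lag: int = 10
    n_fit_points: int = 4
    n_boot: int = 1000
    n_perm: int = 10000
    cdf_lags: tuple[int, ...] = (1, 2, 3, 4)
    condition: str | None = None

    def __post_init__(self) -> None:
        if (self.input_tracks is None) == (self.simulation is None):
            raise ValueError("exactly one of input_tracks or simulation must be set")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from JSON or YAML; ``seed`` is mandatory."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if "seed" not in raw:
        raise ValueError(f"{path}: 'seed' is mandatory")
    sim = raw.pop("simulation", None)
    if sim is not None:
        from .simcell import CellGeometry, DiffusionModel

        geometry = CellGeometry(**sim.pop("geometry", {}))
        model = DiffusionModel(**sim.pop("model", {}))
        sim = SimulationConfig(geometry=geometry, model=model, **sim)
    if "cdf_lags" in raw:
        raw["cdf_lags"] = tuple(raw["cdf_lags"])
    return RunConfig(simulation=sim, **raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _json_dump(obj: Any, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(o: Any):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _obtain_tracks(cfg: RunConfig, outdir: Path | None) -> track_io.TrackSet:
    if cfg.simulation is not None:
        result = simulate_tracks(cfg.simulation)
        log.info("simulated %d tracks from %d molecules",
                 result.tracks.n_tracks, cfg.simulation.n_molecules)
        if outdir is not None:
            track_io.write_tracks(result.tracks, outdir / "tracks.csv")
            result.truth.to_csv(outdir / "truth.csv", index=False, float_format="%.6f")
        return result.tracks
    ts = track_io.read_tracks(cfg.input_tracks, cfg.frame_interval)
    log.info("read %d tracks from %s", ts.n_tracks, cfg.input_tracks)
    return ts


def run_single_condition(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full per-condition analysis and return (and write) the report.

    Emits: MSD table, diffusion estimate with bootstrap SD, one- and
    two-species CDF fits and the model choice.  All randomness derives from
    ``cfg.seed``; rerunning with the same config writes identical files.
    """
    outdir_p: Path | None = None
    if outdir is not None:
        outdir_p = Path(outdir)
        outdir_p.mkdir(parents=True, exist_ok=True)

    ts = _obtain_tracks(cfg, outdir_p)
    filtered = track_io.filter_by_length(ts, cfg.min_points, cfg.max_points)
    log.info("length filter [%d, %d]: %d -> %d tracks",
             cfg.min_points, cfg.max_points, ts.n_tracks, filtered.n_tracks)
    if filtered.n_tracks == 0:
        raise track_io.TrackValidationError(
            f"no tracks left after the [{cfg.min_points}, {cfg.max_points}]-point filter"
        )

    msd = diffusion_stats.compute_msd(filtered, cfg.msd_max_lag)
    est = diffusion_stats.bootstrap_diffusion(
        filtered, n_boot=cfg.n_boot, seed=cfg.seed, n_fit_points=cfg.n_fit_points
    )
    log.info("d_app = %.5g ± %.2g μm²/s (n=%d tracks, %d bootstrap)",
             est.d_app, est.boot_sd or 0.0, est.n_tracks, est.n_boot)

    steps = stepsize_cdf.collect_step_sizes(filtered, cfg.cdf_lags)
    fit1 = stepsize_cdf.fit_cdf(steps, "one_species", seed=cfg.seed)
    fit2 = stepsize_cdf.fit_cdf(steps, "two_species", seed=cfg.seed)
    choice = stepsize_cdf.compare_models(fit1, fit2)
    log.info("model choice: %s (Δbic=%.1f)", choice.chosen, choice.delta_bic)

    report = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "condition": cfg.condition or (filtered.conditions[0] if filtered.conditions else None),
        "n_tracks_input": ts.n_tracks,
        "n_tracks_filtered": filtered.n_tracks,
        "msd": {
            "lags_s": msd.lags,
            "msd_um2": msd.msd,
            "sem_um2": msd.sem,
            "n_tracks_per_lag": msd.n_tracks_per_lag,
            "n_pairs_per_lag": msd.n_pairs_per_lag,
        },
        "diffusion": {
            "d_app_um2_s": est.d_app,
            "intercept_um2": est.intercept,
            "boot_sd_um2_s": est.boot_sd,
            "n_boot": est.n_boot,
            "n_tracks": est.n_tracks,
        },
        "cdf_fit_one": {"params": dict(fit1.params), "rss": fit1.rss, "bic": fit1.bic,
                        "n_points": fit1.n_points, "n_per_lag": fit1.n_per_lag},
        "cdf_fit_two": {"params": dict(fit2.params), "rss": fit2.rss, "bic": fit2.bic,
                        "n_points": fit2.n_points, "n_per_lag": fit2.n_per_lag},
        "model_choice": {
            "chosen": choice.chosen,
            "delta_bic": choice.delta_bic,
            "f_stat": choice.f_stat,
            "f_p_value": choice.f_p_value,
        },
    }
    if outdir_p is not None:
        pd.DataFrame(
            {
                "lag_s": msd.lags,
                "msd_um2": msd.msd,
                "sem_um2": msd.sem,
                "n_tracks": msd.n_tracks_per_lag,
                "n_pairs": msd.n_pairs_per_lag,
            }
        ).to_csv(outdir_p / "msd.csv", index=False, float_format="%.8g")
        _json_dump(report, outdir_p / "report.json")
    return report


def run_comparison(
    cfg_a: RunConfig, cfg_b: RunConfig, outdir: str | Path | None = None
) -> dict:
    """Condition-vs-condition comparison: per-condition reports, permutation
    p-value on Δd_app, and Δα between the two-species CDF fits."""
    outdir_p = Path(outdir) if outdir is not None else None
    rep_a = run_single_condition(cfg_a, outdir_p / "a" if outdir_p else None)
    rep_b = run_single_condition(cfg_b, outdir_p / "b" if outdir_p else None)

    ts_a = track_io.filter_by_length(
        _obtain_tracks(cfg_a, None), cfg_a.min_points, cfg_a.max_points
    )
    ts_b = track_io.filter_by_length(
        _obtain_tracks(cfg_b, None), cfg_b.min_points, cfg_b.max_points
    )
    perm = diffusion_stats.permutation_test(
        ts_a, ts_b, n_perm=min(cfg_a.n_perm, cfg_b.n_perm),
        seed=cfg_a.seed, n_fit_points=cfg_a.n_fit_points,
    )
    delta_alpha = (
        rep_a["cdf_fit_two"]["params"]["alpha"] - rep_b["cdf_fit_two"]["params"]["alpha"]
    )
    report = {
        "condition_a": rep_a,
        "condition_b": rep_b,
        "permutation": {
            "stat_observed_um2_s": perm.stat_observed,
            "p_value": perm.p_value,
            "n_perm": perm.n_perm,
        },
        "delta_alpha": delta_alpha,
    }
    if outdir_p is not None:
        outdir_p.mkdir(parents=True, exist_ok=True)
        _json_dump(report, outdir_p / "comparison.json")
    return report
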