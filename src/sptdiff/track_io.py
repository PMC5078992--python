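"""Reading, writing, validating and filtering single-molecule track tables.

The on-disk format is a plain CSV with header ``track_id,condition,frame,x_um,y_um``,
one row per localization, coordinates in micrometres written with six decimals,
0-based integer frame indices.  The frame interval (seconds) and free-form
provenance metadata live in a sidecar JSON file ``<name>.meta.json`` rather
than being repeated per row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CSV_COLUMNS = ["track_id", "condition", "frame", "x_um", "y_um"]
COORD_DECIMALS = 6


class TrackValidationError(ValueError):
    """Raised when a track table violates the schema or track invariants."""


@dataclass(frozen=True)
class Track:
    """One molecule's time-ordered 2D localizations.

    Attributes
    ----------
    track_id : str
        Unique identifier within a :class:`TrackSet`.
    condition : str
        Experimental condition label (e.g. ``"untreated"``).
    frames : numpy.ndarray of int
        Strictly increasing 0-based frame indices.
    positions : numpy.ndarray, shape (n, 2)
        In-plane coordinates in micrometres.
    """

    track_id: str
    condition: str
    frames: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        positions = np.asarray(self.positions, dtype=np.float64)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "positions", positions)
        if frames.ndim != 1:
            raise TrackValidationError(f"track {self.track_id!r}: frames must be 1-D")
        if positions.shape != (frames.size, 2):
            raise TrackValidationError(
                f"track {self.track_id!r}: positions shape {positions.shape} "
                f"does not match {frames.size} frames"
            )
        if frames.size < 2:
            raise TrackValidationError(
                f"track {self.track_id!r}: needs at least 2 points, got {frames.size}"
            )
        if np.any(np.diff(frames) <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: frame indices not strictly increasing"
            )
        if not np.all(np.isfinite(positions)):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite positions"
            )

    @property
    def n_points(self) -> int:
        return int(self.frames.size)

    def times(self, frame_interval: float) -> np.ndarray:
        """Observation times in seconds (``frames * frame_interval``)."""
        return self.frames * float(frame_interval)


@dataclass
class TrackSet:
    """A collection of tracks sharing one frame interval.

    ``metadata`` is free-form provenance (source config, seed, filter history).
    """

    tracks: list[Track]
    frame_interval: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise TrackValidationError("frame_interval must be > 0")
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise TrackValidationError(f"duplicate track_id {dup!r}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterable[Track]:
        return iter(self.tracks)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    @property
    def conditions(self) -> list[str]:
        return sorted({t.condition for t in self.tracks})

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with one row per localization."""
        if not self.tracks:
            return pd.DataFrame(columns=CSV_COLUMNS)
        parts = []
        for t in self.tracks:
            parts.append(
                pd.DataFrame(
                    {
                        "track_id": t.track_id,
                        "condition": t.condition,
                        "frame": t.frames,
                        "x_um": t.positions[:, 0],
                        "y_um": t.positions[:, 1],
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def read_tracks(path: str | Path, frame_interval: float) -> TrackSet:
    """Read and validate a track CSV.

    Malformed rows are rejected with a :class:`TrackValidationError` naming the
    offending track; nothing is silently coerced.  If a sidecar
    ``<name>.meta.json`` exists its contents populate ``TrackSet.metadata``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"track_id": str, "condition": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrackValidationError(f"{path}: missing columns {missing}")

    for col in ("frame", "x_um", "y_um"):
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "track_id"].iloc[0]
            raise TrackValidationError(f"{path}: missing {col} value in track {bad!r}")
    frame_float = pd.to_numeric(df["frame"], errors="coerce")
    if frame_float.isna().any() or not np.allclose(frame_float, np.round(frame_float)):
        bad = df.loc[frame_float.isna() | (frame_float != np.round(frame_float)), "track_id"].iloc[0]
        raise TrackValidationError(f"{path}: non-integer frame index in track {bad!r}")

    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=True):
        conds = grp["condition"].unique()
        if len(conds) > 1:
            raise TrackValidationError(
                f"{path}: track {tid!r} has multiple condition labels {sorted(conds)}"
            )
        frames = grp["frame"].to_numpy(dtype=np.int64)
        if np.unique(frames).size != frames.size:
            raise TrackValidationError(
                f"{path}: duplicate (track_id, frame) pair in track {tid!r}"
            )
        order = np.argsort(frames, kind="stable")
        if np.any(np.diff(frames) <= 0):
            # Rows out of order are a format violation, not something to sort away.
            raise TrackValidationError(
                f"{path}: frames not strictly increasing in track {tid!r}"
            )
        del order
        positions = grp[["x_um", "y_um"]].to_numpy(dtype=np.float64)
        tracks.append(Track(str(tid), str(conds[0]), frames, positions))

    metadata: dict = {}
    mp = _meta_path(path)
    if mp.exists():
        with open(mp) as fh:
            metadata = json.load(fh)
        fi = metadata.get("frame_interval")
        if fi is not None and not np.isclose(fi, frame_interval):
            raise TrackValidationError(
                f"{path}: frame_interval {frame_interval} disagrees with sidecar value {fi}"
            )
    return TrackSet(tracks, float(frame_interval), metadata)


def write_tracks(ts: TrackSet, path: str | Path) -> Path:
    """Write a track CSV (rows sorted by track_id then frame) plus metadata sidecar.

    Coordinates are written with :data:`COORD_DECIMALS` decimals; the sidecar
    JSON carries ``frame_interval`` and the TrackSet metadata.
    """
    path = Path(path)
    df = ts.to_frame()
    if len(df):
        df = df.sort_values(["track_id", "frame"], kind="stable")
        df["x_um"] = df["x_um"].map(lambda v: f"{v:.{COORD_DECIMALS}f}")
        df["y_um"] = df["y_um"].map(lambda v: f"{v:.{COORD_DECIMALS}f}")
    df.to_csv(path, index=False, columns=CSV_COLUMNS)
    meta = {"frame_interval": ts.frame_interval, **ts.metadata}
    with open(_meta_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def filter_by_length(ts: TrackSet, min_points: int, max_points: int | float) -> TrackSet:
    """Keep exactly the tracks whose point count lies in ``[min_points, max_points]``.

    The applied filter is appended to ``metadata["filter_history"]``.  Track
    order is preserved; the operation is idempotent.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    if min_points > max_points:
        raise ValueError(f"min_points ({min_points}) > max_points ({max_points})")
    kept = [t for t in ts.tracks if min_points <= t.n_points <= max_points]
    metadata = dict(ts.metadata)
    history = list(metadata.get("filter_history", []))
    history.append(
        {
            "filter": "length",
            "min_points": int(min_points),
            "max_points": (None if np.isinf(max_points) else int(max_points)),
            "n_in": ts.n_tracks,
            "n_out": len(kept),
        }
    )
    metadata["filter_history"] = history
    return TrackSet(kept, ts.frame_interval, metadata)


def concat_tracksets(sets: Iterable[TrackSet], relabel: Mapping[str, str] | None = None) -> TrackSet:
    """Pool several TrackSets (same frame interval) into one, keeping ids unique."""
    sets = list(sets)
    if not sets:
        raise ValueError("no TrackSets given")
    fi = sets[0].frame_interval
    if any(not np.isclose(s.frame_interval, fi) for s in sets):
        raise TrackValidationError("TrackSets have differing frame intervals")
    tracks: list[Track] = []
    for i, s in enumerate(sets):
        for t in s.tracks:
            tid = f"{i}:{t.track_id}" if len(sets) > 1 else t.track_id
            cond = relabel.get(t.condition, t.condition) if relabel else t.condition
            tracks.append(Track(tid, cond, t.frames, t.positions))
    return TrackSet(tracks, fi, {"pooled_from": len(sets)})
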