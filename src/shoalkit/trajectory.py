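"""Trajectory container, file I/O, gap handling and kinematics.

A :class:`TrajectorySet` holds the positions of N fish over T frames in mm,
as exported by multi-animal trackers such as TRex (one x/y sample per fish
per frame, with dropouts where the tracker lost an animal). Missing samples
are stored as NaN and always handled explicitly downstream.

File format: a long-form CSV with header ``frame,fish_id,x_mm,y_mm`` (empty
x/y fields encode missing samples) plus a JSON sidecar carrying the frame
rate, arena geometry, source id, and optionally a pixel-to-mm scale applied
at ingest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TrajectoryParseError, UndefinedStatisticError
from .geometry import ArenaGeometry, arena_from_dict

Window = tuple[int, int]  # half-open frame interval [start, end)


@dataclass
class TrajectorySet:
    """Positions of N fish over T frames.

    Attributes
    ----------
    fish_ids:
        Ordered fish identifiers (strings).
    positions:
        Array of shape (N, T, 2) in mm; NaN marks missing samples
        (a missing sample has both coordinates NaN).
    frame_rate_hz:
        Acquisition rate; 30 for the shoaling assay, 20 or 30 for the
        preference assay, but any positive value is accepted.
    arena:
        Arena geometry the positions live in.
    source_id:
        Recording/movie identifier.
    """

    fish_ids: list[str]
    positions: np.ndarray
    frame_rate_hz: float
    arena: ArenaGeometry
    source_id: str = "unknown"
    extra_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ConfigurationError(
                f"positions must have shape (N, T, 2), got {self.positions.shape}"
            )
        n, t, _ = self.positions.shape
        if len(self.fish_ids) != n:
            raise ConfigurationError(
                f"{len(self.fish_ids)} fish_ids for {n} position tracks"
            )
        if n < 1:
            raise ConfigurationError("empty TrajectorySet (no fish)")
        if t < 1:
            raise ConfigurationError("TrajectorySet needs at least one frame")
        if len(set(self.fish_ids)) != n:
            raise ConfigurationError("duplicate fish_ids")
        if not self.frame_rate_hz > 0:
            raise ConfigurationError("frame_rate_hz must be > 0")
        # half-missing samples (x XOR y) are not representable states
        xy_nan = np.isnan(self.positions)
        if np.any(xy_nan[..., 0] != xy_nan[..., 1]):
            raise ConfigurationError("a missing sample must have both x and y missing")
        ok = ~xy_nan[..., 0]
        if ok.any():
            x = self.positions[..., 0][ok]
            y = self.positions[..., 1][ok]
            inside = self.arena.contains(x, y, tol=1e-6)
            if not np.all(inside):
                bad = int(np.count_nonzero(~inside))
                raise ConfigurationError(
                    f"{bad} non-missing positions fall outside the arena bounding region"
                )

    @property
    def n_fish(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def missing(self) -> np.ndarray:
        """(N, T) boolean mask, True where the sample is missing."""
        return np.isnan(self.positions[..., 0])

    def fish_index(self, fish: str) -> int:
        try:
            return self.fish_ids.index(fish)
        except ValueError:
            raise KeyError(f"unknown fish id {fish!r}")

    def check_window(self, window: Window) -> Window:
        start, end = int(window[0]), int(window[1])
        if not (0 <= start < end <= self.n_frames):
            raise ConfigurationError(
                f"window [{start}, {end}) invalid for T={self.n_frames}"
            )
        return start, end

    def time_to_frame(self, t_s: float) -> int:
        return int(round(t_s * self.frame_rate_hz))

    def copy(self) -> "TrajectorySet":
        return replace(self, positions=self.positions.copy(),
                       fish_ids=list(self.fish_ids),
                       extra_metadata=dict(self.extra_metadata))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trajectories(ts: TrajectorySet, path: str | Path) -> Path:
    """Write the CSV dialect plus JSON sidecar; lossless for finite
    positions and the gap mask. Returns the CSV path."""
    path = Path(path)
    n, t = ts.n_fish, ts.n_frames
    frames = np.tile(np.arange(t), n)
    ids = np.repeat(np.asarray(ts.fish_ids, dtype=object), t)
    df = pd.DataFrame(
        {
            "frame": frames,
            "fish_id": ids,
            "x_mm": ts.positions[..., 0].ravel(),
            "y_mm": ts.positions[..., 1].ravel(),
        }
    )
    try:
        df.to_csv(path, index=False, na_rep="", float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write trajectory file {path}: {exc}") from exc
    meta = {
        "frame_rate_hz": ts.frame_rate_hz,
        "arena": ts.arena.to_dict(),
        "source_id": ts.source_id,
        **({"extra": ts.extra_metadata} if ts.extra_metadata else {}),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_trajectories(path: str | Path, geometry: ArenaGeometry | None = None) -> TrajectorySet:
    """Read a trajectory CSV + JSON sidecar into a :class:`TrajectorySet`.

    ``geometry`` overrides the sidecar's arena if given. Missing samples
    (empty x/y fields) are preserved as gaps; fish order follows first
    appearance in the file.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise ConfigurationError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    if "frame_rate_hz" not in meta:
        raise ConfigurationError(f"sidecar {side} lacks frame_rate_hz")
    if geometry is None:
        if "arena" not in meta:
            raise ConfigurationError(f"sidecar {side} lacks arena geometry")
        geometry = arena_from_dict(meta["arena"])

    try:
        df = pd.read_csv(path, dtype={"fish_id": str}, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise TrajectoryParseError(f"cannot parse {path}: {exc}") from exc
    required = ["frame", "fish_id", "x_mm", "y_mm"]
    if list(df.columns) != required:
        raise TrajectoryParseError(
            f"{path}: expected header {','.join(required)}, got {','.join(df.columns)}"
        )
    if df["frame"].isna().any() or df["fish_id"].isna().any():
        line = int(df.index[df["frame"].isna() | df["fish_id"].isna()][0]) + 2
        raise TrajectoryParseError(f"{path}: malformed row at line {line}")

    scale = meta.get("px_per_mm")
    if scale is not None:
        df["x_mm"] = df["x_mm"] / float(scale)
        df["y_mm"] = df["y_mm"] / float(scale)

    fish_ids = list(dict.fromkeys(df["fish_id"]))
    counts = df.groupby("fish_id", sort=False)["frame"].count()
    if counts.nunique() != 1:
        detail = ", ".join(f"{k}: {v}" for k, v in counts.items())
        raise TrajectoryParseError(f"{path}: inconsistent frame counts ({detail})")
    t = int(counts.iloc[0])

    positions = np.full((len(fish_ids), t, 2), np.nan)
    for i, fid in enumerate(fish_ids):
        sub = df[df["fish_id"] == fid]
        frames = sub["frame"].to_numpy(dtype=int)
        if not np.array_equal(np.sort(frames), np.arange(t)):
            raise TrajectoryParseError(
                f"{path}: fish {fid!r} frames are not exactly 0..{t - 1}"
            )
        positions[i, frames, 0] = sub["x_mm"].to_numpy(dtype=float)
        positions[i, frames, 1] = sub["y_mm"].to_numpy(dtype=float)

    return TrajectorySet(
        fish_ids=fish_ids,
        positions=positions,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        arena=geometry,
        source_id=str(meta.get("source_id", path.stem)),
        extra_metadata=meta.get("extra", {}),
    )


def _gap_runs(missing_1d: np.ndarray):
    """Yield (start, length) of runs of True in a 1-D boolean array."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], missing_1d, [False])).astype(int)))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e - s)


def fill_gaps(ts: TrajectorySet, max_gap_frames: int = 5) -> TrajectorySet:
    """Linearly interpolate interior tracking gaps of length <= max_gap_frames.

    Longer gaps and leading/trailing gaps are left missing. Originally
    present samples are never modified; a new set is returned.
    """
    if max_gap_frames < 0:
        raise ConfigurationError("max_gap_frames must be >= 0")
    out = ts.copy()
    if max_gap_frames == 0:
        return out
    t = ts.n_frames
    for i in range(ts.n_fish):
        miss = ts.missing[i]
        if not miss.any():
            continue
        for start, length in _gap_runs(miss):
            end = start + length  # first present frame after the gap
            if start == 0 or end == t or length > max_gap_frames:
                continue
            before = ts.positions[i, start - 1]
            after = ts.positions[i, end]
            frac = (np.arange(1, length + 1) / (length + 1))[:, None]
            out.positions[i, start:end] = before + frac * (after - before)
    return out


def step_lengths(ts: TrajectorySet, fish: str, window: Window | None = None) -> np.ndarray:
    """Euclidean lengths of consecutive-frame steps for one fish.

    Only pairs of adjacent frames where both samples are present contribute;
    pairs spanning a gap are omitted entirely.
    """
    i = ts.fish_index(fish)
    start, end = ts.check_window(window if window is not None else (0, ts.n_frames))
    pos = ts.positions[i, start:end]
    ok = ~np.isnan(pos[:, 0])
    both = ok[:-1] & ok[1:]
    d = np.diff(pos, axis=0)
    return np.hypot(d[both, 0], d[both, 1])


def mean_swim_speed(ts: TrajectorySet, fish: str, window: Window | None = None) -> float:
    """Mean swim speed (mm/s) of one fish over a half-open frame window.

    The mean of consecutive non-missing step lengths times the frame rate;
    steps spanning tracking gaps are excluded from both numerator and
    denominator. No smoothing is applied.
    """
    steps = step_lengths(ts, fish, window)
    if steps.size == 0:
        raise UndefinedStatisticError(
            f"fish {fish!r}: fewer than 2 non-missing frames in window, speed undefined"
        )
    return float(steps.mean() * ts.frame_rate_hz)
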