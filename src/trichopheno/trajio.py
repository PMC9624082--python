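"""Trajectory, design-table and arena-configuration I/O plus artefact cleaning.

Trajectories are C-trax-style CSV tables with a ``frame,x,y,theta`` header,
one row per video frame (25 fps, 90 s trials).  All internal geometry is in
cm with the origin at the centre of the white disc; pixel-to-cm conversion
happens once, at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from trichopheno.errors import DegenerateInputError, DesignError, FormatError, GeometryError

TRAJECTORY_COLUMNS = ("frame", "x", "y", "theta")


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry of the disc-on-rectangle arena and acquisition parameters.

    The arena is a 24 x 18 cm glass plate over an LCD screen showing a white
    disc (diameter 5.5 cm) on a dark background, with virtual border bands of
    0.5 cm on either side of the printed disc edge.  Coordinates are expressed
    relative to the disc centre.
    """

    circle_center: tuple[float, float] = (0.0, 0.0)
    circle_radius: float = 2.75
    band_halfwidth: float = 0.5
    arena_bounds: tuple[float, float] = (24.0, 18.0)  # full width, height (cm), centred
    pixel_to_cm: float = 1.0
    fps: float = 25.0

    def __post_init__(self) -> None:
        if not (self.circle_radius > self.band_halfwidth > 0):
            raise GeometryError("require circle_radius > band_halfwidth > 0")
        w, h = self.arena_bounds
        if self.circle_radius + self.band_halfwidth > min(w, h) / 2:
            raise GeometryError("disc plus outer band must fit inside the arena")
        if self.fps <= 0 or self.pixel_to_cm <= 0:
            raise GeometryError("fps and pixel_to_cm must be positive")

    @property
    def half_bounds(self) -> tuple[float, float]:
        return self.arena_bounds[0] / 2.0, self.arena_bounds[1] / 2.0

    @classmethod
    def from_yaml(cls, path) -> "ArenaConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "circle_center" in raw:
            raw["circle_center"] = tuple(raw["circle_center"])
        if "arena_bounds" in raw:
            raw["arena_bounds"] = tuple(raw["arena_bounds"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "circle_center": list(self.circle_center),
            "circle_radius": self.circle_radius,
            "band_halfwidth": self.band_halfwidth,
            "arena_bounds": list(self.arena_bounds),
            "pixel_to_cm": self.pixel_to_cm,
            "fps": self.fps,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class Trajectory:
    """One female's path in one 90-s trial.

    ``segment`` marks maximal contiguous runs: cleaning never interpolates
    across long tracking gaps, it splits the trajectory instead, and all
    step-based statistics stay within a segment.
    """

    trial_id: str
    individual_id: str
    day: int
    fps: float
    t: np.ndarray        # seconds, strictly increasing
    x: np.ndarray        # cm, arena frame (origin at disc centre)
    y: np.ndarray
    theta: np.ndarray    # body orientation, radians (read but unused downstream)
    segment: np.ndarray = field(default=None)  # int run id per point

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.segment is None:
            self.segment = np.zeros(len(self.t), dtype=int)
        else:
            self.segment = np.asarray(self.segment, dtype=int)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.theta) == len(self.segment) == n):
            raise FormatError("trajectory arrays must have equal length")
        if n and not np.all(np.diff(self.t) > 0):
            raise FormatError("time must be strictly increasing")
        for arr in (self.t, self.x, self.y):
            if n and not np.all(np.isfinite(arr)):
                raise FormatError("coordinates and times must be finite")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def copy(self) -> "Trajectory":
        return Trajectory(self.trial_id, self.individual_id, self.day, self.fps,
                          self.t.copy(), self.x.copy(), self.y.copy(),
                          self.theta.copy(), self.segment.copy())


def read_trajectory(path, config: ArenaConfig, trial_id: str = "", individual_id: str = "",
                    day: int = 1) -> Trajectory:
    """Read a C-trax-style trajectory CSV and convert it to the arena frame.

    Raw coordinates are multiplied by ``pixel_to_cm`` and recentred on the
    disc centre; time is ``frame / fps`` (frame numbers are 0-based).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    frames = df["frame"].to_numpy(dtype=float)
    if len(frames) == 0:
        raise DegenerateInputError(f"{path}: empty trajectory")
    if not np.all(np.diff(frames) > 0):
        raise FormatError(f"{path}: frame index must be strictly increasing")
    cx, cy = config.circle_center
    x = df["x"].to_numpy(dtype=float) * config.pixel_to_cm - cx
    y = df["y"].to_numpy(dtype=float) * config.pixel_to_cm - cy
    return Trajectory(
        trial_id=trial_id or str(path),
        individual_id=individual_id,
        day=day,
        fps=config.fps,
        t=frames / config.fps,
        x=x,
        y=y,
        theta=df["theta"].to_numpy(dtype=float),
    )


def write_trajectory(traj: Trajectory, path, config: ArenaConfig | None = None) -> None:
    """Write a trajectory back to the CSV dialect ``read_trajectory`` accepts.

    Coordinates are written in the arena frame (the inverse pixel/recentring
    transform is applied only when a config is given).
    """
    x, y = traj.x, traj.y
    if config is not None:
        cx, cy = config.circle_center
        x = (x + cx) / config.pixel_to_cm
        y = (y + cy) / config.pixel_to_cm
    frames = np.rint(traj.t * traj.fps).astype(int)
    pd.DataFrame({"frame": frames, "x": x, "y": y, "theta": traj.theta}).to_csv(path, index=False)


def clean_trajectory(traj: Trajectory, max_speed: float = 30.0, max_gap: int = 5) -> Trajectory:
    """Remove tracking artefacts: teleport points and short dropouts.

    A point is dropped when the instantaneous speed from the last retained
    point exceeds ``max_speed`` (cm/s).  Gaps of at most ``max_gap`` missing
    frames are filled by linear interpolation, provided the implied crossing
    speed itself is admissible; longer (or too fast) gaps split the trajectory
    into segments.  The operation is idempotent.
    """
    if len(traj) == 0:
        raise DegenerateInputError("empty trajectory")
    dt0 = 1.0 / traj.fps
    # pass 1: drop teleport points, measured against the last retained point
    keep = [0]
    for i in range(1, len(traj)):
        j = keep[-1]
        dist = float(np.hypot(traj.x[i] - traj.x[j], traj.y[i] - traj.y[j]))
        if dist / (traj.t[i] - traj.t[j]) <= max_speed:
            keep.append(i)
    if len(keep) < 1:
        raise DegenerateInputError("no points left after cleaning")
    idx = np.array(keep)
    t, x, y, th = traj.t[idx], traj.x[idx], traj.y[idx], traj.theta[idx]
    seg_in = traj.segment[idx]

    # pass 2: interpolate short gaps, split at long ones
    out_t, out_x, out_y, out_th, out_seg = [t[0]], [x[0]], [y[0]], [th[0]], [0]
    seg = 0
    for i in range(1, len(t)):
        n_missing = int(round((t[i] - t[i - 1]) / dt0)) - 1
        gap_speed = np.hypot(x[i] - x[i - 1], y[i] - y[i - 1]) / (t[i] - t[i - 1])
        if seg_in[i] != seg_in[i - 1] or n_missing > max_gap or (n_missing > 0 and gap_speed > max_speed):
            seg += 1  # split: no interpolation across this gap
        elif n_missing > 0:
            for k in range(1, n_missing + 1):
                f = k / (n_missing + 1)
                out_t.append(t[i - 1] + f * (t[i] - t[i - 1]))
                out_x.append(x[i - 1] + f * (x[i] - x[i - 1]))
                out_y.append(y[i - 1] + f * (y[i] - y[i - 1]))
                out_th.append(th[i - 1] + f * (th[i] - th[i - 1]))
                out_seg.append(seg)
        out_t.append(t[i]); out_x.append(x[i]); out_y.append(y[i])
        out_th.append(th[i]); out_seg.append(seg)

    return Trajectory(traj.trial_id, traj.individual_id, traj.day, traj.fps,
                      np.array(out_t), np.array(out_x), np.array(out_y),
                      np.array(out_th), np.array(out_seg))


def cleaning_report(raw: Trajectory, cleaned: Trajectory) -> dict:
    """Validation summary of a cleaning pass (JSON-serializable)."""
    raw_frames = set(np.rint(raw.t * raw.fps).astype(int).tolist())
    out_frames = set(np.rint(cleaned.t * cleaned.fps).astype(int).tolist())
    return {
        "trial_id": raw.trial_id,
        "n_points_in": len(raw),
        "n_points_out": len(cleaned),
        "n_removed": len(raw_frames - out_frames),
        "n_interpolated": len(out_frames - raw_frames),
        "n_segments": int(len(np.unique(cleaned.segment))),
        "duration_s": cleaned.duration,
    }


DESIGN_COLUMNS = ("individual_id", "line", "subline", "session", "day")
TRAIT_COLUMNS = ("offspring", "longevity", "tibia")


def validate_design(df: pd.DataFrame) -> pd.DataFrame:
    """Validate factor nesting and uniqueness of a design/phenotype table."""
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"design table missing column(s) {missing}")
    nesting = df.groupby("subline")["line"].nunique()
    bad = nesting[nesting > 1]
    if len(bad):
        raise DesignError(f"subline(s) {list(bad.index)} appear under more than one line")
    if df.duplicated(subset=["individual_id", "day"]).any():
        raise DesignError("duplicate (individual_id, day) rows")
    return df


def read_design(path) -> pd.DataFrame:
    """Read the experiment design + fitness-trait table (one row per trial).

    Fitness traits (offspring, longevity, tibia) are optional columns; missing
    cells stay NaN and are treated as missing downstream, never imputed.
    """
    df = pd.read_csv(path)
    return validate_design(df)
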