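"""The seven behavioural variables computed from a zone-annotated trajectory.

Boldness:   time to first dark-area entry; |speed contrast| and |sinuosity
            contrast| between the white border band (zone 2) and the inner
            disc (zone 1).
Exploration: explored-area rate and path sinuosity, both in zone 1.
Activity:   activity rate (fraction of samples moving faster than a small
            threshold) and mean speed, both in the outer dark field (zone 4).

Sinuosity is Benhamou's corrected index S = 2 [p ((1+c)/(1-c) + b^2)]^(-1/2)
with p the mean step length (cm), c the mean cosine of turning angles and b
the coefficient of variation of step length; units cm^(-1/2).  It is computed
on raw (non-rediscretized) steps within each zone-residence run of at least
``min_steps`` steps, combining runs by step-count-weighted averaging of
(p, c, b) before applying the formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from trichopheno.geometry import ZoneAnnotatedTrajectory
from trichopheno.trajio import Trajectory

#: behavioural variable names, in canonical pipeline order
VARIABLES = (
    "mean_speed",        # activity: mean speed in zone 4, cm/s
    "activity_rate",     # activity: fraction of zone-4 samples moving, [0, 1]
    "dspeed_border",     # boldness: |speed(zone2) - speed(zone1)|, cm/s
    "dsinuosity_border",  # boldness: |sinuosity(zone2) - sinuosity(zone1)|, cm^-1/2
    "time_to_dark",      # boldness: latency to first dark-area entry, s
    "area_rate",         # exploration: explored area per unit time in zone 1, cm^2/s
    "mean_sinuosity",    # exploration: sinuosity in zone 1, cm^-1/2
)


@dataclass(frozen=True)
class EthoParams:
    """Tunable measurement parameters (all exposed in the pipeline config)."""

    cell_size: float = 0.1          # cm, occupancy-grid cell side for explored area
    min_steps: int = 10             # minimum steps per run for sinuosity
    activity_threshold: float = 0.01  # cm/s; active iff speed strictly above


@dataclass
class BehaviouralRecord:
    """Per-trial values of the seven behavioural variables (NaN = missing)."""

    individual_id: str
    day: int
    time_to_dark: float = np.nan
    censored: bool = False
    dspeed_border: float = np.nan
    dsinuosity_border: float = np.nan
    area_rate: float = np.nan
    mean_sinuosity: float = np.nan
    activity_rate: float = np.nan
    mean_speed: float = np.nan

    def as_dict(self) -> dict:
        return {
            "individual_id": self.individual_id, "day": self.day,
            "time_to_dark": self.time_to_dark, "censored": self.censored,
            "dspeed_border": self.dspeed_border,
            "dsinuosity_border": self.dsinuosity_border,
            "area_rate": self.area_rate, "mean_sinuosity": self.mean_sinuosity,
            "activity_rate": self.activity_rate, "mean_speed": self.mean_speed,
        }


def step_speeds(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-step (t_start, speed) pairs; no step crosses a cleaning split."""
    if len(traj) < 2:
        return np.empty(0), np.empty(0)
    same = traj.segment[1:] == traj.segment[:-1]
    dt = np.diff(traj.t)[same]
    dist = np.hypot(np.diff(traj.x), np.diff(traj.y))[same]
    return traj.t[:-1][same], dist / dt


def _steps(traj: Trajectory):
    """Step arrays (start index, dt, dist) within cleaning segments."""
    if len(traj) < 2:
        return np.empty(0, int), np.empty(0), np.empty(0)
    same = np.nonzero(traj.segment[1:] == traj.segment[:-1])[0]
    dt = traj.t[same + 1] - traj.t[same]
    dist = np.hypot(traj.x[same + 1] - traj.x[same], traj.y[same + 1] - traj.y[same])
    return same, dt, dist


def sinuosity_from_params(p: float, c: float, b: float) -> float:
    """Benhamou's corrected sinuosity from mean step length, mean turning-angle
    cosine and step-length CV.  Straight paths (c -> 1) return 0; the
    degenerate back-and-forth limit (c = -1, b = 0) is undefined (NaN)."""
    if not np.isfinite(p) or not np.isfinite(c) or p <= 0:
        return np.nan
    if c >= 1.0:
        return 0.0
    denom = p * ((1.0 + c) / (1.0 - c) + b * b)
    if denom <= 0 or not np.isfinite(denom):
        return np.nan
    return float(2.0 / np.sqrt(denom))


def _run_params(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """(p, c, b, n_steps) of one contiguous run of points."""
    dx, dy = np.diff(x), np.diff(y)
    dist = np.hypot(dx, dy)
    n = len(dist)
    if n == 0 or np.all(dist == 0):
        return np.nan, np.nan, np.nan, n
    headings = np.arctan2(dy, dx)
    moving = dist > 0  # heading undefined for zero-length steps
    turn = np.diff(headings[moving])
    c = float(np.mean(np.cos(turn))) if len(turn) else np.nan
    p = float(np.mean(dist))
    b = float(np.std(dist) / p)
    return p, c, b, n


def _combined_sinuosity(runs: list[tuple[np.ndarray, np.ndarray]], min_steps: int) -> float:
    """Step-count-weighted (p, c, b) across runs of >= min_steps steps."""
    ps, cs, bs, ws = [], [], [], []
    for x, y in runs:
        p, c, b, n = _run_params(x, y)
        if n >= min_steps and np.isfinite(p) and np.isfinite(c):
            ps.append(p); cs.append(c); bs.append(b); ws.append(n)
    if not ws:
        return np.nan
    w = np.asarray(ws, dtype=float)
    return sinuosity_from_params(np.average(ps, weights=w),
                                 np.average(cs, weights=w),
                                 np.average(bs, weights=w))


def sinuosity(traj: Trajectory, min_steps: int = 10) -> float:
    """Sinuosity of a whole trajectory (cm^-1/2), one run per cleaning segment."""
    runs = []
    for s in np.unique(traj.segment):
        m = traj.segment == s
        runs.append((traj.x[m], traj.y[m]))
    return _combined_sinuosity(runs, min_steps)


def _zone_runs(annotated: ZoneAnnotatedTrajectory, zone: int):
    """Contiguous runs of points in ``zone`` (within one cleaning segment)."""
    traj, zones = annotated.base, annotated.zone_per_point
    runs = []
    start = None
    for i in range(len(traj) + 1):
        inside = i < len(traj) and zones[i] == zone and (start is None or traj.segment[i] == traj.segment[start])
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            runs.append((traj.x[start:i], traj.y[start:i]))
            start = i if i < len(traj) and zones[i] == zone else None
    return runs


def zone_sinuosity(annotated: ZoneAnnotatedTrajectory, zone: int, min_steps: int = 10) -> float:
    return _combined_sinuosity(_zone_runs(annotated, zone), min_steps)


def _zone_step_speeds(annotated: ZoneAnnotatedTrajectory, zone: int) -> np.ndarray:
    idx, dt, dist = _steps(annotated.base)
    in_zone = annotated.zone_per_point[idx] == zone
    return (dist / dt)[in_zone]


def zone_mean_speed(annotated: ZoneAnnotatedTrajectory, zone: int) -> float:
    """Unweighted mean of per-step speeds whose starting point lies in ``zone``."""
    speeds = _zone_step_speeds(annotated, zone)
    return float(np.mean(speeds)) if len(speeds) else np.nan


def zone_residence_time(annotated: ZoneAnnotatedTrajectory, zone: int) -> float:
    """Total time attributed to ``zone``: sum of step dt starting in the zone."""
    idx, dt, _ = _steps(annotated.base)
    return float(np.sum(dt[annotated.zone_per_point[idx] == zone]))


def explored_area_rate(annotated: ZoneAnnotatedTrajectory, cell_size: float = 0.1) -> float:
    """Explored area per unit time in zone 1 (cm^2/s): distinct occupied cells
    of a square grid anchored at the disc centre, divided by zone-1 time."""
    t_in = zone_residence_time(annotated, 1)
    if t_in <= 0:
        return np.nan
    m = annotated.zone_per_point == 1
    ix = np.floor(annotated.base.x[m] / cell_size).astype(np.int64)
    iy = np.floor(annotated.base.y[m] / cell_size).astype(np.int64)
    n_cells = len(set(zip(ix.tolist(), iy.tolist())))
    return n_cells * cell_size * cell_size / t_in


def activity_rate(annotated: ZoneAnnotatedTrajectory, threshold: float = 0.01) -> float:
    """Fraction of zone-4 speed samples strictly greater than ``threshold``."""
    speeds = _zone_step_speeds(annotated, 4)
    if len(speeds) == 0:
        return np.nan
    return float(np.mean(speeds > threshold))


def border_contrasts(annotated: ZoneAnnotatedTrajectory, min_steps: int = 10) -> tuple[float, float]:
    """(|speed contrast|, |sinuosity contrast|) between zones 2 and 1."""
    s1, s2 = zone_mean_speed(annotated, 1), zone_mean_speed(annotated, 2)
    dspeed = abs(s2 - s1) if np.isfinite(s1) and np.isfinite(s2) else np.nan
    sin1 = zone_sinuosity(annotated, 1, min_steps)
    sin2 = zone_sinuosity(annotated, 2, min_steps)
    dsin = abs(sin2 - sin1) if np.isfinite(sin1) and np.isfinite(sin2) else np.nan
    return dspeed, dsin


def compute_record(annotated: ZoneAnnotatedTrajectory, params: EthoParams = EthoParams()) -> BehaviouralRecord:
    """All seven behavioural variables for one trial; missing stays NaN."""
    from trichopheno.geometry import first_entry_time

    ttd, censored = first_entry_time(annotated, zone=3)
    dspeed, dsin = border_contrasts(annotated, params.min_steps)
    return BehaviouralRecord(
        individual_id=annotated.base.individual_id,
        day=annotated.base.day,
        time_to_dark=ttd,
        censored=censored,
        dspeed_border=dspeed,
        dsinuosity_border=dsin,
        area_rate=explored_area_rate(annotated, params.cell_size),
        mean_sinuosity=zone_sinuosity(annotated, 1, params.min_steps),
        activity_rate=activity_rate(annotated, params.activity_threshold),
        mean_speed=zone_mean_speed(annotated, 4),
    )
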