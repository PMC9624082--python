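"""Arena zones and zone annotation of trajectories.

The arena is partitioned radially around the disc centre into four zones:

1. inner white disc (r < R - w)
2. white side of the border band (R - w <= r < R)
3. dark side of the border band (R <= r < R + w)
4. outer dark field (r >= R + w)

Intervals are half-open with the boundary assigned outward, so a point
exactly on the printed border (r = R) is already in the dark zone 3:
"entering the dark area" triggers on the first frame at or beyond the border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from trichopheno.errors import DegenerateInputError, GeometryError
from trichopheno.trajio import ArenaConfig, Trajectory


def zone_of_radius(r, arena: ArenaConfig):
    """Vectorized zone label from radial distance(s) to the disc centre."""
    r = np.asarray(r, dtype=float)
    R, w = arena.circle_radius, arena.band_halfwidth
    return np.asarray(1 + (r >= R - w).astype(int) + (r >= R).astype(int) + (r >= R + w).astype(int))


def assign_zone(point, arena: ArenaConfig) -> int:
    """Zone label (1-4) of a single (x, y) point in the arena frame."""
    x, y = float(point[0]), float(point[1])
    hx, hy = arena.half_bounds
    if abs(x) > hx or abs(y) > hy:
        raise GeometryError(f"point ({x}, {y}) outside arena bounds")
    return int(zone_of_radius(np.hypot(x, y), arena))


@dataclass
class ZoneAnnotatedTrajectory:
    """Trajectory plus per-point zone labels and residence segments.

    ``residence_segments`` is a list of (zone, t_start, t_end) tuples tiling
    the trajectory: maximal runs of constant zone within a cleaning segment.
    The duration of a run extends to the first point of the next run (each
    inter-frame step is attributed to the zone of its starting point).
    """

    base: Trajectory
    zone_per_point: np.ndarray
    residence_segments: list

    def __len__(self) -> int:
        return len(self.base)


def annotate(traj: Trajectory, arena: ArenaConfig) -> ZoneAnnotatedTrajectory:
    """Label every point with its zone and build residence segments."""
    if len(traj) == 0:
        raise DegenerateInputError("empty trajectory")
    hx, hy = arena.half_bounds
    if np.any(np.abs(traj.x) > hx) or np.any(np.abs(traj.y) > hy):
        raise GeometryError("trajectory leaves the arena bounds")
    zones = zone_of_radius(np.hypot(traj.x, traj.y), arena).astype(int)

    segments = []
    start = 0
    for i in range(1, len(traj) + 1):
        if i == len(traj) or zones[i] != zones[start] or traj.segment[i] != traj.segment[start]:
            t_end = traj.t[i] if i < len(traj) and traj.segment[i] == traj.segment[start] else traj.t[i - 1]
            segments.append((int(zones[start]), float(traj.t[start]), float(t_end)))
            start = i
    return ZoneAnnotatedTrajectory(base=traj, zone_per_point=zones, residence_segments=segments)


def write_annotated(annotated: ZoneAnnotatedTrajectory, path) -> None:
    """Annotated trajectory CSV: the standard columns plus a ``zone`` column."""
    import pandas as pd

    traj = annotated.base
    pd.DataFrame({
        "frame": np.rint(traj.t * traj.fps).astype(int),
        "x": traj.x, "y": traj.y, "theta": traj.theta,
        "zone": annotated.zone_per_point,
    }).to_csv(path, index=False)


def segments_to_json(annotated: ZoneAnnotatedTrajectory) -> list:
    """Residence segments as JSON-serializable records."""
    return [{"zone": z, "t_start": t0, "t_end": t1}
            for z, t0, t1 in annotated.residence_segments]


def first_entry_time(annotated: ZoneAnnotatedTrajectory, zone: int = 3) -> tuple[float, bool]:
    """Time until the female first reaches the dark area (zone >= ``zone``).

    Returns ``(time_s, censored)``; a female that never crosses is censored at
    the trial duration.  Time is measured from the first recorded frame.
    """
    if len(annotated) == 0:
        raise DegenerateInputError("empty trajectory")
    t0 = annotated.base.t[0]
    hits = np.nonzero(annotated.zone_per_point >= zone)[0]
    if len(hits) == 0:
        return float(annotated.base.t[-1] - t0), True
    return float(annotated.base.t[hits[0]] - t0), False
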