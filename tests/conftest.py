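"""Shared fixtures: arenas, hand-built trajectories, and small record-level
synthetic designs (no trajectory stage) for the statistical modules."""

import numpy as np
import pandas as pd
import pytest

from trichopheno.trajio import ArenaConfig, Trajectory


@pytest.fixture
def arena():
    return ArenaConfig()


def make_trajectory(x, y, fps=25.0, theta=None, individual_id="f1", day=1, segment=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.arange(len(x)) / fps
    theta = np.zeros_like(x) if theta is None else np.asarray(theta, dtype=float)
    return Trajectory(trial_id="trial", individual_id=individual_id, day=day,
                      fps=fps, t=t, x=x, y=y, theta=theta, segment=segment)


@pytest.fixture
def traj_factory():
    return make_trajectory


def study_design(n_lines=24, n_sessions=17, n_per=3):
    """Row-level crossed/nested layout matching the full study shape."""
    n_ind = n_lines * n_sessions * n_per
    lines = np.tile(np.repeat(np.arange(n_lines), n_per), n_sessions)
    sessions = np.repeat(np.arange(n_sessions), n_lines * n_per)
    sublines = lines * 2 + (np.arange(n_ind) % 2)
    return pd.DataFrame({
        "individual": np.tile(np.arange(n_ind), 2),
        "line": np.tile(lines, 2),
        "subline": np.tile(sublines, 2),
        "session": np.tile(sessions, 2),
        "day": np.repeat([1, 2], n_ind),
    })


def simulate_response(design, rng, line=0.0, subline=0.0, individual=0.0,
                      session=0.0, residual=1.0, mean=0.0):
    """Gaussian response with the given variance components on a design frame."""
    y = np.full(len(design), mean)
    for col, var in (("line", line), ("subline", subline),
                     ("individual", individual), ("session", session)):
        if var > 0:
            levels = design[col].to_numpy()
            u = rng.normal(0, np.sqrt(var), size=levels.max() + 1)
            y = y + u[levels]
    return y + rng.normal(0, np.sqrt(residual), size=len(design))


@pytest.fixture
def design_factory():
    return study_design


@pytest.fixture
def response_factory():
    return simulate_response
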