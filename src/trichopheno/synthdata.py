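"""Synthetic experiments with known ground truth.

Generates the full study layout — 24 isogenic lines x 2 sublines x 17
sessions x 3 females per line and session, each female assayed on 2
consecutive days — together with latent behavioural traits structured by
line / subline / session / individual variance components, correlated
random-walk trajectories expressing those latents, and fitness traits
(offspring count, longevity, tibia length) with a controlled line-level
correlation to the behavioural latents.  Every stage is reproducible from a
single master seed.

The trajectory generator is intentionally simple — an AR(1) speed process
around the individual's latent baseline speed, wrapped-normal heading
increments whose concentration is set by the latent exploration trait, and a
multiplicative modulation of speed and turning variance inside the border
band (zones 2-3) set by the latent boldness trait — just enough structure
for all seven measured variables to carry signal with controllable truth.

Latent traits (all on log scales where multiplicative):

- ``activity``: log baseline speed (cm/s); sets mean speed and, through the
  zero-clipping of the speed process, the activity rate.
- ``exploration``: log turning concentration; higher values mean straighter
  paths, more area explored, lower sinuosity.
- ``boldness``: log border-response factor; 0 means no reaction at the
  border, negative values mean slowing and straightening in the band.
- ``fecundity``: log expected offspring over 72 h (Poisson).
- ``longevity``: days (Gaussian).
- ``tibia``: mm (Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trichopheno.errors import DesignError
from trichopheno.trajio import ArenaConfig, Trajectory

TRAITS = ("activity", "exploration", "boldness", "fecundity", "longevity", "tibia")
COMPONENTS = ("line", "subline", "individual", "session", "residual")


@dataclass(frozen=True)
class VarianceSpec:
    """Absolute variance components of one latent trait (trait units^2)."""

    line: float = 0.0
    subline: float = 0.0
    individual: float = 0.0
    session: float = 0.0
    residual: float = 0.0

    def __post_init__(self):
        for c in COMPONENTS:
            if getattr(self, c) < 0:
                raise ValueError(f"negative variance component {c}")

    @property
    def total(self) -> float:
        return self.line + self.subline + self.individual + self.session + self.residual

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in COMPONENTS}


def _default_components() -> dict:
    # Calibrated (moment-matched against pilot simulations at the full study
    # size) so the *measured* traits land in the published range: the
    # trajectory stage adds within-trial measurement noise on top of these
    # latent components, so latent shares deliberately exceed the target
    # variance shares.  Targets: repeatability about 0.35 (mean speed),
    # 0.08 (activity rate), ~0.1 (border contrasts), ~0.2-0.25 (exploration);
    # heritability about 0.11 (mean speed), 0.05 (exploration measures);
    # fitness heritabilities 0.12 / 0.28 / 0.05.
    return {
        "activity":    VarianceSpec(line=.030, subline=.0022, individual=.031,
                                    session=.0051, residual=.027),
        "exploration": VarianceSpec(line=.0035, subline=.001, individual=.010,
                                    session=.003, residual=.037),
        "boldness":    VarianceSpec(line=.002, subline=.001, individual=.018,
                                    session=.006, residual=.045),
        "fecundity":   VarianceSpec(line=.024, subline=.006, individual=.13,
                                    session=.01, residual=.03),
        "longevity":   VarianceSpec(line=14.0, subline=2.0, individual=30.0,
                                    session=2.0, residual=2.0),
        "tibia":       VarianceSpec(line=.5e-5, subline=.1e-5, individual=8.0e-5,
                                    session=.2e-5, residual=1.2e-5),
    }


def _default_line_corr() -> pd.DataFrame:
    # Line-level (genetic) correlations: exploration trades off against
    # fecundity; activity goes with body size.
    C = np.eye(len(TRAITS))
    idx = {t: i for i, t in enumerate(TRAITS)}

    def set_corr(a, b, r):
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r

    set_corr("exploration", "fecundity", -0.6)
    set_corr("activity", "tibia", 0.5)
    return pd.DataFrame(C, index=list(TRAITS), columns=list(TRAITS))


@dataclass
class SyntheticTruth:
    """Generating parameters of a synthetic experiment."""

    components: dict = field(default_factory=_default_components)  # trait -> VarianceSpec
    means: dict = field(default_factory=lambda: {
        "activity": np.log(0.45),   # baseline speed ~0.45 cm/s
        "exploration": 0.0,         # multiplies the baseline turning sd
        "boldness": np.log(0.45),   # border factor ~0.45 (slows in the band)
        "fecundity": np.log(45.0),  # ~45 offspring per 72 h
        "longevity": 25.0,          # days
        "tibia": 0.175,             # mm
    })
    line_corr: pd.DataFrame = field(default_factory=_default_line_corr)
    base_turn_sd: float = 0.55      # rad per frame at exploration = 0
    speed_ar: float = 0.85          # AR(1) persistence of the speed process
    speed_cv: float = 1.0           # speed-noise scale (see speed_ref)
    # speed-noise sd = speed_cv * mu^speed_gamma * speed_ref^(1-speed_gamma):
    # partly absolute, partly proportional, so slower individuals pause more
    # often (zero-clipped speeds below the activity threshold), which is what
    # gives the activity rate its individual signal
    speed_ref: float = 0.45
    speed_gamma: float = 0.6
    dropout: float = 0.0            # fraction of day-2 trials lost
    master_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        C = self.line_corr.loc[list(TRAITS), list(TRAITS)].to_numpy()
        if np.min(np.linalg.eigvalsh((C + C.T) / 2)) < -1e-10:
            raise ValueError("line-level correlation matrix is not positive semi-definite")

    def to_json_dict(self) -> dict:
        return {
            "components": {t: v.as_dict() for t, v in self.components.items()},
            "means": {k: float(v) for k, v in self.means.items()},
            "line_corr": self.line_corr.to_dict(),
            "base_turn_sd": self.base_turn_sd,
            "speed_ar": self.speed_ar,
            "speed_cv": self.speed_cv,
            "speed_ref": self.speed_ref,
            "speed_gamma": self.speed_gamma,
            "dropout": self.dropout,
            "master_seed": self.master_seed,
        }


def generate_design(n_lines: int = 24, n_sublines: int = 2, n_sessions: int = 17,
                    n_per_line_session: int = 3, dropout: float = 0.0,
                    seed: int = 0) -> pd.DataFrame:
    """Trial table of the crossed/nested study layout, one row per trial.

    With the defaults and no dropout: 24*17*3 = 1224 individuals, two trials
    (days) each.  Dropout removes day-2 rows at the given rate, emulating
    females lost between the two observation days.
    """
    if min(n_lines, n_sublines, n_sessions, n_per_line_session) < 1:
        raise DesignError("all design counts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for session in range(1, n_sessions + 1):
        for line in range(1, n_lines + 1):
            for k in range(n_per_line_session):
                subline = (line - 1) * n_sublines + (k % n_sublines) + 1
                iid = f"L{line:02d}S{session:02d}F{k + 1}"
                for day in (1, 2):
                    rows.append((iid, line, subline, session, day))
    df = pd.DataFrame(rows, columns=["individual_id", "line", "subline", "session", "day"])
    if dropout > 0:
        day2 = df.index[df["day"] == 2]
        drop = day2[rng.random(len(day2)) < dropout]
        df = df.drop(drop).reset_index(drop=True)
    return df


def generate_latents(design: pd.DataFrame, truth: SyntheticTruth,
                     seed: int | None = None) -> pd.DataFrame:
    """Per-individual latent trait values mu + u_line + u_subline + u_session
    + u_individual (the per-day residual is added at trajectory / phenotype
    generation time).

    Line effects are drawn jointly across traits from the line-level
    correlation matrix, so genetic correlations between behaviour and fitness
    are controlled; subline, session and individual effects are independent
    across traits.
    """
    rng = np.random.default_rng(truth.master_seed if seed is None else seed)
    ind = (design[["individual_id", "line", "subline", "session"]]
           .drop_duplicates("individual_id").reset_index(drop=True))
    lines = np.unique(ind["line"])
    sublines = np.unique(ind["subline"])
    sessions = np.unique(ind["session"])
    li = pd.Series(np.arange(len(lines)), index=lines)[ind["line"]].to_numpy()
    si = pd.Series(np.arange(len(sublines)), index=sublines)[ind["subline"]].to_numpy()
    se = pd.Series(np.arange(len(sessions)), index=sessions)[ind["session"]].to_numpy()

    C = truth.line_corr.loc[list(TRAITS), list(TRAITS)].to_numpy()
    sd_line = np.array([np.sqrt(truth.components[t].line) for t in TRAITS])
    cov = C * np.outer(sd_line, sd_line)
    u_line = rng.multivariate_normal(np.zeros(len(TRAITS)), cov, size=len(lines),
                                     method="svd")

    out = ind.copy()
    for j, t in enumerate(TRAITS):
        vs = truth.components[t]
        u_sub = rng.normal(0, np.sqrt(vs.subline), size=len(sublines))
        u_ses = rng.normal(0, np.sqrt(vs.session), size=len(sessions))
        u_ind = rng.normal(0, np.sqrt(vs.individual), size=len(ind))
        out[t] = truth.means[t] + u_line[li, j] + u_sub[si] + u_ses[se] + u_ind
    return out


def sample_trait_observations(design: pd.DataFrame, latents: pd.DataFrame,
                              truth: SyntheticTruth, trait: str,
                              seed: int = 0) -> np.ndarray:
    """One latent-scale observation per design row: latent + day residual."""
    rng = np.random.default_rng(seed)
    lat = latents.set_index("individual_id")[trait][design["individual_id"]].to_numpy()
    return lat + rng.normal(0, np.sqrt(truth.components[trait].residual), size=len(design))


def _trajectory_params(latent_row, truth: SyntheticTruth, day_noise) -> dict:
    """Map (latent + per-day residual) to walk parameters for one trial."""
    act = latent_row["activity"] + day_noise[0]
    exp_ = latent_row["exploration"] + day_noise[1]
    bold = latent_row["boldness"] + day_noise[2]
    return {
        "mu_speed": float(np.exp(act)),
        "turn_sd": float(truth.base_turn_sd * np.exp(-exp_)),
        "border_factor": float(np.exp(bold)),
    }


def _simulate_walks(params: list[dict], arena: ArenaConfig, duration: float,
                    fps: float, seeds: list[int], truth: SyntheticTruth) -> np.ndarray:
    """Vectorized correlated random walks; returns (n, steps+1, 3) = (x, y, theta).

    Per-trial noise streams are drawn from per-trial generators up front, so a
    batch run and a single-trial run with the same seed produce identical
    paths.  Walls reflect; the border band (zones 2-3) multiplies the target
    speed and the turning variance by the trial's border-response factor.
    """
    n = len(params)
    steps = int(round(duration * fps))
    dt = 1.0 / fps
    n1 = np.empty((n, steps)); n2 = np.empty((n, steps)); h0 = np.empty(n)
    for i, s in enumerate(seeds):
        g = np.random.default_rng(s)
        h0[i] = g.uniform(-np.pi, np.pi)
        n1[i] = g.standard_normal(steps)   # heading noise
        n2[i] = g.standard_normal(steps)   # speed noise
    mu = np.array([p["mu_speed"] for p in params])
    tsd = np.array([p["turn_sd"] for p in params])
    bf = np.array([p["border_factor"] for p in params])
    phi = truth.speed_ar
    s_sd = (truth.speed_cv * mu**truth.speed_gamma * truth.speed_ref**(1 - truth.speed_gamma)
            * np.sqrt(1 - phi**2))

    hx, hy = arena.half_bounds
    R, w = arena.circle_radius, arena.band_halfwidth
    out = np.empty((n, steps + 1, 3))
    x = np.zeros(n); y = np.zeros(n)
    heading = h0.copy()
    speed = mu.copy()
    out[:, 0, 0], out[:, 0, 1], out[:, 0, 2] = x, y, heading
    for k in range(steps):
        r = np.hypot(x, y)
        in_band = (r >= R - w) & (r < R + w)
        fac = np.where(in_band, bf, 1.0)
        target = mu * fac
        speed = target + phi * (speed - target) + s_sd * np.sqrt(fac) * n2[:, k]
        speed = np.maximum(speed, 0.0)
        # heading diffusion scales with sqrt(speed): constant turning variance
        # per unit path length, so path sinuosity is speed-invariant and the
        # exploration latent, not the activity latent, owns it
        heading = heading + tsd * np.sqrt(fac * speed / truth.speed_ref) * n1[:, k]
        x = x + speed * dt * np.cos(heading)
        y = y + speed * dt * np.sin(heading)
        # reflective walls
        over = x > hx
        x = np.where(over, 2 * hx - x, x)
        heading = np.where(over, np.pi - heading, heading)
        under = x < -hx
        x = np.where(under, -2 * hx - x, x)
        heading = np.where(under, np.pi - heading, heading)
        over = y > hy
        y = np.where(over, 2 * hy - y, y)
        heading = np.where(over, -heading, heading)
        under = y < -hy
        y = np.where(under, -2 * hy - y, y)
        heading = np.where(under, -heading, heading)
        out[:, k + 1, 0], out[:, k + 1, 1], out[:, k + 1, 2] = x, y, heading
    return out


def _trial_seed(master_seed: int, individual_id: str, day: int) -> int:
    """Stable per-trial sub-seed (FNV-1a hash of master seed and trial ids)."""
    h = 14695981039346656037
    for ch in f"{master_seed}|{individual_id}|{day}":
        h = ((h ^ ord(ch)) * 1099511628211) % 2**64
    return int(h % 2**31)


def _day_params(latent_row, day: int, truth: SyntheticTruth, seed: int) -> dict:
    day_rng = np.random.default_rng(seed + 2**31)
    day_noise = [day_rng.normal(0, np.sqrt(truth.components[t].residual))
                 for t in ("activity", "exploration", "boldness")]
    return _trajectory_params(latent_row, truth, day_noise)


def generate_trajectory(latent_row, day: int, truth: SyntheticTruth,
                        arena: ArenaConfig | None = None, duration: float = 90.0,
                        fps: float = 25.0, seed: int | None = None) -> Trajectory:
    """One trial's correlated random walk as a Trajectory (duration*fps + 1
    points), started at the disc centre."""
    arena = arena or ArenaConfig()
    iid = latent_row["individual_id"]
    s = _trial_seed(truth.master_seed, iid, day) if seed is None else seed
    p = _day_params(latent_row, day, truth, s)
    path = _simulate_walks([p], arena, duration, fps, [s], truth)[0]
    t = np.arange(path.shape[0]) / fps
    return Trajectory(trial_id=f"{iid}-d{day}", individual_id=iid, day=day, fps=fps,
                      t=t, x=path[:, 0], y=path[:, 1], theta=path[:, 2])


def generate_trajectories(design: pd.DataFrame, latents: pd.DataFrame,
                          truth: SyntheticTruth, arena: ArenaConfig | None = None,
                          duration: float = 90.0, fps: float = 25.0) -> list[Trajectory]:
    """All trial trajectories of an experiment, batch-vectorized (identical
    to calling ``generate_trajectory`` per trial)."""
    arena = arena or ArenaConfig()
    lat = latents.set_index("individual_id")
    params, seeds, meta = [], [], []
    for iid, day in design[["individual_id", "day"]].itertuples(index=False):
        s = _trial_seed(truth.master_seed, iid, day)
        params.append(_day_params(lat.loc[iid], day, truth, s))
        seeds.append(s)
        meta.append((iid, day))
    paths = _simulate_walks(params, arena, duration, fps, seeds, truth)
    t = np.arange(paths.shape[1]) / fps
    return [Trajectory(trial_id=f"{iid}-d{day}", individual_id=iid, day=day, fps=fps,
                       t=t.copy(), x=paths[i, :, 0], y=paths[i, :, 1], theta=paths[i, :, 2])
            for i, (iid, day) in enumerate(meta)]


def generate_fitness(latents: pd.DataFrame, truth: SyntheticTruth,
                     seed: int | None = None) -> pd.DataFrame:
    """Offspring count (Poisson around the exponentiated fecundity latent),
    longevity and tibia length (Gaussian measurement noise) per individual."""
    rng = np.random.default_rng((truth.master_seed + 1) if seed is None else seed)
    n = len(latents)
    out = latents[["individual_id", "line", "subline", "session"]].copy()
    lam = np.exp(latents["fecundity"].to_numpy()
                 + rng.normal(0, np.sqrt(truth.components["fecundity"].residual), n))
    out["offspring"] = rng.poisson(lam)
    out["longevity"] = latents["longevity"].to_numpy() + rng.normal(
        0, np.sqrt(truth.components["longevity"].residual), n)
    out["tibia"] = latents["tibia"].to_numpy() + rng.normal(
        0, np.sqrt(truth.components["tibia"].residual), n)
    return out
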