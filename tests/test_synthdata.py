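"""Synthetic-experiment generator: design layout, latent structure,
trajectory realism constraints, fitness traits, and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from trichopheno.errors import DesignError
from trichopheno.ethometrics import zone_mean_speed
from trichopheno.geometry import annotate, zone_of_radius
from trichopheno.synthdata import (SyntheticTruth, VarianceSpec, generate_design,
                                   generate_fitness, generate_latents,
                                   generate_trajectories, generate_trajectory,
                                   sample_trait_observations)
from trichopheno.trajio import ArenaConfig, clean_trajectory


def small_truth(**kw):
    comps = {
        "activity": VarianceSpec(line=.02, individual=.02, residual=.01),
        "exploration": VarianceSpec(line=.01, individual=.01, residual=.01),
        "boldness": VarianceSpec(individual=.02, residual=.01),
        "fecundity": VarianceSpec(line=.02, individual=.1, residual=.03),
        "longevity": VarianceSpec(line=10.0, individual=30.0, residual=5.0),
        "tibia": VarianceSpec(line=1e-5, individual=5e-5, residual=1e-5),
    }
    return SyntheticTruth(components=comps, **kw)


class TestDesign:
    def test_default_counts(self):
        df = generate_design()
        assert df["individual_id"].nunique() == 1224
        assert len(df) == 2448
        assert df.groupby("line")["subline"].nunique().eq(2).all()

    def test_small_layout(self):
        df = generate_design(n_lines=2, n_sublines=2, n_sessions=1, n_per_line_session=3)
        assert df["individual_id"].nunique() == 6

    def test_dropout_only_day2_and_deterministic(self):
        a = generate_design(dropout=0.15, seed=5)
        b = generate_design(dropout=0.15, seed=5)
        assert a.equals(b)
        assert (a[a["day"] == 1]["individual_id"].nunique() == 1224)
        n_day2 = (a["day"] == 2).sum()
        assert 1224 * 0.75 < n_day2 < 1224 * 0.95

    def test_invalid_counts_rejected(self):
        with pytest.raises(DesignError):
            generate_design(n_lines=0)


class TestLatents:
    def test_zero_variance_gives_means(self):
        truth = SyntheticTruth(components={
            t: VarianceSpec() for t in
            ("activity", "exploration", "boldness", "fecundity", "longevity", "tibia")})
        design = generate_design(n_lines=3, n_sessions=2)
        lat = generate_latents(design, truth)
        for t, mu in truth.means.items():
            assert lat[t].to_numpy() == pytest.approx(np.full(len(lat), mu))

    def test_line_level_correlation_recovered(self):
        """Across replicate draws, the sample correlation of line effects in
        exploration and fecundity concentrates on the generating -0.6."""
        comps = dict(small_truth().components)
        # line-dominant components so line means are nearly the line effects
        comps["exploration"] = VarianceSpec(line=0.5, individual=0.01, residual=0.01)
        comps["fecundity"] = VarianceSpec(line=0.5, individual=0.01, residual=0.01)
        truth = SyntheticTruth(components=comps)
        design = generate_design(n_lines=24, n_sessions=2)
        corrs = []
        for seed in range(300):
            lat = generate_latents(design, truth, seed=seed)
            line_means = lat.groupby("line")[["exploration", "fecundity"]].mean()
            corrs.append(np.corrcoef(line_means["exploration"],
                                     line_means["fecundity"])[0, 1])
        assert np.mean(corrs) == pytest.approx(-0.6, abs=0.05)

    def test_individual_variance_law_of_large_numbers(self):
        truth = small_truth()
        design = generate_design(n_lines=24, n_sessions=17)
        lat = generate_latents(design, truth, seed=1)
        within = lat.groupby("line")["activity"].transform("mean")
        resid = lat["activity"] - within
        # within-line spread ~ individual + session variance
        expected = (truth.components["activity"].individual
                    + truth.components["activity"].session)
        assert np.var(resid) == pytest.approx(expected, rel=0.15)

    def test_non_psd_matrix_rejected(self):
        bad = small_truth().line_corr.copy()
        bad.loc["activity", "exploration"] = 0.9
        bad.loc["exploration", "activity"] = 0.9
        bad.loc["exploration", "fecundity"] = -0.9
        bad.loc["fecundity", "exploration"] = -0.9
        bad.loc["activity", "fecundity"] = 0.9
        bad.loc["fecundity", "activity"] = 0.9
        with pytest.raises(ValueError):
            SyntheticTruth(line_corr=bad)


class TestTrajectories:
    def test_point_count_and_bounds(self):
        truth = small_truth()
        design = generate_design(n_lines=2, n_sessions=1)
        lat = generate_latents(design, truth, seed=0)
        traj = generate_trajectory(lat.iloc[0], day=1, truth=truth)
        arena = ArenaConfig()
        assert len(traj) == 90 * 25 + 1
        hx, hy = arena.half_bounds
        assert np.all(np.abs(traj.x) <= hx) and np.all(np.abs(traj.y) <= hy)
        assert traj.x[0] == 0.0 and traj.y[0] == 0.0

    def test_zero_noise_straight_until_wall(self):
        comps = {k: VarianceSpec() for k in small_truth().components}
        truth = SyntheticTruth(components=comps, base_turn_sd=0.0, speed_cv=0.0)
        design = generate_design(n_lines=1, n_sublines=1, n_sessions=1,
                                 n_per_line_session=1)
        lat = generate_latents(design, truth, seed=3)
        traj = generate_trajectory(lat.iloc[0], day=1, truth=truth)
        # straight path: all turning angles zero until (possibly) a reflection
        dx, dy = np.diff(traj.x), np.diff(traj.y)
        headings = np.arctan2(dy, dx)
        changes = np.abs(np.diff(headings)) > 1e-9
        # heading changes only at wall reflections (40 cm of path in a
        # 24 x 18 box supports at most a handful)
        assert changes.sum() <= 5

    def test_batch_equals_single(self):
        truth = small_truth()
        design = generate_design(n_lines=2, n_sessions=1)
        lat = generate_latents(design, truth, seed=0)
        batch = generate_trajectories(design, lat, truth)
        row = lat[lat["individual_id"] == batch[3].individual_id].iloc[0]
        single = generate_trajectory(row, day=batch[3].day, truth=truth)
        assert np.array_equal(single.x, batch[3].x)
        assert np.array_equal(single.y, batch[3].y)

    def test_reproducible_from_master_seed(self):
        truth = small_truth(master_seed=11)
        design = generate_design(n_lines=2, n_sessions=1)
        lat = generate_latents(design, truth)
        t1 = generate_trajectory(lat.iloc[0], day=2, truth=truth)
        t2 = generate_trajectory(lat.iloc[0], day=2, truth=truth)
        assert np.array_equal(t1.x, t2.x)

    def test_zone4_speed_matches_generator_truth(self, arena):
        """Per-zone mean speed recomputed by the measurement pipeline agrees
        with the speed series the generator realized (discretization < 2%)."""
        truth = small_truth()
        design = generate_design(n_lines=3, n_sessions=1)
        lat = generate_latents(design, truth, seed=2)
        diffs = []
        for i in range(6):
            traj = generate_trajectory(lat.iloc[i], day=1, truth=truth)
            # generator-side truth: realized step speeds by zone of step start
            speeds = np.hypot(np.diff(traj.x), np.diff(traj.y)) * 25.0
            zones = zone_of_radius(np.hypot(traj.x[:-1], traj.y[:-1]), arena)
            if not np.any(zones == 4):
                continue
            gen_truth = speeds[zones == 4].mean()
            measured = zone_mean_speed(annotate(clean_trajectory(traj), arena), 4)
            diffs.append(abs(measured - gen_truth) / gen_truth)
        assert diffs and max(diffs) < 0.02


class TestFitness:
    def test_poisson_mean_recovers_latent(self):
        comps = {k: VarianceSpec() for k in
                 ("activity", "exploration", "boldness", "fecundity", "longevity", "tibia")}
        truth = SyntheticTruth(components=comps)
        truth.means["fecundity"] = np.log(50.0)
        design = generate_design(n_lines=24, n_sessions=17)
        lat = generate_latents(design, truth, seed=0)
        fit = generate_fitness(lat, truth, seed=1)
        assert fit["offspring"].mean() == pytest.approx(50.0, rel=0.02)

    def test_reproducible(self):
        truth = small_truth(master_seed=4)
        design = generate_design(n_lines=2, n_sessions=2)
        lat = generate_latents(design, truth)
        a = generate_fitness(lat, truth)
        b = generate_fitness(lat, truth)
        assert a.equals(b)

    def test_zero_line_variance_null_heritability(self):
        from trichopheno.varcomp import ModelSpec, fit_random_intercepts, ratio_estimate
        comps = {k: VarianceSpec(individual=1e-6, residual=1e-6) for k in
                 ("activity", "exploration", "boldness", "fecundity", "longevity")}
        comps["tibia"] = VarianceSpec(line=0.0, individual=5e-5, session=1e-5,
                                      subline=0.0, residual=1e-5)
        truth = SyntheticTruth(components=comps)
        design = generate_design(n_lines=24, n_sessions=17)
        lat = generate_latents(design, truth, seed=5)
        fit = generate_fitness(lat, truth, seed=6)
        fit = fit.rename(columns={"individual_id": "individual"})
        vc = fit_random_intercepts(fit, ModelSpec("tibia", ("line", "subline", "session")))
        assert ratio_estimate(vc, "line").point < 0.02


class TestRecordLevelSampling:
    def test_observation_equals_latent_plus_day_noise(self):
        truth = small_truth()
        design = generate_design(n_lines=24, n_sessions=5)
        lat = generate_latents(design, truth, seed=0)
        obs = sample_trait_observations(design, lat, truth, "activity", seed=1)
        assert len(obs) == len(design)
        lat_map = lat.set_index("individual_id")["activity"][design["individual_id"]]
        resid = obs - lat_map.to_numpy()
        sd = np.sqrt(truth.components["activity"].residual)
        assert np.std(resid) == pytest.approx(sd, rel=0.1)
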