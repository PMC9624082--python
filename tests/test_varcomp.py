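"""REML variance components against closed forms and a dense-likelihood
oracle; ratios, bootstrap CIs and BLUPs."""

import numpy as np
import pandas as pd
import pytest

from trichopheno.errors import FitError
from trichopheno.varcomp import (ModelSpec, RatioEstimate, VarianceComponents,
                                 _Collapsed, bootstrap_ci, extract_blups,
                                 fit_random_intercepts, ratio_estimate,
                                 transform_response)
from tests.conftest import simulate_response, study_design


def oneway(rng, n_groups=20, reps=5, var_g=0.5, var_e=1.0):
    g = np.repeat(np.arange(n_groups), reps)
    y = rng.normal(0, np.sqrt(var_e), n_groups * reps) + \
        rng.normal(0, np.sqrt(var_g), n_groups)[g]
    return pd.DataFrame({"y": y, "group": g})


def anova_estimates(df, reps):
    """Closed-form balanced one-way ANOVA estimators."""
    wide = df["y"].to_numpy().reshape(-1, reps)
    means = wide.mean(axis=1)
    msb = reps * np.var(means, ddof=1)
    msw = np.sum((wide - means[:, None]) ** 2) / (len(means) * (reps - 1))
    return (msb - msw) / reps, msw


class TestRemlOracles:
    def test_balanced_oneway_matches_anova(self):
        rng = np.random.default_rng(42)
        spec = ModelSpec("y", ("group",))
        for _ in range(10):
            df = oneway(rng)
            sig_g, sig_e = anova_estimates(df, 5)
            vc = fit_random_intercepts(df, spec)
            if sig_g >= 0:
                assert vc.sigma2["group"] == pytest.approx(sig_g, abs=1e-6)
                assert vc.sigma2_resid == pytest.approx(sig_e, abs=1e-6)
            else:
                assert vc.sigma2["group"] == 0.0

    def test_criterion_matches_dense_reml(self, design_factory, response_factory):
        """Collapsed+Woodbury criterion equals the brute-force dense restricted
        likelihood (up to a theta-independent constant) on a small design."""
        rng = np.random.default_rng(3)
        design = design_factory(n_lines=4, n_sessions=3, n_per=2)
        design["y"] = response_factory(design, rng, line=0.6, subline=0.1,
                                       individual=0.7, session=0.4, residual=1.0)
        spec = ModelSpec("y", ("line", "subline", "individual", "session"))
        model = _Collapsed(design, spec, None)

        n = len(design)
        X = np.ones((n, 1))
        Zs = []
        for f in ["individual"] + model.small_names:
            levels, codes = np.unique(design[f], return_inverse=True)
            Z = np.zeros((n, len(levels)))
            Z[np.arange(n), codes] = 1.0
            Zs.append(Z)

        def dense(theta):
            V = theta[0] * np.eye(n)
            for Z, v in zip(Zs, theta[1:]):
                V += v * (Z @ Z.T)
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ design["y"].to_numpy())
            r = design["y"].to_numpy() - X @ beta
            return (np.linalg.slogdet(V)[1] + np.linalg.slogdet(X.T @ Vi @ X)[1]
                    + r @ Vi @ r)

        t1 = np.array([0.9, 0.5, 0.6, 0.1, 0.9])
        t2 = np.array([1.2, 0.2, 0.1, 0.4, 0.3])
        assert (model.criterion(t1) - model.criterion(t2)) == pytest.approx(
            dense(t1) - dense(t2), abs=1e-9)

    def test_analytic_gradient_matches_finite_differences(self, design_factory,
                                                          response_factory):
        rng = np.random.default_rng(4)
        design = design_factory(n_lines=4, n_sessions=3, n_per=2)
        design["y"] = response_factory(design, rng, line=0.3, individual=0.5,
                                       session=0.2, residual=0.8)
        spec = ModelSpec("y", ("line", "subline", "individual", "session"))
        model = _Collapsed(design, spec, None)
        theta = np.array([0.8, 0.4, 0.3, 0.2, 0.5])
        _, grad = model.eval(theta, want_grad=True)
        eps = 1e-6
        for k in range(len(theta)):
            d = np.zeros_like(theta)
            d[k] = eps
            fd = (model.criterion(theta + d) - model.criterion(theta - d)) / (2 * eps)
            assert grad[k] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_study_size_recovery(self, design_factory, response_factory):
        """Mean estimates across replicate experiments near the generating
        components at the full study size."""
        rng = np.random.default_rng(5)
        design = study_design()
        truth = dict(line=0.10, subline=0.05, individual=0.35, session=0.10, residual=0.40)
        spec = ModelSpec("y", ("line", "subline", "individual", "session"))
        keys = ["line", "subline", "individual", "session"]
        sums = dict.fromkeys(keys + ["residual"], 0.0)
        n_rep = 20
        for _ in range(n_rep):
            design["y"] = simulate_response(design, rng, **truth)
            vc = fit_random_intercepts(design, spec)
            for k in keys:
                sums[k] += vc.sigma2[k]
            sums["residual"] += vc.sigma2_resid
        for k, target in truth.items():
            assert sums[k] / n_rep == pytest.approx(target, rel=0.10, abs=0.01)


class TestEdgeCases:
    def test_constant_response_all_zero(self):
        df = pd.DataFrame({"y": np.ones(40), "group": np.repeat(np.arange(8), 5)})
        vc = fit_random_intercepts(df, ModelSpec("y", ("group",)))
        assert vc.converged
        assert vc.sigma2["group"] == 0.0
        assert vc.sigma2_resid == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        df = oneway(rng)
        spec = ModelSpec("y", ("group",))
        vc1 = fit_random_intercepts(df, spec)
        df2 = df.assign(y=df["y"] + 137.5)
        vc2 = fit_random_intercepts(df2, spec)
        assert vc2.sigma2["group"] == pytest.approx(vc1.sigma2["group"], abs=1e-8)
        assert vc2.sigma2_resid == pytest.approx(vc1.sigma2_resid, abs=1e-8)

    def test_scale_equivariance_and_ratio_invariance(self):
        rng = np.random.default_rng(7)
        df = oneway(rng)
        spec = ModelSpec("y", ("group",))
        vc1 = fit_random_intercepts(df, spec)
        k = 3.7
        vc2 = fit_random_intercepts(df.assign(y=df["y"] * k), spec)
        assert vc2.sigma2["group"] == pytest.approx(k**2 * vc1.sigma2["group"], rel=1e-5)
        r1 = ratio_estimate(vc1, "group").point
        r2 = ratio_estimate(vc2, "group").point
        assert r2 == pytest.approx(r1, abs=1e-6)

    def test_missing_factor_rejected(self):
        df = pd.DataFrame({"y": np.arange(10.0), "group": np.arange(10) % 2})
        with pytest.raises(FitError):
            fit_random_intercepts(df, ModelSpec("y", ("group", "session")))

    def test_individual_needs_replicates(self):
        df = pd.DataFrame({"y": np.arange(10.0), "individual": np.arange(10),
                           "session": np.arange(10) % 2})
        with pytest.raises(FitError):
            fit_random_intercepts(df, ModelSpec("y", ("individual", "session")))


class TestRatios:
    def test_ratio_arithmetic(self):
        vc = VarianceComponents(sigma2={"individual": 1.0, "session": 0.5},
                                sigma2_resid=2.0, reml_loglik=0.0,
                                converged=True, n_obs=10)
        est = ratio_estimate(vc, "individual")
        assert est.point == pytest.approx(1.0 / 3.5)
        assert est.label == "repeatability"

    def test_zero_grouping_variance(self):
        vc = VarianceComponents(sigma2={"line": 0.0, "individual": 1.0},
                                sigma2_resid=1.0, reml_loglik=0.0,
                                converged=True, n_obs=10)
        assert ratio_estimate(vc, "line").point == 0.0
        assert ratio_estimate(vc, "line").label == "heritability"

    def test_zero_total_variance_rejected(self):
        vc = VarianceComponents(sigma2={"line": 0.0}, sigma2_resid=0.0,
                                reml_loglik=0.0, converged=True, n_obs=10)
        with pytest.raises(FitError):
            ratio_estimate(vc, "line")

    def test_nonconverged_refused(self):
        vc = VarianceComponents(sigma2={"line": 0.5}, sigma2_resid=1.0,
                                reml_loglik=0.0, converged=False, n_obs=10)
        with pytest.raises(FitError):
            ratio_estimate(vc, "line")


class TestBootstrap:
    def test_point_only_without_bootstrap(self):
        rng = np.random.default_rng(8)
        df = oneway(rng)
        est = bootstrap_ci(df, ModelSpec("y", ("group",)), "group", n_boot=0, seed=1)
        assert np.isnan(est.ci_low) and np.isnan(est.ci_high)
        assert est.n_boot == 0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        df = oneway(rng, n_groups=10, reps=3)
        spec = ModelSpec("y", ("group",))
        a = bootstrap_ci(df, spec, "group", n_boot=50, seed=77)
        b = bootstrap_ci(df, spec, "group", n_boot=50, seed=77)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_zero_variance_boundary_mass(self):
        rng = np.random.default_rng(10)
        df = oneway(rng, n_groups=50, reps=4, var_g=0.0)
        est = bootstrap_ci(df, ModelSpec("y", ("group",)), "group", n_boot=100, seed=3)
        assert est.ci_low == 0.0


class TestBlups:
    def test_shrinkage_closed_form(self):
        rng = np.random.default_rng(11)
        reps = 5
        df = oneway(rng, reps=reps)
        vc = fit_random_intercepts(df, ModelSpec("y", ("group",)))
        sa, se = vc.sigma2["group"], vc.sigma2_resid
        shrink = reps * sa / (reps * sa + se)
        means = df.groupby("group")["y"].mean()
        # GLS grand mean for a balanced design = unweighted mean of group means
        expected = shrink * (means - means.mean())
        got = extract_blups(vc, "group").as_series()
        assert np.max(np.abs(got - expected)) < 1e-8

    def test_blups_sum_to_zero(self, design_factory, response_factory):
        rng = np.random.default_rng(12)
        design = design_factory(n_lines=6, n_sessions=4, n_per=2)
        design["y"] = response_factory(design, rng, line=0.4, subline=0.1,
                                       individual=0.5, session=0.2, residual=1.0)
        spec = ModelSpec("y", ("line", "subline", "individual", "session"))
        vc = fit_random_intercepts(design, spec)
        for f in spec.random_factors:
            vals = extract_blups(vc, f).as_series()
            assert abs(vals.mean()) < 1e-8 * max(vals.std(), 1e-12)

    def test_dense_mme_oracle(self, design_factory, response_factory):
        """BLUPs equal the dense conditional mean sigma2_f Z' V^-1 (y - X beta)."""
        rng = np.random.default_rng(13)
        design = design_factory(n_lines=3, n_sessions=2, n_per=2)
        design["y"] = response_factory(design, rng, line=0.5, individual=0.6,
                                       session=0.3, residual=0.9)
        spec = ModelSpec("y", ("line", "individual", "session"))
        vc = fit_random_intercepts(design, spec)
        n = len(design)
        y = design["y"].to_numpy()
        X = np.ones((n, 1))
        V = vc.sigma2_resid * np.eye(n)
        Zmap = {}
        for f in spec.random_factors:
            levels, codes = np.unique(design[f], return_inverse=True)
            Z = np.zeros((n, len(levels)))
            Z[np.arange(n), codes] = 1.0
            Zmap[f] = Z
            V += vc.sigma2[f] * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        for f in spec.random_factors:
            dense = vc.sigma2[f] * Zmap[f].T @ Vi @ r
            got = extract_blups(vc, f).as_series().to_numpy()
            assert np.max(np.abs(dense - got)) < 1e-8

    def test_absent_factor_rejected(self):
        rng = np.random.default_rng(14)
        vc = fit_random_intercepts(oneway(rng), ModelSpec("y", ("group",)))
        with pytest.raises(FitError):
            extract_blups(vc, "line")


class TestTransform:
    def test_log_with_zero_offset_rule(self):
        y = np.array([0.0, 2.0, 4.0])
        out, meta = transform_response(y, "log")
        assert meta["offset"] == 1.0  # half the smallest positive value
        assert out == pytest.approx(np.log(y + 1.0))

    def test_none_is_identity(self):
        y = np.array([1.0, -2.0])
        out, meta = transform_response(y, "none")
        assert out == pytest.approx(y)
        assert meta["transformation"] == "none"
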