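"""Correlation inference and line comparisons.

Phenotypic correlations: Spearman's rank rho between individual-level
predictors (and fitness traits), with percentile bootstrap 95% CIs over
resampled pairs and Benjamini-Hochberg FDR within each table family.
Genetic correlations: the same machinery applied to line-level predictors
(24 isogenic lines).  Line comparisons: mixed model with line fixed and
individual/subline/session random, Tukey-style single-step all-pairs
contrasts, summarized as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr, studentized_range
from statsmodels.stats.multitest import multipletests

from trichopheno.errors import DegenerateInputError, FitError
from trichopheno.varcomp import INDIVIDUAL, ModelSpec, fit_random_intercepts


@dataclass
class CorrelationEstimate:
    """Spearman rho with percentile-bootstrap CI and (adjusted) p-values."""

    pair: tuple
    rho: float
    ci_low: float
    ci_high: float
    p_raw: float
    n: int
    n_boot: int
    seed: int
    p_adj: float = np.nan

    @property
    def significant_ci(self) -> bool:
        return bool(self.ci_low > 0 or self.ci_high < 0)


def spearman_ci(x, y, n_boot: int = 1000, seed: int = 0,
                pair: tuple = ("x", "y")) -> CorrelationEstimate:
    """Average-rank Spearman rho with a percentile bootstrap 95% CI.

    Pairs with a missing value are dropped; needs >= 5 complete pairs and
    non-constant margins.  The bootstrap p-value is the smallest level (on a
    grid of 999 quantile levels) at which the percentile CI excludes zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise DegenerateInputError(f"need >= 5 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant vector: Spearman rho undefined")
    rho = float(spearmanr(x, y).statistic)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bx = rankdata(x[idx], axis=1)
    by = rankdata(y[idx], axis=1)
    bx = bx - bx.mean(axis=1, keepdims=True)
    by = by - by.mean(axis=1, keepdims=True)
    denom = np.sqrt((bx * bx).sum(axis=1) * (by * by).sum(axis=1))
    boots = np.where(denom > 0, (bx * by).sum(axis=1) / np.where(denom > 0, denom, 1.0), np.nan)
    boots = boots[np.isfinite(boots)]
    if len(boots) == 0:
        lo = hi = np.nan
        p = np.nan
    else:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        # smallest alpha on the 999-level grid whose percentile CI excludes 0
        below = np.mean(boots <= 0)
        above = np.mean(boots >= 0)
        p = float(np.ceil(2 * min(below, above) * 1000) / 1000)
        p = min(max(p, 1.0 / 1000), 1.0)
    return CorrelationEstimate(pair=tuple(pair), rho=rho, ci_low=float(lo),
                               ci_high=float(hi), p_raw=p, n=n,
                               n_boot=n_boot, seed=seed)


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def correlation_table(traits: dict, pairs: list | None = None, n_boot: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """All requested pairwise Spearman correlations within one test family.

    ``traits`` maps name -> per-unit value Series indexed by unit id
    (individual or line); values are aligned on the index per pair.  FDR is
    applied within the family (one family per published-table analogue,
    never pooled).  Per-pair failures (too few pairs, constant margin) yield
    NaN rows rather than aborting the table.
    """
    names = list(traits)
    if pairs is None:
        pairs = list(combinations(names, 2))
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        sub_seed = int(rng.integers(2**31))
        sa, sb = pd.Series(traits[a]), pd.Series(traits[b])
        joined = pd.concat([sa, sb], axis=1, join="inner").dropna()
        try:
            est = spearman_ci(joined.iloc[:, 0], joined.iloc[:, 1],
                              n_boot=n_boot, seed=sub_seed, pair=(a, b))
            rows.append({"trait_a": a, "trait_b": b, "rho": est.rho,
                         "ci_low": est.ci_low, "ci_high": est.ci_high,
                         "significant_ci": est.significant_ci,
                         "p_raw": est.p_raw, "n": est.n, "seed": sub_seed})
        except DegenerateInputError:
            rows.append({"trait_a": a, "trait_b": b, "rho": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "significant_ci": False, "p_raw": np.nan,
                         "n": len(joined), "seed": sub_seed})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = adjust_fdr(out.loc[ok, "p_raw"].to_numpy())
    out["significant_adj"] = out["p_adj"] < 0.05
    return out


# ---------------------------------------------------------------------------
# line comparison with compact letter display


@dataclass
class LineComparison:
    """Fixed-line mixed-model comparison of all line pairs."""

    estimates: pd.Series          # line -> adjusted mean
    pairwise: pd.DataFrame        # line_a, line_b, estimate, t, p_adj
    letters: dict                 # line -> letter string
    alpha: float


def _letter_display(levels: list, significant: dict) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant[(a, b)]`` is True when a and b differ.  Invariant: two
    levels share a letter iff their comparison is non-significant.
    """
    groups = [set(levels)]
    for a, b in combinations(levels, 2):
        if not significant.get((a, b), False):
            continue
        for g in list(groups):
            if a in g and b in g:
                groups.remove(g)
                ga, gb = g - {b}, g - {a}
                for cand in (ga, gb):
                    if not any(cand <= other for other in groups):
                        groups.append(cand)
    groups.sort(key=lambda g: sorted(levels.index(v) for v in g))
    letters = {lv: "" for lv in levels}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i) if i < 26 else f"({i})"
        for lv in g:
            letters[lv] += ch
    # hard verification of the defining invariant
    for a, b in combinations(levels, 2):
        shared = set(letters[a]) & set(letters[b])
        if significant.get((a, b), False) == bool(shared):
            raise AssertionError("letter display violates the shared-letter invariant")
    return letters


def compare_lines(scores: pd.DataFrame, design: pd.DataFrame, response: str = "pc1",
                  alpha: float = 0.05) -> LineComparison:
    """Line differences in a personality score.

    Fits the mixed model with line as a fixed effect (cell means) and
    individual, subline and session as random effects, then tests all line
    pairs with a single-step max-|t| adjustment using the studentized-range
    distribution (residual degrees of freedom from the fixed-effect fit),
    and summarizes the result as a compact letter display.
    """
    data = scores.merge(design[["individual_id", "line", "subline", "session"]]
                        .drop_duplicates("individual_id"), on="individual_id")
    data = data.rename(columns={"individual_id": INDIVIDUAL})
    lines = sorted(data["line"].unique())
    if len(lines) < 2:
        raise FitError("need at least 2 lines")
    counts = data.groupby("line")[INDIVIDUAL].nunique()
    if (counts < 2).any():
        raise FitError(f"line(s) {list(counts[counts < 2].index)} have < 2 individuals")
    spec = ModelSpec(response, (INDIVIDUAL, "subline", "session"))
    vc = fit_random_intercepts(data, spec, fixed="line")
    if not vc.converged:
        raise FitError("line-comparison model did not converge")
    beta = vc.fixed_effects
    model = vc._state
    # Cov(beta) = (X' V^-1 X)^-1 with V in absolute (variance) units
    cov = np.linalg.inv(vc._aux["XtViX"])
    k = len(lines)
    df = max(vc.n_obs - k, 1)
    rows = []
    sig = {}
    for i, j in combinations(range(k), 2):
        diff = beta[i] - beta[j]
        se = np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
        tstat = diff / se
        p = float(studentized_range.sf(np.sqrt(2.0) * abs(tstat), k, df))
        a, b = lines[i], lines[j]
        rows.append({"line_a": a, "line_b": b, "estimate": float(diff),
                     "t": float(tstat), "p_adj": p})
        sig[(a, b)] = p < alpha
    letters = _letter_display(lines, sig)
    est = pd.Series(beta, index=pd.Index(vc.fixed_levels, name="line"), name="estimate")
    return LineComparison(estimates=est, pairwise=pd.DataFrame(rows),
                          letters=letters, alpha=alpha)
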