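"""Personality scores: standardized PCA over the repeatable behavioural
variables.

Observations are individual x day rows (both days enter the PCA when
available, complete cases only).  The decomposition is of the correlation
matrix, so eigenvalues sum to the number of variables.  Axis orientation is
fixed by convention: PC1 is the exploration score (explored-area rate loads
positively), PC2 the activity score (mean speed loads positively).

``loadings`` holds the orthonormal eigenvectors (scores are standardized
rows times loadings); ``variable_correlations`` = loadings * sqrt(eigenvalue)
gives the variable-component correlations usually printed in tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trichopheno.errors import DegenerateInputError, FitError


def select_repeatable(repeatability: dict) -> list:
    """Variables whose repeatability CI excludes zero (lower bound > 0 after
    rounding to the 2 decimals used in summary tables)."""
    kept = [name for name, est in repeatability.items() if est.significant]
    return kept


@dataclass
class PcaModel:
    """Standardized PCA of the repeatable behavioural variables."""

    variables: list
    loadings: np.ndarray        # (n_vars, K) orthonormal eigenvectors
    eigenvalues: np.ndarray     # (K,), non-increasing, sum = n_vars
    center: np.ndarray
    scale: np.ndarray

    @property
    def pct_variance(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / len(self.variables)

    @property
    def variable_correlations(self) -> np.ndarray:
        """Correlation of each variable with each component (table scale)."""
        return self.loadings * np.sqrt(self.eigenvalues)

    def to_json_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "pct_variance": self.pct_variance.tolist(),
            "variable_correlations": self.variable_correlations.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
        }


@dataclass
class PersonalityScores:
    """PC1/PC2 scores per observation (individual x day) and per individual
    (day-averaged)."""

    observation_scores: pd.DataFrame   # columns individual_id, day, pc1, pc2
    individual_scores: pd.DataFrame    # columns individual_id, pc1, pc2


def fit_pca(observations: pd.DataFrame, variables: list, standardize: bool = True) -> PcaModel:
    """Eigendecomposition of the correlation matrix of complete-case rows.

    ``observations`` has one row per individual x day with the variable
    columns; rows with any missing selected variable are excluded.
    """
    if not standardize:
        raise FitError("only correlation-matrix (standardized) PCA is supported")
    data = observations[list(variables)].dropna()
    if len(data) < 2:
        raise DegenerateInputError("need at least 2 complete observations")
    mat = data.to_numpy(dtype=float)
    center = mat.mean(axis=0)
    scale = mat.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = [v for v, s in zip(variables, scale) if s == 0]
        raise FitError(f"constant variable(s) {bad}: zero variance")
    z = (mat - center) / scale
    corr = (z.T @ z) / (len(z) - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    return PcaModel(variables=list(variables), loadings=evecs[:, order],
                    eigenvalues=np.clip(evals[order], 0.0, None),
                    center=center, scale=scale)


def orient_axes(model: PcaModel, pc1_positive: str = "area_rate",
                pc2_positive: str = "mean_speed") -> PcaModel:
    """Fix component signs: exploration axis has the explored-area rate
    loading positively, activity axis has mean speed loading positively.
    Idempotent; never changes eigenvalues."""
    loadings = model.loadings.copy()
    for k, var in enumerate((pc1_positive, pc2_positive)):
        if k >= loadings.shape[1] or var not in model.variables:
            continue
        i = model.variables.index(var)
        if loadings[i, k] < 0:
            loadings[:, k] = -loadings[:, k]
    return PcaModel(variables=model.variables, loadings=loadings,
                    eigenvalues=model.eigenvalues, center=model.center,
                    scale=model.scale)


def score_individuals(model: PcaModel, observations: pd.DataFrame) -> PersonalityScores:
    """Project observations on the first two axes and average per individual.

    Observation score = standardized row . loading vector; observations with
    any missing selected variable get no score.  Individual scores are the
    mean over that individual's scored days.
    """
    cols = list(model.variables)
    complete = observations.dropna(subset=cols)
    z = (complete[cols].to_numpy(dtype=float) - model.center) / model.scale
    proj = z @ model.loadings[:, :2]
    obs = pd.DataFrame({
        "individual_id": complete["individual_id"].to_numpy(),
        "day": complete["day"].to_numpy(),
        "pc1": proj[:, 0],
        "pc2": proj[:, 1],
    })
    ind = (obs.groupby("individual_id", as_index=False)[["pc1", "pc2"]].mean())
    return PersonalityScores(observation_scores=obs, individual_scores=ind)
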