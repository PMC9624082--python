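"""End-to-end orchestration: simulate / extract / model / summarize.

Stages (each also usable on its own, and each writing a CSV/JSON artifact
analogous to one of the published tables):

1. simulate   - synthetic experiment (design, latents, trajectories, fitness)
2. extract    - trajectories -> cleaned, zone-annotated -> behavioural records
3. repeatability - two-factor REML per variable, bootstrap CI (Table-1 analogue)
4. scores     - PCA personality scores over the repeatable variables
5. correlate  - phenotypic correlation families (Table-2/4 analogues)
6. heritability - four-factor REML per trait (Table-5 analogue)
7. genetic    - line-level predictor correlations (Table-6 analogue)
8. compare-lines - fixed-line model + compact letter display

All behavioural variables are modelled on a natural-log scale except the
explored-area rate; the censored time-to-dark variable enters at the trial
duration (higher = less bold) and is dropped after its repeatability test
when not significantly repeatable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from trichopheno import synthdata
from trichopheno.ethometrics import VARIABLES, EthoParams, compute_record
from trichopheno.geometry import annotate
from trichopheno.inference import compare_lines, correlation_table
from trichopheno.scoring import fit_pca, orient_axes, score_individuals, select_repeatable
from trichopheno.trajio import ArenaConfig, clean_trajectory
from trichopheno.varcomp import (INDIVIDUAL, ModelSpec, bootstrap_ci, extract_blups,
                                 fit_random_intercepts)

#: modelling transformation per behavioural variable (log everywhere except
#: the explored-area rate)
TRANSFORMS = {v: ("none" if v == "area_rate" else "log") for v in VARIABLES}
FITNESS_TRAITS = ("offspring", "longevity", "tibia")
REPEATABILITY_FACTORS = (INDIVIDUAL, "session")
HERITABILITY_FACTORS = ("line", "subline", INDIVIDUAL, "session")

def _model_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Model-facing view: the ``individual_id`` key becomes the ``individual``
    random factor column expected by :mod:`trichopheno.varcomp`."""
    return df.rename(columns={"individual_id": INDIVIDUAL})



@dataclass
class PipelineConfig:
    """Everything the pipeline needs; seed is mandatory for stochastic stages."""

    out_dir: str = "results"
    seed: int = 0
    n_boot: int = 1000
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    etho: EthoParams = field(default_factory=EthoParams)
    max_speed: float = 30.0     # cleaning: cm/s
    max_gap: int = 5            # cleaning: frames
    # simulate stage
    n_lines: int = 24
    n_sublines: int = 2
    n_sessions: int = 17
    n_per_line_session: int = 3
    dropout: float = 0.0
    duration: float = 90.0
    fps: float = 25.0


def simulate_experiment(config: PipelineConfig, truth: synthdata.SyntheticTruth | None = None):
    """Design, latents, trajectories and fitness traits of one synthetic
    experiment under the default (study-calibrated) truth."""
    if truth is None:
        truth = synthdata.SyntheticTruth(master_seed=config.seed)
    design = synthdata.generate_design(config.n_lines, config.n_sublines,
                                       config.n_sessions, config.n_per_line_session,
                                       dropout=config.dropout, seed=truth.master_seed)
    latents = synthdata.generate_latents(design, truth)
    trajectories = synthdata.generate_trajectories(design, latents, truth,
                                                   arena=config.arena,
                                                   duration=config.duration,
                                                   fps=config.fps)
    fitness = synthdata.generate_fitness(latents, truth)
    return truth, design, latents, trajectories, fitness


def extract_records(trajectories, design: pd.DataFrame,
                    config: PipelineConfig) -> pd.DataFrame:
    """Clean, annotate and measure every trajectory; one row per trial."""
    rows = []
    for traj in trajectories:
        cleaned = clean_trajectory(traj, config.max_speed, config.max_gap)
        rec = compute_record(annotate(cleaned, config.arena), config.etho)
        rows.append(rec.as_dict())
    records = pd.DataFrame(rows)
    keys = design[["individual_id", "line", "subline", "session"]].drop_duplicates("individual_id")
    return records.merge(keys, on="individual_id", how="left")


def repeatability_table(records: pd.DataFrame, n_boot: int, seed: int) -> tuple[pd.DataFrame, dict]:
    """Repeatability (individual-level ICC) of each behavioural variable from
    the two-factor {individual, session} model, with bootstrap CIs."""
    rng = np.random.default_rng(seed)
    rows, estimates = [], {}
    # bootstrap data are simulated from the full four-factor model (when the
    # design columns are present) so that CIs see the line-level dependence
    # the two-factor repeatability model folds into the individual effect
    rich = all(c in records.columns for c in HERITABILITY_FACTORS)
    for var in VARIABLES:
        spec = ModelSpec(var, REPEATABILITY_FACTORS, TRANSFORMS[var])
        sim_spec = ModelSpec(var, HERITABILITY_FACTORS, TRANSFORMS[var]) if rich else None
        est = bootstrap_ci(_model_frame(records), spec, INDIVIDUAL, n_boot=n_boot,
                           seed=int(rng.integers(2**31)), sim_spec=sim_spec)
        estimates[var] = est
        rows.append({"variable": var, "R": est.point, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "significant": est.significant,
                     "n_boot": est.n_boot, "seed": est.seed})
    return pd.DataFrame(rows), estimates


def personality_scores(records: pd.DataFrame, selected: list):
    """Transformed-scale PCA over the repeatable variables; observation
    (individual x day) and day-averaged individual scores."""
    from trichopheno.varcomp import transform_response

    if len(selected) < 2:
        from trichopheno.errors import FitError
        raise FitError(f"need >= 2 repeatable variables for personality scores, "
                       f"got {selected}")
    obs = records[["individual_id", "day"] + list(selected)].copy()
    for var in selected:
        obs[var], _ = transform_response(obs[var].to_numpy(), TRANSFORMS[var])
    model = orient_axes(fit_pca(obs, selected))
    scores = score_individuals(model, obs)
    return model, scores


def heritability_table(records: pd.DataFrame, fitness: pd.DataFrame,
                       scores_obs: pd.DataFrame | None, n_boot: int,
                       seed: int) -> tuple[pd.DataFrame, dict]:
    """Broad-sense heritability (line-level share) per trait.

    Behavioural variables and scores use the four-factor model; fitness
    traits, measured once per female, use {line, subline, session} (the
    individual effect is then not separable from the residual).
    """
    rng = np.random.default_rng(seed)
    rows, estimates = [], {}

    def add(name, data, factors, transform):
        spec = ModelSpec(name, factors, transform)
        est = bootstrap_ci(_model_frame(data), spec, "line", n_boot=n_boot,
                           seed=int(rng.integers(2**31)))
        estimates[name] = est
        rows.append({"trait": name, "H2": est.point, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "significant": est.significant,
                     "n_boot": est.n_boot, "seed": est.seed})

    for var in VARIABLES:
        add(var, records, HERITABILITY_FACTORS, TRANSFORMS[var])
    if scores_obs is not None:
        keys = records[["individual_id", "line", "subline", "session"]].drop_duplicates("individual_id")
        sc = scores_obs.merge(keys, on="individual_id")
        for pc in ("pc1", "pc2"):
            add(pc, sc, HERITABILITY_FACTORS, "none")
    for trait in FITNESS_TRAITS:
        transform = "log" if trait == "offspring" else "none"
        add(trait, fitness, ("line", "subline", "session"), transform)
    return pd.DataFrame(rows), estimates


def individual_predictors(records: pd.DataFrame, variables: list) -> pd.DataFrame:
    """Individual-level linear predictors (BLUPs of the individual effect)
    from the four-factor model, one column per behavioural variable."""
    out = {}
    for var in variables:
        spec = ModelSpec(var, HERITABILITY_FACTORS, TRANSFORMS[var])
        vc = fit_random_intercepts(_model_frame(records), spec)
        out[var] = extract_blups(vc, INDIVIDUAL).as_series()
    return pd.DataFrame(out)


def line_predictors(records: pd.DataFrame, fitness: pd.DataFrame,
                    scores_obs: pd.DataFrame | None, variables: list) -> pd.DataFrame:
    """Line-level linear predictors (BLUPs of the line effect) per trait."""
    out = {}
    for var in variables:
        spec = ModelSpec(var, HERITABILITY_FACTORS, TRANSFORMS[var])
        vc = fit_random_intercepts(_model_frame(records), spec)
        out[var] = extract_blups(vc, "line").as_series()
    if scores_obs is not None:
        keys = records[["individual_id", "line", "subline", "session"]].drop_duplicates("individual_id")
        sc = scores_obs.merge(keys, on="individual_id")
        for pc in ("pc1", "pc2"):
            vc = fit_random_intercepts(_model_frame(sc), ModelSpec(pc, HERITABILITY_FACTORS))
            out[pc] = extract_blups(vc, "line").as_series()
    for trait in FITNESS_TRAITS:
        transform = "log" if trait == "offspring" else "none"
        vc = fit_random_intercepts(_model_frame(fitness), ModelSpec(trait, ("line", "subline", "session"), transform))
        out[trait] = extract_blups(vc, "line").as_series()
    return pd.DataFrame(out)


def run(config: PipelineConfig, truth: synthdata.SyntheticTruth | None = None,
        records: pd.DataFrame | None = None,
        fitness: pd.DataFrame | None = None) -> dict:
    """Full pipeline; returns the artifact dict and writes CSV/JSON files.

    When ``records`` (and ``fitness``) are given the trajectory stages are
    skipped and the statistical stages run on the provided per-trial table —
    the entry point for data deposited as derived variables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "n_boot": config.n_boot, "stages": [],
                "parameters": {"cleaning": {"max_speed": config.max_speed,
                                            "max_gap": config.max_gap},
                               "ethometrics": asdict(config.etho)}}
    artifacts = {}

    if records is None:
        truth, design, latents, trajectories, fitness = simulate_experiment(config, truth)
        manifest["stages"].append({"stage": "simulate", "seed": truth.master_seed,
                                   "n_individuals": design["individual_id"].nunique(),
                                   "n_trials": len(design)})
        with open(out / "truth.json", "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1)
        design.to_csv(out / "design.csv", index=False)
        records = extract_records(trajectories, design, config)
        manifest["stages"].append({"stage": "extract", "n_records": len(records)})
    records.to_csv(out / "records.csv", index=False)
    artifacts["records"] = records

    rng = np.random.default_rng(config.seed)
    rep_seed, her_seed, cor_seed, gen_seed = (int(rng.integers(2**31)) for _ in range(4))

    rep_table, rep_est = repeatability_table(records, config.n_boot, rep_seed)
    rep_table.to_csv(out / "repeatability.csv", index=False)
    artifacts["repeatability"] = rep_table
    manifest["stages"].append({"stage": "repeatability", "seed": rep_seed})

    selected = select_repeatable(rep_est)
    pca_model, scores = personality_scores(records, selected)
    with open(out / "pca.json", "w") as fh:
        json.dump(pca_model.to_json_dict(), fh, indent=1)
    scores.observation_scores.to_csv(out / "scores.csv", index=False)
    artifacts["pca"] = pca_model
    artifacts["scores"] = scores
    artifacts["selected_variables"] = selected
    manifest["stages"].append({"stage": "scores", "selected": selected})

    # phenotypic correlations: behaviour-behaviour and behaviour-fitness
    blups = individual_predictors(records, selected)
    traits_bb = {v: blups[v] for v in selected}
    table_bb = correlation_table(traits_bb, n_boot=config.n_boot, seed=cor_seed)
    ind_scores = scores.individual_scores.set_index("individual_id")
    traits_bf = dict(traits_bb)
    traits_bf["pc1"] = ind_scores["pc1"]
    traits_bf["pc2"] = ind_scores["pc2"]
    fit_ind = fitness.set_index("individual_id")
    pairs = [(a, f) for a in traits_bf for f in FITNESS_TRAITS]
    for f in FITNESS_TRAITS:
        traits_bf[f] = fit_ind[f]
    table_bf = correlation_table(traits_bf, pairs=pairs, n_boot=config.n_boot,
                                 seed=cor_seed + 1)
    pheno = pd.concat([table_bb.assign(family="behaviour"),
                       table_bf.assign(family="fitness")], ignore_index=True)
    pheno.to_csv(out / "phenotypic_correlations.csv", index=False)
    artifacts["phenotypic_correlations"] = pheno
    manifest["stages"].append({"stage": "correlate", "seed": cor_seed})

    her_table, her_est = heritability_table(records, fitness,
                                            scores.observation_scores,
                                            config.n_boot, her_seed)
    her_table.to_csv(out / "heritability.csv", index=False)
    artifacts["heritability"] = her_table
    manifest["stages"].append({"stage": "heritability", "seed": her_seed})

    lblups = line_predictors(records, fitness, scores.observation_scores, selected)
    gen_traits = {c: lblups[c] for c in lblups.columns}
    gen_pairs = [(a, f) for a in list(selected) + ["pc1", "pc2"] for f in FITNESS_TRAITS]
    gen = correlation_table(gen_traits, pairs=gen_pairs, n_boot=config.n_boot,
                            seed=gen_seed)
    gen.to_csv(out / "genetic_correlations.csv", index=False)
    artifacts["genetic_correlations"] = gen
    artifacts["line_predictors"] = lblups
    manifest["stages"].append({"stage": "genetic", "seed": gen_seed})

    keys = records[["individual_id", "line", "subline", "session"]].drop_duplicates("individual_id")
    letters_rows = []
    for pc in ("pc1", "pc2"):
        cmp_ = compare_lines(scores.observation_scores, keys, response=pc)
        for line, letters in cmp_.letters.items():
            letters_rows.append({"score": pc, "line": line,
                                 "estimate": cmp_.estimates[line], "letters": letters})
        artifacts[f"line_comparison_{pc}"] = cmp_
    pd.DataFrame(letters_rows).to_csv(out / "line_letters.csv", index=False)
    manifest["stages"].append({"stage": "compare-lines"})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    artifacts["manifest"] = manifest
    return artifacts
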