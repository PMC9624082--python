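"""Phenotypic correlations: behavioural syndrome and links to fitness traits.

Uses individual-level linear predictors (BLUPs of the individual effect from
the four-factor model) for the behavioural variables, Spearman rho with
bootstrap 95% CIs, and BH-FDR within each table family (behaviour-behaviour
and behaviour-fitness are separate families).
"""

import argparse
from pathlib import Path

import pandas as pd

from trichopheno.inference import correlation_table
from trichopheno.pipeline import FITNESS_TRAITS, individual_predictors


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--n-boot", type=int, default=1000)
    ap.add_argument("--results-dir", default="results")
    args = ap.parse_args()

    out = Path(args.results_dir)
    records = pd.read_csv(out / "records.csv")
    fitness = pd.read_csv(out / "fitness.csv").set_index("individual_id")
    rep = pd.read_csv(out / "repeatability.csv")
    scores = pd.read_csv(out / "individual_scores.csv").set_index("individual_id")
    selected = rep[rep["significant"]]["variable"].tolist()

    blups = individual_predictors(records, selected)
    bb = correlation_table({v: blups[v] for v in selected},
                           n_boot=args.n_boot, seed=args.seed)

    traits = {v: blups[v] for v in selected}
    traits["pc1"], traits["pc2"] = scores["pc1"], scores["pc2"]
    pairs = [(a, f) for a in traits for f in FITNESS_TRAITS]
    for f in FITNESS_TRAITS:
        traits[f] = fitness[f]
    bf = correlation_table(traits, pairs=pairs, n_boot=args.n_boot, seed=args.seed + 1)

    table = pd.concat([bb.assign(family="behaviour"),
                       bf.assign(family="fitness")], ignore_index=True)
    table.to_csv(out / "phenotypic_correlations.csv", index=False)

    print("behaviour-behaviour correlations (CI excluding 0 marked *):")
    for _, r in bb.iterrows():
        star = "*" if r["significant_ci"] else " "
        print(f"  {r.trait_a:18s} x {r.trait_b:18s} rho={r.rho:+.2f}{star} "
              f"[{r.ci_low:+.2f}, {r.ci_high:+.2f}]")
    sig = bf[bf["significant_adj"]]
    print(f"\n{len(sig)} behaviour-fitness correlations significant after FDR:")
    for _, r in sig.iterrows():
        print(f"  {r.trait_a} x {r.trait_b}: rho={r.rho:+.2f} (p_adj={r.p_adj:.3g})")


if __name__ == "__main__":
    main()
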