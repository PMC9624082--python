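"""Broad-sense heritability from the isogenic-line design.

The line-level variance share of the four-factor model (clonal design:
between-line variance proxies genetic variance) for each behavioural
variable, both personality scores, and the fitness traits, with parametric
bootstrap 95% CIs.
"""

import argparse
from pathlib import Path

import pandas as pd

from trichopheno.pipeline import heritability_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=4)
    ap.add_argument("--n-boot", type=int, default=1000)
    ap.add_argument("--results-dir", default="results")
    args = ap.parse_args()

    out = Path(args.results_dir)
    records = pd.read_csv(out / "records.csv")
    fitness = pd.read_csv(out / "fitness.csv")
    scores = pd.read_csv(out / "scores.csv")

    table, _ = heritability_table(records, fitness, scores, args.n_boot, args.seed)
    table.to_csv(out / "heritability.csv", index=False)
    print(table.round(2).to_string(index=False))
    beh = table[~table["trait"].isin(["offspring", "longevity", "tibia"])]
    print(f"\nbehavioural H2 range: {beh['H2'].min():.2f} to {beh['H2'].max():.2f}")
    fit = table[table["trait"].isin(["offspring", "longevity", "tibia"])]
    print(f"fitness-trait H2 range: {fit['H2'].min():.2f} to {fit['H2'].max():.2f}")


if __name__ == "__main__":
    main()
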