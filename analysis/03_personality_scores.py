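"""Personality scores: standardized PCA over the repeatable variables.

Rows are individual x day observations (complete cases); PC1 is oriented as
the exploration score, PC2 as the activity score.  Writes the PCA model
(eigenvalues, loadings, variable-component correlations) and the observation
and individual scores.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from trichopheno.pipeline import personality_scores


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", default="results")
    args = ap.parse_args()

    out = Path(args.results_dir)
    records = pd.read_csv(out / "records.csv")
    rep = pd.read_csv(out / "repeatability.csv")
    selected = rep[rep["significant"]]["variable"].tolist()

    model, scores = personality_scores(records, selected)
    with open(out / "pca.json", "w") as fh:
        json.dump(model.to_json_dict(), fh, indent=1)
    scores.observation_scores.to_csv(out / "scores.csv", index=False)
    scores.individual_scores.to_csv(out / "individual_scores.csv", index=False)

    pct = model.pct_variance
    print(f"PCA over {selected}")
    print(f"eigenvalues: {model.eigenvalues.round(2).tolist()}")
    print(f"PC1 {pct[0]:.1f}% + PC2 {pct[1]:.1f}% = {pct[:2].sum():.1f}% of variance")
    corr = pd.DataFrame(model.variable_correlations[:, :2],
                        index=model.variables, columns=["PC1", "PC2"])
    print("variable-component correlations:")
    print(corr.round(2).to_string())


if __name__ == "__main__":
    main()
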