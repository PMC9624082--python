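"""Do the isogenic lines differ in personality?

Mixed model with line fixed and individual/subline/session random per
personality score, Tukey-style single-step all-pairs contrasts, compact
letter display (lines sharing a letter do not differ at alpha = 0.05).
"""

import argparse
from pathlib import Path

import pandas as pd

from trichopheno.inference import compare_lines


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", default="results")
    args = ap.parse_args()

    out = Path(args.results_dir)
    scores = pd.read_csv(out / "scores.csv")
    design = pd.read_csv(out / "design.csv")

    rows = []
    for pc, label in (("pc1", "exploration"), ("pc2", "activity")):
        cmp_ = compare_lines(scores, design, response=pc)
        n_sig = int(cmp_.pairwise["p_adj"].lt(0.05).sum())
        print(f"\n{label} score ({pc}): {n_sig} of {len(cmp_.pairwise)} "
              f"line pairs differ (adjusted p < 0.05)")
        order = cmp_.estimates.sort_values()
        for line in order.index:
            rows.append({"score": pc, "line": line,
                         "estimate": cmp_.estimates[line],
                         "letters": cmp_.letters[line]})
            print(f"  line {line:>3}: {cmp_.estimates[line]:+.2f}  {cmp_.letters[line]}")
    pd.DataFrame(rows).to_csv(out / "line_letters.csv", index=False)


if __name__ == "__main__":
    main()
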