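"""Group statistics over the pipeline's apex summary.

One-way ANOVA + Tukey HSD across the stage conditions for each morphometric,
compact letter display, and fold changes relative to the vegetative stage —
the quantitative summary of photoperiod-induced doming.
"""

import argparse
from pathlib import Path

import pandas as pd

from meristemorph.stats import anova_tukey, fold_changes


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--summary", type=Path,
                    default=Path("results/pipeline/apex_summary.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    summary = pd.read_csv(args.summary)
    rows = []
    for metric in ("meristem_area", "cell_number", "median_cell_area"):
        groups = {c: g[metric].to_numpy()
                  for c, g in summary.groupby("condition", sort=False)}
        comp = anova_tukey(groups)
        print(f"\n{metric}: F={comp.f_statistic:.2f} "
              f"(df {comp.df_between},{comp.df_within}) "
              f"p={comp.p_value:.2e}")
        for g, letters in comp.letters.items():
            print(f"  {g:12s} mean={groups[g].mean():9.2f}  [{letters}]")
        for (a, b), (diff, p) in comp.tukey.items():
            rows.append({"metric": metric, "group_a": a, "group_b": b,
                         "difference": diff, "p_adj": p,
                         "letters_a": comp.letters[a],
                         "letters_b": comp.letters[b]})
    pd.DataFrame(rows).to_csv(args.out / "group_comparisons.csv",
                              index=False)

    fc = fold_changes(summary, "vegetative")
    fc.to_csv(args.out / "doming_fold_changes.csv", index=False)
    print("\nfold changes vs vegetative:")
    print(fc.to_string(index=False))


if __name__ == "__main__":
    main()
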