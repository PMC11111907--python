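#!/usr/bin/env python
"""Statistical comparison of mouse-level metrics across panels.

Builds the factorial mouse-level table from the 02 run summaries
(antigen identity x synapse class), runs the two-way ANOVA on
fraction-positive, and a Sidak post-hoc family on the class contrast
within each antigen.  Tables go to results/stats/; the summary figure
goes to scratch/figures/.

Run from the repository root, after 02:  python analysis/04_stats.py
"""

from pathlib import Path

import pandas as pd

from synaptomap.stats_report import anova, plot_group_means, posthoc

RESULTS = Path("results")
RUNS = {
    "shank_like": RESULTS / "runs/molecular_shank_like/mouse_summary.csv",
    "uniform": RESULTS / "runs/molecular_uniform/mouse_summary.csv",
}


def main() -> None:
    frames = []
    for antigen, path in RUNS.items():
        df = pd.read_csv(path)
        df = df[(df.class_label.isin(["PF-PC", "nonPF-PC"])) & (df.subclass.isna())]
        df = df.assign(antigen=antigen)
        frames.append(df[["mouse_id", "antigen", "class_label", "fraction_positive"]])
    table = pd.concat(frames, ignore_index=True)

    out = RESULTS / "stats"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "mouse_table.csv", index=False)

    eff = anova(table, "fraction_positive", ["antigen", "class_label"])
    eff.to_csv(out / "anova_fraction_positive.csv")
    print("Two-way ANOVA on fraction positive (antigen x synapse class):")
    print(eff.to_string())

    ph = posthoc(table, "fraction_positive", "class_label", "sidak")
    ph.to_csv(out / "posthoc_class_sidak.csv", index=False)
    print("\nSidak post-hoc on the class contrast:")
    print(ph.to_string(index=False))

    figdir = Path("scratch/figures")
    figdir.mkdir(parents=True, exist_ok=True)
    plot_group_means(table, "fraction_positive", "class_label", hue="antigen",
                     path=figdir / "fraction_positive_by_class.png")
    print(f"\nfigure -> {figdir / 'fraction_positive_by_class.png'}")


if __name__ == "__main__":
    main()
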