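"""Fixed-effects ANOVA and post-hoc comparisons on mouse-level tables.

A thin layer over statsmodels/scipy reproducing the study's testing
design: one- to three-way ANOVA (Type II sums of squares, so balanced
designs are unaffected and unbalanced ones remain well-defined) with
Tukey, Sidak, or Dunnett post-hoc families.  Inputs are tidy tables with
one row per mouse-level observation.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

POSTHOC_METHODS = ("tukey", "sidak", "dunnett")


def _check_table(table: pd.DataFrame, response: str, factors: Sequence[str]) -> None:
    if not 1 <= len(factors) <= 3:
        raise ValueError("between one and three factors are supported")
    missing = [c for c in (response, *factors) if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if not np.isfinite(table[response].to_numpy(dtype=float)).all():
        raise ValueError("responses must be finite")
    for f in factors:
        levels = table[f].nunique()
        if levels < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels, found {levels}")


def anova(table: pd.DataFrame, response: str, factors: Sequence[str]) -> pd.DataFrame:
    """N-way fixed-effects ANOVA; returns sum_sq, df, F and p per term.

    All main effects and interactions of the given factors are included
    (full factorial model); Type II sums of squares.
    """
    _check_table(table, response, factors)
    clean = table.rename(columns={response: "_y", **{f: f"_f{i}" for i, f in enumerate(factors)}})
    rhs = "*".join(f"C(_f{i})" for i in range(len(factors)))
    model = smf.ols(f"_y ~ {rhs}", data=clean).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    tab = tab.rename(index=lambda s: _pretty_term(s, factors))
    tab = tab.rename(columns={"PR(>F)": "p"})
    return tab


def _pretty_term(term: str, factors: Sequence[str]) -> str:
    for i, f in enumerate(factors):
        term = term.replace(f"C(_f{i})", f)
    return term


def posthoc(
    table: pd.DataFrame,
    response: str,
    factor: str,
    method: str,
    reference_level: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise post-hoc comparisons on one factor.

    ``tukey``: Tukey's HSD over all pairs.  ``sidak``: all-pairs Welch-free
    t tests with Sidak family correction ``1 - (1 - p)^m``.  ``dunnett``:
    all levels against ``reference_level`` (required), via the exact
    many-to-one Dunnett distribution.

    Returns one row per comparison with raw (where defined) and adjusted
    p-values; adjusted >= raw always.
    """
    _check_table(table, response, [factor])
    if method not in POSTHOC_METHODS:
        raise ValueError(f"method must be one of {POSTHOC_METHODS}, got {method!r}")
    groups = {lvl: sub[response].to_numpy(dtype=float) for lvl, sub in table.groupby(factor)}
    levels = sorted(groups)

    if method == "tukey":
        res = pairwise_tukeyhsd(
            table[response].to_numpy(dtype=float), table[factor].astype(str).to_numpy(), alpha=alpha
        )
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        return pd.DataFrame(
            dict(
                group1=frame["group1"],
                group2=frame["group2"],
                estimate=frame["meandiff"].astype(float),
                p_raw=np.nan,
                p_adj=np.asarray(res.pvalues, dtype=float),
            )
        )

    if method == "sidak":
        pairs = list(combinations(levels, 2))
        m = len(pairs)
        rows = []
        for a, b in pairs:
            t = sps.ttest_ind(groups[a], groups[b])
            p_raw = float(t.pvalue)
            rows.append(
                dict(
                    group1=a,
                    group2=b,
                    estimate=float(np.mean(groups[a]) - np.mean(groups[b])),
                    p_raw=p_raw,
                    p_adj=min(1.0, 1.0 - (1.0 - p_raw) ** m),
                )
            )
        return pd.DataFrame(rows)

    # dunnett
    if reference_level is None:
        raise ValueError("dunnett requires reference_level")
    if reference_level not in groups:
        raise ValueError(f"reference level {reference_level!r} not found in {levels}")
    others = [lvl for lvl in levels if lvl != reference_level]
    res = sps.dunnett(*(groups[lvl] for lvl in others), control=groups[reference_level])
    rows = []
    for lvl, p_adj in zip(others, res.pvalue):
        p_raw = float(sps.ttest_ind(groups[lvl], groups[reference_level]).pvalue)
        rows.append(
            dict(
                group1=lvl,
                group2=reference_level,
                estimate=float(np.mean(groups[lvl]) - np.mean(groups[reference_level])),
                p_raw=p_raw,
                p_adj=max(float(p_adj), p_raw),
            )
        )
    return pd.DataFrame(rows)


def plot_group_means(
    table: pd.DataFrame,
    response: str,
    factor: str,
    hue: str | None = None,
    path: str | Path | None = None,
):
    """Mean +- SD summary plot with individual mouse-level points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    hues = sorted(table[hue].unique()) if hue else [None]
    width = 0.8 / len(hues)
    levels = sorted(table[factor].unique())
    for k, h in enumerate(hues):
        sub = table if h is None else table[table[hue] == h]
        means = [sub.loc[sub[factor] == lvl, response].mean() for lvl in levels]
        sds = [sub.loc[sub[factor] == lvl, response].std() for lvl in levels]
        xs = np.arange(len(levels)) + (k - (len(hues) - 1) / 2) * width
        ax.bar(xs, means, width=width * 0.9, yerr=sds, capsize=3,
               label=None if h is None else str(h))
        for x, lvl in zip(xs, levels):
            pts = sub.loc[sub[factor] == lvl, response]
            ax.plot(np.full(len(pts), x), pts, "ko", ms=3, alpha=0.6)
    ax.set_xticks(np.arange(len(levels)))
    ax.set_xticklabels(levels, rotation=30, ha="right")
    ax.set_ylabel(response)
    if hue:
        ax.legend(title=hue)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
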