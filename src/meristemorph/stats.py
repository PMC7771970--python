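"""Group statistics in the reporting style of meristem morphometrics papers.

One-way ANOVA across combined genotype×condition groups, Tukey HSD pairwise
comparisons (Tukey–Kramer for unbalanced designs, adjusted p from the
studentized-range distribution), a compact letter display ("letters a–f";
groups sharing a letter are not significantly different), and fold-change
summaries relative to a baseline condition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "anova_tukey", "letter_display", "fold_changes"]


@dataclass
class GroupComparison:
    """ANOVA + Tukey HSD over labeled samples of one scalar morphometric."""

    groups: dict[str, np.ndarray]
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    tukey: dict[tuple[str, str], tuple[float, float]]  # (difference, adj p)
    letters: dict[str, str]
    alpha: float = 0.05
    degenerate: bool = False   # zero within-group variance

    def pair_p(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.tukey else (b, a)
        return self.tukey[key][1]


def anova_tukey(groups: dict[str, "np.ndarray | list"],
                alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA followed by Tukey's HSD test.

    Adjusted p-values come from the studentized-range distribution with the
    Tukey–Kramer standard error, so balanced and unbalanced designs are both
    supported.  With zero within-group variance the comparison is flagged
    degenerate: separated means get p = 0, identical means p = 1.
    """
    names = list(groups)
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for k, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    k = len(names)
    ns = {g: len(data[g]) for g in names}
    n_tot = sum(ns.values())
    means = {g: data[g].mean() for g in names}
    grand = np.concatenate(list(data.values())).mean()
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in names)
    ss_within = sum(((data[g] - means[g]) ** 2).sum() for g in names)
    df_b, df_w = k - 1, n_tot - k
    degenerate = ss_within <= 1e-12 * max(ss_between, 1.0)

    tukey: dict[tuple[str, str], tuple[float, float]] = {}
    if degenerate:
        f_stat = 0.0 if ss_between <= 1e-12 else float("inf")
        p_val = 1.0 if ss_between <= 1e-12 else 0.0
        for a, b in itertools.combinations(names, 2):
            diff = means[a] - means[b]
            tukey[(a, b)] = (diff, 1.0 if abs(diff) <= 1e-12 else 0.0)
    else:
        ms_b = ss_between / df_b
        ms_w = ss_within / df_w
        f_stat = ms_b / ms_w
        p_val = float(sps.f.sf(f_stat, df_b, df_w))
        for a, b in itertools.combinations(names, 2):
            diff = means[a] - means[b]
            se = np.sqrt(ms_w / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se
            tukey[(a, b)] = (diff, float(sps.studentized_range.sf(q, k, df_w)))

    comp = GroupComparison(
        groups=data, f_statistic=float(f_stat), p_value=float(p_val),
        df_between=df_b, df_within=df_w, tukey=tukey, letters={},
        alpha=alpha, degenerate=bool(degenerate))
    comp.letters = letter_display(comp)
    return comp


def letter_display(comparison: GroupComparison) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Start with one letter containing every group; for each significant pair,
    split any letter containing both; absorb letters that became subsets of
    another.  The result satisfies: two groups share at least one letter iff
    their adjusted p >= alpha, and every group carries >= 1 letter.
    """
    names = list(comparison.groups)
    alpha = comparison.alpha
    letters: list[set[str]] = [set(names)]
    for a, b in itertools.combinations(names, 2):
        if comparison.pair_p(a, b) >= alpha:
            continue
        nxt: list[set[str]] = []
        for L in letters:
            if a in L and b in L:
                nxt.append(L - {a})
                nxt.append(L - {b})
            else:
                nxt.append(L)
        # absorb: drop any letter contained in another
        nxt.sort(key=len, reverse=True)
        kept: list[set[str]] = []
        for L in nxt:
            if L and not any(L <= K for K in kept):
                kept.append(L)
        letters = kept
    # name letters 'a', 'b', ... by the first (group-order) member
    order = {g: i for i, g in enumerate(names)}
    letters.sort(key=lambda L: min(order[g] for g in L))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for i, L in enumerate(letters):
        for g in names:
            if g in L:
                out[g] += alphabet[i % len(alphabet)]
    return out


def fold_changes(records: pd.DataFrame, baseline: str,
                 condition_col: str = "condition") -> pd.DataFrame:
    """Per-condition ratios to a baseline condition.

    ``records`` needs one row per apex with columns ``condition``,
    ``meristem_area``, ``cell_number`` and ``median_cell_area``.  Ratios are
    of group means (median cell area reported additionally as percent
    change); per-apex values stay available in ``records`` itself.
    """
    if baseline not in set(records[condition_col]):
        raise ValueError(f"baseline condition {baseline!r} not present")
    base = records[records[condition_col] == baseline]
    rows = []
    for cond, grp in records.groupby(condition_col, sort=False):
        rows.append({
            condition_col: cond,
            "n_apices": len(grp),
            "meristem_area_ratio":
                grp["meristem_area"].mean() / base["meristem_area"].mean(),
            "cell_number_ratio":
                grp["cell_number"].mean() / base["cell_number"].mean(),
            "median_cell_area_ratio":
                grp["median_cell_area"].mean()
                / base["median_cell_area"].mean(),
            "median_cell_area_pct_change":
                100.0 * (grp["median_cell_area"].mean()
                         / base["median_cell_area"].mean() - 1.0),
        })
    return pd.DataFrame(rows)
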