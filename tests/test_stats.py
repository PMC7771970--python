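"""ANOVA / Tukey HSD, compact letter display, and fold changes."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.integrate import quad

from meristemorph.stats import (GroupComparison, anova_tukey, fold_changes,
                                letter_display)


def studentized_range_sf_oracle(q, k, df):
    """P(Q > q) by direct double quadrature of the classical formula.

    F(q) = ∫ f_s(s) · k ∫ φ(z) [Φ(z) − Φ(z − q·s)]^(k−1) dz ds where s is
    distributed as sqrt(chi²_df / df).  Independent of scipy's internal
    studentized-range implementation.
    """
    def inner(s):
        def f(z):
            return sps.norm.pdf(z) * (
                sps.norm.cdf(z) - sps.norm.cdf(z - q * s)) ** (k - 1)
        return k * quad(f, -8, 8, limit=200)[0]

    def chi_scaled_pdf(s):
        # density of sqrt(chi2_df/df)
        return (2 * (df / 2.0) ** (df / 2.0) / math.gamma(df / 2.0)
                * s ** (df - 1) * np.exp(-df * s * s / 2.0))

    cdf = quad(lambda s: chi_scaled_pdf(s) * inner(s), 1e-6, 8,
               limit=200)[0]
    return 1.0 - cdf


class TestAnovaTukey:
    def test_identical_groups_f_zero_p_one(self):
        c = anova_tukey({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert c.f_statistic == 0.0
        assert all(p == pytest.approx(1.0) for _, p in c.tukey.values())
        assert set(c.letters.values()) == {"a"}

    def test_fully_separated_groups(self):
        c = anova_tukey({"lo": [1, 2, 3], "hi": [101, 102, 103]})
        assert c.pair_p("lo", "hi") < 1e-6
        assert c.letters["lo"] != c.letters["hi"]

    def test_adjusted_p_matches_quadrature_oracle(self):
        """Three groups, n = 4 each, vs the double-quadrature oracle."""
        groups = {"g1": [5.1, 4.9, 5.3, 5.0],
                  "g2": [5.6, 5.8, 5.5, 5.9],
                  "g3": [5.2, 5.4, 5.1, 5.5]}
        c = anova_tukey(groups)
        data = {g: np.asarray(v, float) for g, v in groups.items()}
        ms_w = sum(((v - v.mean()) ** 2).sum()
                   for v in data.values()) / c.df_within
        for (a, b), (diff, p) in c.tukey.items():
            q = abs(diff) / np.sqrt(ms_w / 4.0)
            oracle = studentized_range_sf_oracle(q, 3, c.df_within)
            assert p == pytest.approx(oracle, abs=1e-4)

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(i * 0.5, 1, 6) for i in range(4)}
        c = anova_tukey(groups)
        ref = sps.tukey_hsd(*groups.values())
        names = list(groups)
        for (a, b), (_, p) in c.tukey.items():
            i, j = names.index(a), names.index(b)
            assert p == pytest.approx(ref.pvalue[i, j], abs=1e-9)

    def test_unbalanced_design_supported(self):
        rng = np.random.default_rng(4)
        c = anova_tukey({"a": rng.normal(0, 1, 3),
                         "b": rng.normal(0, 1, 7),
                         "c": rng.normal(3, 1, 5)})
        assert c.pair_p("a", "c") < 0.05
        assert 0 <= c.pair_p("a", "b") <= 1

    def test_zero_variance_degenerate_flag(self):
        c = anova_tukey({"a": [2.0, 2.0], "b": [5.0, 5.0]})
        assert c.degenerate
        assert c.pair_p("a", "b") == 0.0

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0], "b": [1, 2, 3]})

    def test_anova_type_I_error_calibrated(self):
        """Null rejection rate at α=0.05 within [0.03, 0.07] (1000 sims)."""
        rng = np.random.default_rng(123)
        k, n, reps = 4, 5, 1000
        x = rng.normal(0, 1, (reps, k, n))
        gm = x.mean(axis=2)
        grand = x.mean(axis=(1, 2))
        ssb = n * ((gm - grand[:, None]) ** 2).sum(axis=1)
        ssw = ((x - gm[..., None]) ** 2).sum(axis=(1, 2))
        F = (ssb / (k - 1)) / (ssw / (k * n - k))
        crit = sps.f.ppf(0.95, k - 1, k * n - k)
        rate = (F > crit).mean()
        assert 0.03 <= rate <= 0.07

    def test_tukey_familywise_error_controlled(self):
        """Fraction of null sims with >=1 significant pair <= 0.07."""
        rng = np.random.default_rng(321)
        k, n, reps = 4, 5, 1000
        x = rng.normal(0, 1, (reps, k, n))
        gm = x.mean(axis=2)
        ssw = ((x - gm[..., None]) ** 2).sum(axis=(1, 2))
        ms_w = ssw / (k * n - k)
        spread = gm.max(axis=1) - gm.min(axis=1)
        qmax = spread / np.sqrt(ms_w / n)
        qcrit = sps.studentized_range.ppf(0.95, k, k * n - k)
        assert (qmax > qcrit).mean() <= 0.07


def _stub_comparison(names, pmat, alpha=0.05):
    tukey = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        tukey[(names[i], names[j])] = (0.0, pmat[i][j])
    return GroupComparison(
        groups={n: np.zeros(2) for n in names}, f_statistic=0.0,
        p_value=1.0, df_between=1, df_within=1, tukey=tukey, letters={},
        alpha=alpha)


class TestLetterDisplay:
    def test_all_nonsignificant_single_letter(self):
        c = _stub_comparison(["a", "b", "c"],
                             [[1, 0.9, 0.9], [0, 1, 0.9], [0, 0, 1]])
        assert set(letter_display(c).values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        p = [[1, 0.001, 0.001, 0.001], [0, 1, 0.001, 0.001],
             [0, 0, 1, 0.001], [0, 0, 0, 1]]
        c = _stub_comparison(list("wxyz"), p)
        out = letter_display(c)
        assert sorted(out.values()) == ["a", "b", "c", "d"]

    def test_chain_pattern(self):
        """A≠C significant, A-B and B-C not: A='a', B='ab', C='b'."""
        p = [[1, 0.5, 0.01], [0, 1, 0.5], [0, 0, 1]]
        c = _stub_comparison(["A", "B", "C"], p)
        out = letter_display(c)
        assert out == {"A": "a", "B": "ab", "C": "b"}

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(3, 6), st.integers(0, 10**6))
    def test_share_letter_iff_nonsignificant(self, k, seed):
        """The display contract holds on random p-matrices."""
        rng = np.random.default_rng(seed)
        names = [f"g{i}" for i in range(k)]
        pmat = np.ones((k, k))
        for i, j in itertools.combinations(range(k), 2):
            pmat[i][j] = pmat[j][i] = rng.choice(
                [0.001, 0.2, 0.9], p=[0.4, 0.3, 0.3])
        c = _stub_comparison(names, pmat)
        out = letter_display(c)
        assert all(out[g] for g in names)
        for i, j in itertools.combinations(range(k), 2):
            share = bool(set(out[names[i]]) & set(out[names[j]]))
            assert share == (pmat[i][j] >= 0.05)


class TestFoldChanges:
    def _records(self):
        return pd.DataFrame({
            "condition": ["veg"] * 3 + ["domed"] * 3,
            "meristem_area": [100, 110, 90, 400, 410, 390],
            "cell_number": [10, 11, 9, 31, 30, 32],
            "median_cell_area": [10.0, 10.5, 9.5, 18.0, 18.5, 17.5],
        })

    def test_baseline_against_itself_is_unity(self):
        fc = fold_changes(self._records(), "veg")
        row = fc[fc["condition"] == "veg"].iloc[0]
        assert row["meristem_area_ratio"] == pytest.approx(1.0)
        assert row["median_cell_area_pct_change"] == pytest.approx(0.0)

    def test_ratios_computed_from_group_means(self):
        fc = fold_changes(self._records(), "veg")
        row = fc[fc["condition"] == "domed"].iloc[0]
        assert row["meristem_area_ratio"] == pytest.approx(4.0)
        assert row["cell_number_ratio"] == pytest.approx(3.1)
        assert row["median_cell_area_pct_change"] == pytest.approx(80.0)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            fold_changes(self._records(), "nonexistent")
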