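"""Statistical machinery, checked against hand-coded oracles."""

import numpy as np
import pandas as pd
import pytest

import mstates as ms


# ---------------------------------------------------------------------------
# Independent within-subject sums-of-squares oracle
# ---------------------------------------------------------------------------

def oracle_rm_anova(y):
    """Two-way within-subject ANOVA from scratch.

    y: (n_subjects, levels_a, levels_b).  Returns dict of (F, df1, df2)
    for 'a', 'b' and 'a:b'.
    """
    n, p, q = y.shape
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    a = y.mean(axis=(0, 2))
    b = y.mean(axis=(0, 1))
    ss_a = n * q * np.sum((a - grand) ** 2)
    ss_b = n * p * np.sum((b - grand) ** 2)
    ab = y.mean(axis=0)
    ss_ab = n * np.sum((ab - a[:, None] - b[None, :] + grand) ** 2)
    sa = y.mean(axis=2)  # subject x a
    ss_err_a = q * np.sum((sa - subj[:, None] - a[None, :] + grand) ** 2)
    sb = y.mean(axis=1)
    ss_err_b = p * np.sum((sb - subj[:, None] - b[None, :] + grand) ** 2)
    ss_err_ab = np.sum(
        (
            y
            - sa[:, :, None]
            - sb[:, None, :]
            - ab[None, :, :]
            + subj[:, None, None]
            + a[None, :, None]
            + b[None, None, :]
            - grand
        )
        ** 2
    )
    out = {}
    for name, ss, df1, ss_err, df2 in (
        ("a", ss_a, p - 1, ss_err_a, (n - 1) * (p - 1)),
        ("b", ss_b, q - 1, ss_err_b, (n - 1) * (q - 1)),
        ("a:b", ss_ab, (p - 1) * (q - 1), ss_err_ab, (n - 1) * (p - 1) * (q - 1)),
    ):
        out[name] = (ss / df1 / (ss_err / df2), df1, df2)
    return out


def _table_from_array(y):
    n, p, q = y.shape
    rows = []
    for s in range(n):
        for i in range(p):
            for j in range(q):
                rows.append(
                    {
                        "subject": s,
                        "class": i,
                        "condition": ["neutral", "fear"][j],
                        "v": y[s, i, j],
                    }
                )
    return pd.DataFrame(rows)


class TestTanova:
    def test_identical_maps_give_null(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 16))
        res = ms.tanova(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_exact_p_for_maximal_separation(self):
        """n=5, b = -a: only the two all-same-sign swaps reach the
        observed statistic, so p = 2/32."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=16)
        a = np.tile(base, (5, 1))
        res = ms.tanova(a, -a)
        assert res.p == pytest.approx(2 / 32)
        assert "exact" in res.method

    def test_exact_agrees_with_monte_carlo(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 16))
        b = a + 0.5 * rng.normal(size=(8, 16))
        p_exact = ms.tanova(a, b).p
        p_mc = ms.tanova(a, b, exact=False, n_perm=10_000, seed=3).p
        assert abs(p_exact - p_mc) < 2 / np.sqrt(10_000)

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 20))
        b = rng.normal(size=(6, 20))
        perm = rng.permutation(20)
        assert ms.tanova(a, b).p == pytest.approx(ms.tanova(a[:, perm], b[:, perm]).p)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            ms.tanova(np.zeros((4, 8)), np.zeros((5, 8)))


class TestRmAnova:
    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(5)
        for n in (3, 4, 6):
            y = rng.normal(size=(n, 4, 2))
            inter, mains = ms.rm_anova_2x4(_table_from_array(y), "v")
            want = oracle_rm_anova(y)
            assert inter.statistic == pytest.approx(want["a:b"][0], abs=1e-9)
            assert inter.df == (want["a:b"][1], want["a:b"][2])
            assert mains["class"].statistic == pytest.approx(want["a"][0], abs=1e-9)
            assert mains["condition"].statistic == pytest.approx(want["b"][0], abs=1e-9)

    def test_targeted_shift_drives_interaction(self):
        rng = np.random.default_rng(6)
        y = 0.05 * rng.normal(size=(8, 4, 2))
        y[:, 2, 1] += 1.0  # one class shifted in one condition only
        inter, _ = ms.rm_anova_2x4(_table_from_array(y), "v")
        from scipy.stats import f as fdist

        crit = fdist.ppf(0.95, *inter.df)
        assert inter.statistic > crit

    def test_null_interaction_p_uniform(self):
        """Under exchangeable noise the interaction p-value is uniform."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            y = rng.normal(size=(6, 4, 2))
            inter, _ = ms.rm_anova_2x4(_table_from_array(y), "v")
            ps.append(inter.p)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_missing_cell_rejected(self):
        y = np.random.default_rng(8).normal(size=(4, 4, 2))
        table = _table_from_array(y).iloc[:-1]
        with pytest.raises(ValueError):
            ms.rm_anova_2x4(table, "v")


class TestPairedT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ms.paired_t(x, x)
        assert res.statistic == 0.0 and res.p == 1.0 and res.effect_size == 0.0

    def test_constant_difference_flagged_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ms.paired_t(x, x + 1.0)
        assert res.extra["degenerate"]
        assert np.isnan(res.statistic)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(2000, 12))
        y = rng.normal(size=(2000, 12))
        from scipy.stats import ttest_rel

        p = ttest_rel(x, y, axis=1).pvalue
        # sanity for the vectorized reference, then our scalar wrapper
        sub = [ms.paired_t(x[i], y[i]).p for i in range(200)]
        assert abs(np.mean(np.array(sub) < 0.05) - 0.05) < 0.05
        rate = np.mean(p < 0.05)
        assert 0.04 < rate < 0.06

    def test_bonferroni_family_flags(self):
        rows = []
        rng = np.random.default_rng(10)
        for s in range(10):
            for cond in ("neutral", "fear"):
                for cls in range(4):
                    v = rng.normal() + (3.0 if (cls == 3 and cond == "fear") else 0.0)
                    rows.append(
                        {"subject": s, "condition": cond, "class": cls,
                         "mean_duration_ms": v, "time_coverage": v}
                    )
        table = pd.DataFrame(rows)
        results = ms.paired_contrasts(table, alpha=0.05)
        assert len(results) == 8
        assert all(r.extra["bonferroni_alpha"] == pytest.approx(0.05 / 8) for r in results)


class TestCorrelationsAndScoring:
    def test_perfect_linear_correlation(self):
        x = np.arange(10.0)
        res = ms.pearson_with_fdr(x, {"y": 2 * x + 3})
        assert res[0].statistic == pytest.approx(1.0)

    def test_bh_stepup_rejects_all_four(self):
        """p = (.01, .02, .03, .04) at alpha .05: BH rejects everything."""
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [0.01, 0.02, 0.03, 0.04], alpha=0.05, method="fdr_bh"
        )
        assert reject.all()
        # and BH never rejects fewer than Bonferroni on the same family
        rng = np.random.default_rng(11)
        for _ in range(50):
            ps = rng.uniform(size=6)
            bh, _, _, _ = multipletests(ps, alpha=0.05, method="fdr_bh")
            bonf = ps < 0.05 / ps.size
            assert bh.sum() >= bonf.sum()

    def test_fdr_on_simulated_family(self):
        rng = np.random.default_rng(12)
        trait = rng.uniform(8, 40, size=36)
        fam = {
            "null": rng.normal(size=36),
            "linked": -0.01 * trait + 0.02 * rng.normal(size=36),
        }
        res = ms.pearson_with_fdr(trait, fam)
        linked = [r for r in res if "linked" in r.name][0]
        assert linked.statistic < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ms.pearson_with_fdr(np.ones(6), {"y": np.arange(6.0)})

    def test_bfi_score_bounds_and_reversal(self):
        assert ms.bfi_neuroticism_score([1] * 8) == 8.0
        assert ms.bfi_neuroticism_score([5] * 8) == 40.0
        assert ms.bfi_neuroticism_score([3] * 8) == 24.0
        assert ms.bfi_neuroticism_score([5] * 8, reverse_keys=[0]) == 36.0
        with pytest.raises(ValueError):
            ms.bfi_neuroticism_score([0] + [3] * 7)
        with pytest.raises(ValueError):
            ms.bfi_neuroticism_score([3] * 7)

    def test_odd_even_reliability(self):
        rng = np.random.default_rng(13)
        half = rng.integers(1, 6, size=(20, 4)).astype(float)
        items = np.empty((20, 8))
        items[:, 0::2] = half
        items[:, 1::2] = half  # duplicated halves
        assert ms.odd_even_reliability(items) == pytest.approx(1.0)

    def test_one_factor_model_near_spearman_brown(self):
        """Items = 0.7*factor + noise: split-half r should approach the
        Spearman-Brown expectation for 4-item halves."""
        rng = np.random.default_rng(14)
        n, items, load = 4000, 8, 0.7
        f = rng.normal(size=(n, 1))
        x = load * f + np.sqrt(1 - load**2) * rng.normal(size=(n, items))
        # correlation between two 4-item sums under the one-factor model
        lam2 = load**2
        r_half = 16 * lam2 / (4 + 12 * lam2)
        got = ms.odd_even_reliability(x)
        assert abs(got - r_half) < 0.05
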