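"""Statistical machinery for the microstate analysis.

* TANOVA — a nonparametric permutation test comparing condition
  topographies: each subject map is L2-normalized, the statistic is the
  global field power of the difference between the two condition grand
  means, and the null swaps condition assignment within subject (exactly
  enumerated for small n, Monte-Carlo otherwise).
* 4 x 2 repeated-measures ANOVA (class x condition) per temporal
  parameter.
* Paired two-tailed t contrasts per class with a Bonferroni family
  threshold; Cohen's d uses the pooled SD of the two condition samples
  (a dz variant is reported alongside).
* Pearson correlations between a trait score and microstate parameters
  with Benjamini-Hochberg FDR across the declared family.
* BFI neuroticism scoring (8 items, 1-5 Likert, reverse keys, range
  8-40) and odd-even split-half reliability.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .containers import TestResult

__all__ = [
    "tanova",
    "rm_anova_2x4",
    "paired_t",
    "paired_contrasts",
    "pearson_with_fdr",
    "bfi_neuroticism_score",
    "odd_even_reliability",
]

#: Subject count at or below which TANOVA enumerates all swaps exactly.
EXACT_TANOVA_MAX_N = 12


def _normalize_rows(maps: np.ndarray) -> np.ndarray:
    m = np.asarray(maps, dtype=float)
    m = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if (norms < 1e-300).any():
        raise ValueError("zero-variance subject map")
    return m / norms


def tanova(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    exact: bool | None = None,
) -> TestResult:
    """Topographic ANOVA for paired condition maps.

    Parameters
    ----------
    maps_a, maps_b
        (n_subjects, n_channels) per-subject topographies, paired by row.
    n_perm
        Monte-Carlo permutation count (ignored in exact mode).
    exact
        Force (True) or forbid (False) exhaustive enumeration of all
        2^n within-subject swaps; by default exact mode is used for
        n_subjects <= 12.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("paired subject maps must share shape (n_subjects, n_channels)")
    n, _ = a.shape
    d = _normalize_rows(a) - _normalize_rows(b)

    def stat(signs: np.ndarray) -> np.ndarray:
        mean_map = (signs @ d) / n  # (m, C)
        return mean_map.std(axis=1, ddof=0)

    observed = float(stat(np.ones((1, n)))[0])
    if exact is None:
        exact = n <= EXACT_TANOVA_MAX_N
    if exact:
        if n > 20:
            raise ValueError("exact enumeration is limited to n <= 20 subjects")
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        signs = 1.0 - 2.0 * bits
        null = stat(signs)
        p = float(np.mean(null >= observed - 1e-12))
        method = f"TANOVA exact ({2**n} swaps)"
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        null = stat(signs)
        p = float((np.sum(null >= observed - 1e-12) + 1) / (n_perm + 1))
        method = f"TANOVA Monte-Carlo ({n_perm} swaps)"
    return TestResult(
        name="tanova",
        statistic=observed,
        df=float(n - 1),
        p=p,
        method=method,
        extra={"n_subjects": n},
    )


def rm_anova_2x4(
    table: pd.DataFrame, parameter: str
) -> tuple[TestResult, dict[str, TestResult]]:
    """Two-way repeated-measures ANOVA (class x condition).

    ``table`` is a tidy frame with columns subject, condition, class and
    the parameter column; the subject x condition x class crossing must
    be complete.  Returns the interaction result plus the two main
    effects, with conventional (uncorrected) degrees of freedom.
    """
    needed = {"subject", "condition", "class", parameter}
    if not needed.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(needed)}")
    df = table[["subject", "condition", "class", parameter]].copy()
    if df[parameter].isna().any():
        raise ValueError("missing values in the parameter column")
    n_subj = df["subject"].nunique()
    if n_subj < 3:
        raise ValueError("repeated-measures ANOVA needs >= 3 subjects")
    cells = df.groupby(["subject", "condition", "class"]).size()
    if (cells != 1).any() or len(cells) != n_subj * df["condition"].nunique() * df["class"].nunique():
        raise ValueError("subject x condition x class crossing must be complete")
    # "class" is a Python keyword, which the formula machinery cannot eat
    df = df.rename(columns={"class": "cls", "condition": "cond", parameter: "y"})
    # compositional parameters (coverage sums to 1) make some main-effect
    # error strata exactly zero; report those F as NaN rather than warn
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = AnovaRM(df, depvar="y", subject="subject", within=["cls", "cond"]).fit()
    tbl = fit.anova_table.rename(
        index={"cls": "class", "cond": "condition", "cls:cond": "class:condition"}
    )

    def res(row_name: str, name: str) -> TestResult:
        row = tbl.loc[row_name]
        return TestResult(
            name=name,
            statistic=float(row["F Value"]),
            df=(float(row["Num DF"]), float(row["Den DF"])),
            p=float(row["Pr > F"]),
            method="repeated-measures ANOVA",
        )

    interaction = res("class:condition", f"interaction[{parameter}]")
    mains = {
        "class": res("class", f"class[{parameter}]"),
        "condition": res("condition", f"condition[{parameter}]"),
    }
    return interaction, mains


def paired_t(x: np.ndarray, y: np.ndarray, name: str = "paired_t") -> TestResult:
    """Two-tailed paired t test with Cohen's d.

    d uses the pooled SD of the two condition samples,
    ``mean(x - y) / sqrt((var(x) + var(y)) / 2)``; the difference-score
    standardization dz is reported in ``extra``.  A constant nonzero
    difference (zero variance of x - y) is flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("paired t needs n >= 3")
    diff = x - y
    sd_diff = diff.std(ddof=1)
    mean_diff = float(diff.mean())
    pooled = float(np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0))
    d = mean_diff / pooled if pooled > 0 else (0.0 if mean_diff == 0 else np.nan)
    if sd_diff == 0:
        if mean_diff == 0:
            return TestResult(
                name=name, statistic=0.0, df=float(n - 1), p=1.0,
                effect_size=0.0, method="paired t (two-tailed)",
                extra={"dz": 0.0, "degenerate": False},
            )
        return TestResult(
            name=name, statistic=np.nan, df=float(n - 1), p=np.nan,
            effect_size=d, method="paired t (two-tailed)",
            extra={"dz": np.nan, "degenerate": True},
        )
    t, p = sstats.ttest_rel(x, y)
    dz = mean_diff / sd_diff
    return TestResult(
        name=name, statistic=float(t), df=float(n - 1), p=float(p),
        effect_size=float(d), method="paired t (two-tailed)",
        extra={"dz": float(dz), "degenerate": False},
    )


def paired_contrasts(
    table: pd.DataFrame,
    parameters: Sequence[str] = ("mean_duration_ms", "time_coverage"),
    conditions: tuple[str, str] = ("neutral", "fear"),
    alpha: float = 0.05,
    family_alpha: float | None = None,
) -> list[TestResult]:
    """Per-class paired contrasts (condition A minus condition B) for each
    parameter, Bonferroni-corrected across the class x parameter family.

    The family threshold defaults to ``alpha / m`` with m the family
    size; ``family_alpha`` overrides it (e.g. a preset 0.003).
    """
    classes = sorted(table["class"].unique())
    m = len(classes) * len(parameters)
    threshold = family_alpha if family_alpha is not None else alpha / m
    results = []
    for param in parameters:
        for cls in classes:
            sub = table[table["class"] == cls]
            wide = sub.pivot(index="subject", columns="condition", values=param)
            x = wide[conditions[0]].to_numpy()
            y = wide[conditions[1]].to_numpy()
            res = paired_t(x, y, name=f"{param}[class {cls}] {conditions[0]} vs {conditions[1]}")
            res.corrected = bool(np.isfinite(res.p) and res.p < threshold)
            res.extra.update(
                {"class": cls, "parameter": param, "bonferroni_alpha": threshold}
            )
            results.append(res)
    return results


def pearson_with_fdr(
    trait: np.ndarray,
    params: Mapping[str, np.ndarray],
    alpha: float = 0.05,
) -> list[TestResult]:
    """Pearson correlations of a per-subject trait with each named
    parameter vector, Benjamini-Hochberg corrected across the family.

    Each result carries the raw p (t-based, two-sided, df = n - 2), the
    BH-adjusted p in ``extra['p_adj']`` and the FDR decision in
    ``corrected``.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.std(ddof=0) == 0:
        raise ValueError("trait scores have zero variance")
    results = []
    for name, vals in params.items():
        v = np.asarray(vals, dtype=float)
        if v.shape != trait.shape:
            raise ValueError(f"{name}: length mismatch with trait")
        if v.size < 4:
            raise ValueError("Pearson correlation needs n >= 4 per test")
        if v.std(ddof=0) == 0:
            raise ValueError(f"{name}: zero-variance values")
        r, p = sstats.pearsonr(trait, v)
        results.append(
            TestResult(
                name=f"pearson[{name}]",
                statistic=float(r),
                df=float(trait.size - 2),
                p=float(p),
                method="Pearson r, BH-FDR",
            )
        )
    reject, p_adj, _, _ = multipletests(
        [r.p for r in results], alpha=alpha, method="fdr_bh"
    )
    for res, rej, pa in zip(results, reject, p_adj):
        res.corrected = bool(rej)
        res.extra["p_adj"] = float(pa)
    return results


def bfi_neuroticism_score(
    items: Sequence[float], reverse_keys: Sequence[int] = ()
) -> float:
    """Score the 8 neuroticism items of the Big Five Inventory.

    Items are Likert responses in [1, 5]; reverse-keyed items (0-based
    indices) map x -> 6 - x before summing.  The score ranges 8-40.
    """
    items = np.asarray(items, dtype=float)
    if items.shape != (8,):
        raise ValueError("exactly 8 item responses required")
    if ((items < 1) | (items > 5)).any():
        raise ValueError("item responses must lie in [1, 5]")
    reverse_keys = list(reverse_keys)
    if any(k < 0 or k > 7 for k in reverse_keys):
        raise ValueError("reverse key index out of range")
    scored = items.copy()
    scored[reverse_keys] = 6.0 - scored[reverse_keys]
    return float(scored.sum())


def odd_even_reliability(item_matrix: np.ndarray) -> float:
    """Odd-even split-half reliability of a subjects x items score matrix:
    the Pearson r between odd-item and even-item sums across subjects."""
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 4:
        raise ValueError("need >= 4 subjects and >= 2 items")
    odd = x[:, 0::2].sum(axis=1)   # items 1, 3, 5, ... (1-based)
    even = x[:, 1::2].sum(axis=1)
    return float(sstats.pearsonr(odd, even)[0])
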