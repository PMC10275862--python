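"""Label-shuffling randomization tests, empirical p-values, FDR, and the
deletion/insertion ratio and length comparisons.

One statistic (a mutation burden or a signature exposure) is observed per
clone. For each pairwise group comparison the observed difference of group
means is ranked against the differences obtained after globally shuffling
the clone labels; both one-sided empirical p-values p = (r+1)/(n+1) are
reported and Benjamini-Hochberg correction is applied within the families
of related comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def empirical_p(r: int, n: int) -> float:
    """p = (r + 1) / (n + 1); never exactly zero."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= r <= n:
        raise ValueError(f"exceedance count r={r} outside [0, {n}]")
    return (r + 1) / (n + 1)


@dataclass
class PermutationResult:
    statistic_name: str
    group_a: str
    group_b: str
    stratification: str       # "pooled" or "<column>=<value>"
    observed_diff: float
    n_iter: int
    r_ge: int
    r_le: int
    p_ge: float
    p_le: float
    q: float | None = None

    @property
    def p_min(self) -> float:
        return min(self.p_ge, self.p_le)


@dataclass(frozen=True)
class Comparison:
    """A pairwise group-mean comparison.

    ``by`` is the label column defining the groups (e.g. "treatment"),
    ``group_a``/``group_b`` its two levels, and ``stratum`` optionally
    restricts the comparison to clones where another column takes a given
    value, e.g. ("cell_line", "HAP1"). Shuffles stay global regardless.
    """

    by: str
    group_a: str
    group_b: str
    stratum: tuple[str, str] | None = None

    @property
    def stratification(self) -> str:
        return "pooled" if self.stratum is None else f"{self.stratum[0]}={self.stratum[1]}"


def _masks(labels: pd.DataFrame, cmp: Comparison) -> tuple[np.ndarray, np.ndarray]:
    base = np.ones(len(labels), dtype=bool)
    if cmp.stratum is not None:
        base = (labels[cmp.stratum[0]] == cmp.stratum[1]).values
    a = base & (labels[cmp.by] == cmp.group_a).values
    b = base & (labels[cmp.by] == cmp.group_b).values
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError(f"empty group in comparison {cmp}")
    return a, b


def permutation_test(
    values: pd.Series,
    labels: pd.DataFrame,
    comparisons: list[Comparison],
    n_iter: int = 100_000,
    seed: int = 0,
    statistic_name: str = "statistic",
    method: str = "montecarlo",
) -> list[PermutationResult]:
    """Randomization test over clone labels.

    Clone labels (all label columns jointly) are shuffled globally across
    the whole cohort each iteration; every requested group-mean difference
    is recomputed on the shuffled assignment and exceedance counts in both
    directions are tallied. ``method="exhaustive"`` enumerates every
    distinct assignment of the observed values instead (small cohorts only),
    in which case ``n_iter`` is the number of distinct assignments.
    """
    values = values.loc[labels.index]
    v = values.values.astype(float)
    n = len(v)

    if method == "exhaustive":
        from sympy.utilities.iterables import multiset_permutations

        perms = np.array(list(multiset_permutations(list(v))), dtype=float)
        if perms.shape[0] > 2_000_000:
            raise ValueError("too many assignments for exhaustive enumeration")
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        perms = np.empty((n_iter, n))
        for i in range(n_iter):
            perms[i] = v[rng.permutation(n)]
    else:
        raise ValueError(f"unknown method {method!r}")

    results = []
    for cmp in comparisons:
        a, b = _masks(labels, cmp)
        w = a.astype(float) / a.sum() - b.astype(float) / b.sum()
        observed = float(v @ w)
        diffs = perms @ w
        # tie tolerance: identical label assignments must count as "as
        # extreme" despite summation-order rounding
        eps = 1e-9 * max(1.0, float(np.max(np.abs(diffs), initial=0.0)), abs(observed))
        r_ge = int(np.sum(diffs >= observed - eps))
        r_le = int(np.sum(diffs <= observed + eps))
        n_eff = perms.shape[0]
        results.append(
            PermutationResult(
                statistic_name=statistic_name,
                group_a=cmp.group_a,
                group_b=cmp.group_b,
                stratification=cmp.stratification,
                observed_diff=observed,
                n_iter=n_eff,
                r_ge=r_ge,
                r_le=r_le,
                p_ge=empirical_p(r_ge, n_eff),
                p_le=empirical_p(r_le, n_eff),
            )
        )
    return results


def fdr_adjust(p_by_family: dict[str, list[float]]) -> dict[str, list[float]]:
    """Benjamini-Hochberg step-up, applied separately within each family
    (e.g. SNV signatures, indel signatures, burdens)."""
    out = {}
    for family, ps in p_by_family.items():
        arr = np.asarray(ps, dtype=float)
        if np.any((arr <= 0) | (arr > 1)):
            raise ValueError(f"p-values outside (0, 1] in family {family!r}")
        _, q, _, _ = multipletests(arr, method="fdr_bh")
        out[family] = [float(x) for x in q]
    return out


def adjust_results(results: list[PermutationResult],
                   family_of) -> list[PermutationResult]:
    """Attach BH q-values to permutation results, family-wise; the headline
    p per comparison is min(p_ge, p_le)."""
    fams: dict[str, list[int]] = {}
    for i, r in enumerate(results):
        fams.setdefault(family_of(r), []).append(i)
    for fam, idx in fams.items():
        qs = fdr_adjust({fam: [results[i].p_min for i in idx]})[fam]
        for i, q in zip(idx, qs):
            results[i].q = q
    return results


@dataclass
class RatioStatistic:
    group_id: str
    deletions: int
    insertions: int           # insertions, or insertions + duplications (SV mode)
    ratio: float | None
    log2_ratio: float | None
    mode: str


def del_ins_ratio(
    deletions: int,
    insertions: int,
    mode: str = "small-indel",
    group_id: str = "",
    pseudocount: float | None = None,
) -> RatioStatistic:
    """Deletion/insertion balance: plain ratio for small indels,
    log2(DEL / (INS + DUP)) for SVs. Zero denominators are undefined unless
    a pseudocount is configured."""
    if mode not in ("small-indel", "sv"):
        raise ValueError(f"unknown mode {mode!r}")
    num, den = float(deletions), float(insertions)
    if den == 0:
        if pseudocount is None:
            return RatioStatistic(group_id, deletions, insertions, None, None, mode)
        num, den = num + pseudocount, den + pseudocount
    ratio = num / den
    log2r = math.log2(ratio) if ratio > 0 else None
    return RatioStatistic(group_id, deletions, insertions, ratio, log2r, mode)


def compare_lengths(group_a, group_b, log: bool = False) -> tuple[float, float]:
    """Two-sample (Welch) t-test of mean lengths or distances; optional log
    transform. Degenerate zero-variance input with equal means returns
    (0, 1) by convention."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if log:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log transform requires positive values")
        a, b = np.log10(a), np.log10(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
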