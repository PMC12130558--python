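"""Univariate statistical primitives.

Thin, contract-enforcing wrappers over scipy.stats plus the compact-letter
display used to annotate group comparisons on ordination axes and clinical
indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    direction: int  # sign of the location difference (median-based)
    n1: int
    n2: int


@dataclass
class LetterDisplay:
    """Compact-letter display: groups sharing a letter are not significantly
    different under Tukey-adjusted pairwise comparisons."""

    letters: dict[str, str]
    pairwise_p: "np.ndarray"
    group_order: list[str]
    anova_f: float
    anova_p: float


def _direction(x: np.ndarray, y: np.ndarray) -> int:
    d = float(np.median(x) - np.median(y))
    if d == 0:
        d = float(np.mean(x) - np.mean(y))
    return int(np.sign(d))


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    In ``auto`` mode the exact null distribution is used for n1+n2 <= 12
    with no ties; otherwise the normal approximation with tie and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"bad mode {mode!r}")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if mode == "exact" or (mode == "auto" and x.size + y.size <= 12 and not has_ties):
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        direction=_direction(x, y),
        n1=x.size,
        n2=y.size,
    )


def t_test(x, y) -> TestResult:
    """Welch two-sample t test (optional alternative to the rank test)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t test needs n >= 2 per group")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), _direction(x, y), x.size, y.size)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df.

    All-identical data is H = 0, p = 1 rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if g.size == 0:
            raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return TestResult(0.0, 1.0, 0, groups[0].size, sum(g.size for g in groups[1:]))
    res = sps.kruskal(*groups)
    direction = _direction(groups[0], np.concatenate(groups[1:])) if len(groups) == 2 else 0
    return TestResult(float(res.statistic), float(res.pvalue), direction,
                      groups[0].size, sum(g.size for g in groups[1:]))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.isnan(p).any():
        raise ValueError(f"NaN p-value at index {int(np.flatnonzero(np.isnan(p))[0])}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    if p.size == 0:
        return p.copy()
    return sps.false_discovery_control(p, method="bh")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho on mid-ranks with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("spearman undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _compact_letters(names: list[str], sig: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact-letter display.

    ``sig[i, j]`` is True when groups i and j differ significantly. Starts
    from one letter covering all groups; each significant pair splits every
    letter set containing both; subset letters are absorbed.
    """
    k = len(names)
    letter_sets: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_sets = []
            for s in letter_sets:
                if i in s and j in s:
                    new_sets.append(s - {i})
                    new_sets.append(s - {j})
                else:
                    new_sets.append(s)
            # absorb sets contained in another
            letter_sets = [
                s for s in new_sets
                if s and not any(s < t for t in new_sets)
            ]
            # deduplicate
            seen, uniq = [], []
            for s in letter_sets:
                if s not in seen:
                    seen.append(s)
                    uniq.append(s)
            letter_sets = uniq
    # stable letter assignment: order sets by their smallest member index
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for li, s in enumerate(letter_sets):
        for i in sorted(s):
            out[names[i]] += alphabet[li % 26]
    return out


def anova_tukey_letters(groups: dict[str, np.ndarray], alpha: float = 0.05) -> LetterDisplay:
    """One-way ANOVA with Tukey HSD post hoc and a compact-letter display.

    Two groups share a letter iff their Tukey-adjusted p >= alpha.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for n, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {n!r} has n < 2")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # degenerate: zero variance everywhere, nothing distinguishable
        k = len(names)
        return LetterDisplay({n: "a" for n in names}, np.ones((k, k)), names, 0.0, 1.0)
    f, p = sps.f_oneway(*arrays)
    tk = sps.tukey_hsd(*arrays)
    pmat = np.asarray(tk.pvalue, dtype=float)
    sig = pmat < alpha
    np.fill_diagonal(sig, False)
    letters = _compact_letters(names, sig)
    return LetterDisplay(letters, pmat, names, float(f), float(p))
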