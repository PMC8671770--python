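"""Per-cluster summaries, one-way ANOVA, effect sizes and Tukey–Kramer tests.

All between-group statistics are computable either from raw grouped values
or from the printed summary triples (n, mean, sd); the two routes agree
exactly because the one-way sums of squares are functions of the group
summaries alone:

    SSB = sum n_i (m_i - grand mean)^2,    SSW = sum (n_i - 1) s_i^2,
    F = (SSB / df_b) / (SSW / df_w),       partial eta^2 = SSB / (SSB + SSW),

with df_b = k - 1 and df_w = N - k.  Effect-size bands: below-small < 0.01,
small [0.01, 0.06), medium [0.06, 0.14), large >= 0.14.

Post hoc pairwise contrasts use the Tukey–Kramer generalization of the HSD
to unequal group sizes: q_ij = |m_i - m_j| / sqrt(MSW/2 (1/n_i + 1/n_j)),
with adjusted p-values from the studentized-range distribution on
(k, df_w).  Significant pairs are reported as the conventional letter set
a..f (a = 1v2, b = 1v3, c = 1v4, d = 2v3, e = 2v4, f = 3v4, extended
alphabetically for larger k).
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from edmood.errors import UndefinedStatisticError


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    ci95: tuple[float, float]


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    partial_eta_sq: float
    effect_class: str
    ss_between: float
    ss_within: float


@dataclass
class TukeyPattern:
    significant_pairs: str  # concatenated sorted letters, e.g. "abcdef"
    p_values: dict[tuple[int, int], float]  # 1-based group pairs
    letter_map: dict[str, tuple[int, int]]
    alpha: float


def ci95_from_summary(n: int, mean: float, sd: float) -> tuple[float, float]:
    """t-based 95% CI for a group mean: mean +/- t(.975, n-1) sd / sqrt(n)."""
    if n < 2:
        raise ValueError("confidence interval requires n >= 2")
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return (mean - half, mean + half)


def summarize_group(n: int, mean: float, sd: float) -> GroupSummary:
    return GroupSummary(n=int(n), mean=float(mean), sd=float(sd),
                        ci95=ci95_from_summary(n, mean, sd))


def summarize_groups(groups: Sequence) -> list[GroupSummary]:
    """Sample mean, sample SD (n-1 denominator) and t-based 95% CI per group.

    ``groups`` is a sequence of value arrays, one per cluster.
    """
    out = []
    for g in groups:
        x = np.asarray(g, dtype=float)
        if len(x) < 2:
            raise ValueError("each group needs n >= 2")
        out.append(summarize_group(len(x), x.mean(), x.std(ddof=1)))
    return out


def anova_from_summary(groups: Sequence[tuple[int, float, float]]) -> AnovaResult:
    """One-way ANOVA from (n, mean, sd) group summaries."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    if (ns < 2).any():
        raise ValueError("each group needs n >= 2")
    n_total = ns.sum()
    k = len(groups)
    grand = (ns * means).sum() / n_total
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_b = k - 1
    df_w = int(n_total) - k
    if ssw == 0.0:
        if ssb == 0.0:
            raise UndefinedStatisticError("zero between- and within-group variation")
        f = math.inf
        p = 0.0
        eta = 1.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
        eta = ssb / (ssb + ssw)
    return AnovaResult(
        f_stat=f,
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        partial_eta_sq=eta,
        effect_class=classify_effect(eta),
        ss_between=ssb,
        ss_within=ssw,
    )


def anova_from_raw(groups: Sequence) -> AnovaResult:
    """One-way ANOVA from raw grouped values (identical to the summary route)."""
    triples = []
    for g in groups:
        x = np.asarray(g, dtype=float)
        if len(x) < 2:
            raise ValueError("each group needs n >= 2")
        triples.append((len(x), float(x.mean()), float(x.std(ddof=1))))
    return anova_from_summary(triples)


def pair_letters(k: int) -> dict[str, tuple[int, int]]:
    """Letter -> (i, j) map in lexicographic pair order: a=1v2, b=1v3, ..."""
    pairs = list(itertools.combinations(range(1, k + 1), 2))
    return dict(zip(string.ascii_lowercase, pairs))


def tukey_pattern(
    groups: Sequence[tuple[int, float, float]], alpha: float = 0.05
) -> TukeyPattern:
    """Tukey–Kramer pairwise contrasts from (n, mean, sd) summaries."""
    if len(groups) < 2:
        raise ValueError("post hoc tests require at least 2 groups")
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    k = len(groups)
    df_w = int(ns.sum()) - k
    msw = float(((ns - 1) * sds**2).sum()) / df_w
    if msw <= 0:
        raise UndefinedStatisticError("within-group mean square is zero")
    letters = pair_letters(k)
    p_values: dict[tuple[int, int], float] = {}
    sig = []
    for letter, (i, j) in letters.items():
        se = math.sqrt(msw / 2.0 * (1.0 / ns[i - 1] + 1.0 / ns[j - 1]))
        q = abs(means[i - 1] - means[j - 1]) / se
        p = float(stats.studentized_range.sf(q, k, df_w))
        p_values[(i, j)] = p
        if p < alpha:
            sig.append(letter)
    return TukeyPattern(
        significant_pairs="".join(sorted(sig)),
        p_values=p_values,
        letter_map=letters,
        alpha=alpha,
    )


def classify_effect(partial_eta_sq: float) -> str:
    """Effect-size class for a partial eta-squared value."""
    if not 0.0 <= partial_eta_sq <= 1.0:
        raise ValueError(f"partial eta-squared {partial_eta_sq!r} outside [0, 1]")
    if partial_eta_sq < 0.01:
        return "below_small"
    if partial_eta_sq < 0.06:
        return "small"
    if partial_eta_sq < 0.14:
        return "medium"
    return "large"
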