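"""Statistical reporting: normality, one-way ANOVA with Fisher's LSD and
compact letter display, asterisk-coded two-sample tests, linear
correlation, and division-rate computation.

The reporting conventions mirror the study: sampling time is a single
factor with up to 6 levels (D0, D3, D7, D11, h24, h72); group letters
(a > b > c > d, 'a' on the highest mean) are assigned so that two levels
share a letter iff their pairwise LSD test is not significant at
alpha = 0.05; ecotype contrasts use a t-test whose p-value is rendered as
ns / * / ** / *** with the bands (0.01, 0.05), (0.001, 0.01) and
p < 0.001.  Fisher's LSD is deliberately uncorrected for multiplicity and
gated behind a significant global ANOVA.
"""

from __future__ import annotations

import logging
import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass
class GroupTestResult:
    levels: list[str]
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    f_statistic: float
    p_value: float
    lsd_p: np.ndarray          # symmetric matrix of pairwise LSD p-values
    letters: list[str]
    alpha: float = 0.05


@dataclass
class PairTestResult:
    t_statistic: float
    p_value: float
    code: str
    equal_var: bool = True


def asterisk_code(p: float) -> str:
    """Map a p-value to the ns/*/**/*** bands (open boundaries).

    p values exactly on a boundary (0.05, 0.01, 0.001) fall in the weaker
    band.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def normality_check(groups: dict[str, np.ndarray]):
    """Shapiro-Wilk W and p per group.

    Groups with n < 3 are skipped with a note; zero-variance groups raise
    (W is undefined).  Non-normal groups are logged but do not abort the
    analysis.
    """
    rows = []
    for name, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size < 3:
            log.warning("group %r skipped in normality check (n=%d < 3)",
                        name, x.size)
            continue
        if np.ptp(x) == 0:
            raise ValueError(f"group {name!r} has zero variance; "
                             "Shapiro-Wilk W is undefined")
        w, p = sps.shapiro(x)
        if p < 0.05:
            log.warning("group %r fails the normality check (p=%.3g); "
                        "proceeding with ANOVA regardless", name, p)
        rows.append(dict(group=name, n=x.size, W=w, p=p))
    return pd.DataFrame(rows)


def compact_letter_display(means: np.ndarray, significant: np.ndarray
                           ) -> list[str]:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` marks pairs whose difference is significant.
    Returns one letter string per group such that two groups share a
    letter iff their pair is NOT significant; 'a' is carried by the
    group(s) with the highest mean.
    """
    k = len(means)
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            new_cols: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    new_cols.append(col - {i})
                    new_cols.append(col - {j})
                else:
                    new_cols.append(col)
            # absorb: drop duplicates and subsets of other columns
            new_cols = [c for c in new_cols if c]
            keep: list[set[int]] = []
            for c in sorted(new_cols, key=len, reverse=True):
                if not any(c < other or c == other for other in keep):
                    keep.append(c)
            columns = keep
    # order letters by the best (highest) mean each column contains
    order = np.argsort(-np.asarray(means, dtype=float))
    rank = {g: r for r, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    letters = ["" for _ in range(k)]
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in col:
            letters[g] += letter
    return ["".join(sorted(s)) for s in letters]


def anova_lsd(values, groups, alpha: float = 0.05,
              gate_on_anova: bool = True,
              levels: list[str] | None = None) -> GroupTestResult:
    """One-way ANOVA followed by pairwise Fisher's LSD and letters.

    LSD tests use the pooled within-group variance (ANOVA mean square
    error) with N - k degrees of freedom and are uncorrected.  When
    ``gate_on_anova`` (the default, matching the post-hoc usage), a
    non-significant global F leaves every pair non-significant and all
    groups lettered 'a'.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if levels is None:
        # order of first appearance (levels ordered as sampled)
        _, first = np.unique(groups, return_index=True)
        levels = list(groups[np.sort(first)])
    k = len(levels)
    samples = [values[groups == lev] for lev in levels]
    ns = np.array([len(s) for s in samples])
    if k < 2 or np.any(ns < 2):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    means = np.array([s.mean() for s in samples])
    sds = np.array([s.std(ddof=1) for s in samples])
    n_total = int(ns.sum())
    grand = values[np.isin(groups, levels)].mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((s - m) ** 2).sum() for s, m in zip(samples, means)))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        raise ValueError("zero within-group variance everywhere; "
                         "F is undefined")
    ms_within = ss_within / df_w
    f_stat = (ss_between / df_b) / ms_within
    p_global = float(sps.f.sf(f_stat, df_b, df_w))

    lsd_p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(ms_within * (1.0 / ns[i] + 1.0 / ns[j]))
            t = (means[i] - means[j]) / se
            p = 2.0 * float(sps.t.sf(abs(t), df_w))
            lsd_p[i, j] = lsd_p[j, i] = p

    if gate_on_anova and p_global >= alpha:
        significant = np.zeros((k, k), dtype=bool)
    else:
        significant = lsd_p < alpha
        np.fill_diagonal(significant, False)
    letters = compact_letter_display(means, significant)
    return GroupTestResult(levels=list(levels), means=means, sds=sds, ns=ns,
                           f_statistic=f_stat, p_value=p_global, lsd_p=lsd_p,
                           letters=letters, alpha=alpha)


def pair_test(x, y, equal_var: bool = True) -> PairTestResult:
    """Two-sample t-test with asterisk coding.

    Pooled-variance (Student) by default; set ``equal_var=False`` for
    Welch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero combined variance; t is undefined")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return PairTestResult(t_statistic=float(t), p_value=float(p),
                          code=asterisk_code(float(p)), equal_var=equal_var)


def linear_correlation(x, y) -> dict:
    """Least-squares line and coefficient of determination."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2), "p_value": float(res.pvalue)}


def division_rate(density_t1: float, density_t2: float, dt_days: float
                  ) -> float:
    """Exponential division (doubling) rate log2(N2/N1)/dt in day^-1."""
    if density_t1 <= 0 or density_t2 <= 0 or dt_days <= 0:
        raise ValueError("densities and time interval must be positive")
    return math.log2(density_t2 / density_t1) / dt_days
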