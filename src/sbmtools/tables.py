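"""Group comparison statistics from printed summary values or raw data.

Reproduces demographic-table statistics (two-sample t tests on
mean/SD/n summaries, chi-square tests on 2x2 counts) so that published
cohort tables can be checked or regenerated from either raw phenotype
files or the printed summaries alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean/SD/n for one continuous variable."""

    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    def __post_init__(self):
        if self.n1 <= 1 or self.n2 <= 1:
            raise ValueError("each group needs n > 1")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be >= 0")

    @classmethod
    def from_samples(cls, a, b) -> "GroupSummary":
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        return cls(len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1))


def two_sample_t(summary: GroupSummary, variant: str = "pooled"):
    """Two-sample t test from summary statistics.

    ``pooled`` uses Student's t with df = n1 + n2 - 2; ``welch`` uses
    the Satterthwaite degrees of freedom.  Returns ``(t, df, p)``; when
    both SDs are zero and the means are equal the statistic is undefined
    and NaN is returned.
    """
    s = summary
    if variant == "pooled":
        sp2 = ((s.n1 - 1) * s.sd1**2 + (s.n2 - 1) * s.sd2**2) / (s.n1 + s.n2 - 2)
        se = np.sqrt(sp2 * (1.0 / s.n1 + 1.0 / s.n2))
        df = s.n1 + s.n2 - 2
    elif variant == "welch":
        v1, v2 = s.sd1**2 / s.n1, s.sd2**2 / s.n2
        se = np.sqrt(v1 + v2)
        if se > 0:
            df = (v1 + v2) ** 2 / (v1**2 / (s.n1 - 1) + v2**2 / (s.n2 - 1))
        else:
            df = s.n1 + s.n2 - 2
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    diff = s.mean1 - s.mean2
    if se == 0:
        if diff == 0:
            return float("nan"), float(df), float("nan")  # undefined
        return np.inf * np.sign(diff), float(df), 0.0
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_2x2(table, yates: bool = False):
    """Chi-square test of independence on a 2x2 count table.

    Uses the closed form N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the
    Yates continuity correction subtracts N/2 from |ad - bc| first.
    Returns ``(chi2, p)`` with p from the 1-df chi-square distribution.
    """
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("table has a zero margin")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num**2 / margins
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def summarize_groups(
    table: pd.DataFrame,
    value_col: str,
    group_col: str = "diagnosis",
    groups: tuple = ("autism", "td"),
) -> GroupSummary:
    """Build a :class:`GroupSummary` for one variable from a phenotype table."""
    vals = table[[group_col, value_col]].dropna()
    a = vals.loc[vals[group_col] == groups[0], value_col].to_numpy(float)
    b = vals.loc[vals[group_col] == groups[1], value_col].to_numpy(float)
    return GroupSummary.from_samples(a, b)


def demographics_table(table: pd.DataFrame, continuous=("age", "fsiq")) -> pd.DataFrame:
    """Cohort-comparison table: t tests for continuous rows, chi2 for sex/ADHD."""
    rows = []
    for col in continuous:
        s = summarize_groups(table, col)
        t, df, p = two_sample_t(s, "pooled")
        rows.append(
            {
                "variable": col,
                "autism_mean": s.mean1, "autism_sd": s.sd1, "autism_n": s.n1,
                "td_mean": s.mean2, "td_sd": s.sd2, "td_n": s.n2,
                "stat": t, "stat_name": "t", "p": p,
            }
        )
    for col, positive in (("sex", "male"), ("adhd", 1)):
        if col not in table.columns:
            continue
        sub = table[["diagnosis", col]].dropna()
        counts = np.array(
            [
                [
                    int((sub.loc[sub["diagnosis"] == g, col] == positive).sum()),
                    int((sub.loc[sub["diagnosis"] == g, col] != positive).sum()),
                ]
                for g in ("autism", "td")
            ]
        )
        chi2, p = chi_square_2x2(counts)
        rows.append(
            {
                "variable": col,
                "autism_mean": counts[0, 0], "autism_sd": counts[0, 1],
                "autism_n": int(counts[0].sum()),
                "td_mean": counts[1, 0], "td_sd": counts[1, 1],
                "td_n": int(counts[1].sum()),
                "stat": chi2, "stat_name": "chi2", "p": p,
            }
        )
    return pd.DataFrame(rows)
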