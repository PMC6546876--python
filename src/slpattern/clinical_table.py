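"""Response-group labelling and demographic/clinical group statistics.

Patients whose VAS drops by less than three points after the one-week
medication course are labelled medication-resistant (MRP); the rest
medication-sensitive (MSP).  Group comparisons use two-sample t-tests on
summary statistics (Welch by default) and the Pearson chi-square test
without continuity correction for gender.  A noncentral-t power routine
gives the per-group sample size needed for a target effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "label_response",
    "two_sample_t",
    "chi_square_2x2",
    "sample_size_per_group",
    "summarize",
    "table1",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")


def label_response(pre_vas: float, post_vas: float) -> str:
    """MRP iff the VAS reduction (pre - post) is less than three, else MSP."""
    for name, v in (("pre_vas", pre_vas), ("post_vas", post_vas)):
        if not 0.0 <= v <= 10.0:
            raise ValueError(f"{name}={v} outside the 10-point scale [0, 10]")
    return "MRP" if (pre_vas - post_vas) < 3.0 else "MSP"


def two_sample_t(a: GroupSummary, b: GroupSummary, variant: str = "welch"):
    """Two-sample t-test from group summaries.

    variant="welch" uses unequal variances with Satterthwaite df;
    variant="student" pools variances.  Returns ``(t, df, p)`` two-tailed.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"variant must be 'welch' or 'student', got {variant!r}")
    if a.sd == 0 and b.sd == 0:
        raise ValueError("degenerate comparison: both group SDs are zero")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "student")
    )
    if variant == "student":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(counts, correction: bool = False):
    """Pearson chi-square on a 2x2 table; no continuity correction by default.

    Returns ``(chi2, df, p)`` with df = 1.
    """
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("counts must be a 2x2 table of nonnegative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("all row and column marginals must be positive")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=correction)
    return float(chi2), int(df), float(p)


def sample_size_per_group(effect_size_d: float, alpha: float = 0.05,
                          power: float = 0.8, n_max: int = 100000) -> int:
    """Smallest per-group n reaching ``power`` in a two-sided two-sample t-test.

    Power at per-group size n uses the noncentral t distribution with
    df = 2n - 2 and noncentrality d * sqrt(n/2).
    """
    if effect_size_d <= 0:
        raise ValueError(f"effect size must be positive, got {effect_size_d}")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        nc = effect_size_d * np.sqrt(n / 2.0)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        achieved = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        if achieved >= power:
            return n
    raise ValueError(
        f"target power {power} unattainable within n <= {n_max} for d={effect_size_d}"
    )


def summarize(values) -> GroupSummary:
    """Sample mean/SD summary (ddof=1) of a numeric vector."""
    v = np.asarray(values, dtype=float)
    return GroupSummary(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


_T1_MEASURES = [
    ("Ages", "age"),
    ("Pre-VAS", "pre_vas"),
    ("Post-VAS", "post_vas"),
    ("Pre-PSQI", "pre_psqi"),
    ("Post-PSQI", "post_psqi"),
]


def table1(subjects: pd.DataFrame, variant: str = "welch") -> pd.DataFrame:
    """Demographic/clinical comparison table from a subject table.

    Expects columns group, age, gender, pre_vas, post_vas, pre_psqi,
    post_psqi (extra numeric columns, e.g. duration, are included when
    present).  Rows: one per measure with per-group "mean (sd)" and the
    two-tailed p; gender as male/female counts with the chi-square p.
    """
    groups = list(pd.unique(subjects["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g1 = subjects[subjects["group"] == groups[0]]
    g2 = subjects[subjects["group"] == groups[1]]

    measures = list(_T1_MEASURES)
    if "duration" in subjects.columns:
        measures.insert(1, ("Duration", "duration"))

    rows = []
    for label, col in measures:
        if col not in subjects.columns:
            continue
        sa, sb = summarize(g1[col]), summarize(g2[col])
        _, _, p = two_sample_t(sa, sb, variant=variant)
        rows.append(
            {
                "measure": label,
                groups[0]: f"{sa.mean:.1f} ({sa.sd:.1f})",
                groups[1]: f"{sb.mean:.1f} ({sb.sd:.1f})",
                "p": p,
            }
        )
    if "gender" in subjects.columns:
        counts = [
            [(g["gender"] == "M").sum(), (g["gender"] == "F").sum()] for g in (g1, g2)
        ]
        _, _, p = chi_square_2x2(counts)
        rows.insert(
            1,
            {
                "measure": "Males/Females",
                groups[0]: f"{counts[0][0]}/{counts[0][1]}",
                groups[1]: f"{counts[1][0]}/{counts[1][1]}",
                "p": p,
            },
        )
    return pd.DataFrame(rows)
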