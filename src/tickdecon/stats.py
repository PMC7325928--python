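"""Nonparametric comparisons used in the contamination analysis.

Three tests: a chi-square test of independence on contamination-rate
category counts, a Wilcoxon signed-rank test on paired
filtered/unfiltered diversity values, and a Kruskal-Wallis test between
tick instars. All p-values are two-sided and no multiplicity correction
is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "chi_square_independence",
    "wilcoxon_paired",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "compare_diversity",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[int] = None
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value must lie in [0, 1]")
        if self.df is not None and self.df < 1:
            raise ValueError("df must be >= 1 when present")


def chi_square_independence(
    contingency: Sequence[Sequence[int]], correction: bool = False
) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction by default; set ``correction=True`` for the
    Yates-corrected variant on 2x2 tables.
    """
    obs = np.asarray(contingency)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("all row and column totals must be positive")
    res = sps.chi2_contingency(obs, correction=correction)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=int(res.dof),
        method="chi-square independence" + (" (Yates)" if correction else ""),
    )


def wilcoxon_paired(
    before: Sequence[float],
    after: Sequence[float],
    exact_max_n: int = 25,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped. The exact null distribution is used for
    small samples (n <= ``exact_max_n``, no tied absolute differences);
    otherwise the normal approximation with tie-corrected variance. If
    every difference is zero the test is degenerate and p = 1 is reported
    with a warning.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before and after must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; test degenerate", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, method="wilcoxon signed-rank (degenerate)")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= exact_max_n and not has_ties) else "approx"
    res = sps.wilcoxon(
        b, a, zero_method="wilcox", alternative="two-sided", correction=False,
        method=method,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"wilcoxon signed-rank ({method})",
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Unpaired two-sided Wilcoxon rank-sum (Mann-Whitney) test."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="wilcoxon rank-sum",
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> TestResult:
    """Kruskal-Wallis H test with mid-rank tie correction.

    ``groups`` is a list of >= 2 nonempty value vectors; p comes from the
    chi-square distribution with k - 1 degrees of freedom. If all values
    across all groups are identical the test is degenerate and p = 1 is
    reported with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    label_t = tuple(labels) if labels is not None else ()
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.unique(flat).size == 1:
        warnings.warn("all values identical across groups; test degenerate", stacklevel=2)
        return TestResult(
            statistic=0.0, p_value=1.0, df=len(groups) - 1,
            method="kruskal-wallis (degenerate)", groups=label_t,
        )
    res = sps.kruskal(*groups)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=len(groups) - 1,
        method="kruskal-wallis",
        groups=label_t,
    )


def compare_diversity(impact: pd.DataFrame) -> pd.DataFrame:
    """The full comparison grid over a paired diversity table.

    For each measure: a paired Wilcoxon test filtered vs unfiltered within
    each tick category, and a Kruskal-Wallis test between categories
    within each state (unfiltered and filtered). ``impact`` is the
    long-format output of :func:`tickdecon.diversity.diversity_impact`.
    """
    rows = []
    for measure, sub in impact.groupby("measure"):
        wide = sub.pivot_table(
            index=["sample_id", "category"], columns="filtered", values="value"
        ).reset_index()
        for cat, grp in wide.groupby("category"):
            if grp.shape[0] < 2 or False not in grp or True not in grp:
                continue
            res = wilcoxon_paired(grp[False].to_numpy(), grp[True].to_numpy())
            rows.append(
                {
                    "measure": measure,
                    "comparison": "filtered_vs_unfiltered",
                    "group": cat,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method,
                }
            )
        for state in (False, True):
            by_cat = [
                grp[state].dropna().to_numpy() for _, grp in wide.groupby("category")
            ]
            cats = [c for c, _ in wide.groupby("category")]
            if len(by_cat) >= 2 and all(len(g) for g in by_cat):
                res = kruskal_wallis(by_cat, labels=cats)
                rows.append(
                    {
                        "measure": measure,
                        "comparison": "between_instars",
                        "group": "filtered" if state else "unfiltered",
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "method": res.method,
                    }
                )
    return pd.DataFrame(rows)
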