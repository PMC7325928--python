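"""Two-rule contaminant classification against negative controls.

Rule 1 (main contaminants): an OTU whose pooled count within any single
negative-control category exceeds 1% of that category's pooled sequence
total is a main contaminant.

Rule 2 (cross-talk interval): sequencing cross-talk (index
misassignment on the flow cell) is expected to deposit a small fraction
eps (default 0.02%) of each OTU's dataset-wide total N_i into other
libraries, so negative controls legitimately contain a few reads of
genuine OTUs. Under this null the count of OTU i seen in a control is
modelled as Binomial(N_i, eps); an OTU whose maximum single-control
count M_i exceeds the upper bound U_i of the two-sided 99% interval of
that law is called a contaminant. An OTU below U_i is consistent with
cross-talk alone.

A reverse check confirms that sample-to-control spill is negligible: the
most abundant genuine OTU should never appear in any control above its
expected cross-talk count eps * N_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    NEGATIVE_CONTROL_CATEGORIES,
    CountTable,
    SampleCategory,
    SampleInfo,
)

__all__ = [
    "CrosstalkParams",
    "ContaminantCall",
    "SpillReport",
    "main_contaminants",
    "expected_crosstalk_count",
    "crosstalk_upper_threshold",
    "classify_contaminants",
    "reverse_contamination_check",
    "calls_to_frame",
    "frame_to_calls",
]

RULE_MAIN = "main_1pct"
RULE_CROSSTALK = "crosstalk_ci"
RULE_NONE = "none"


@dataclass(frozen=True)
class CrosstalkParams:
    """Parameters of the cross-talk null model.

    rate
        False-assignment rate eps: the fraction of an OTU's reads expected
        to be misassigned across libraries. Default 0.0002 (0.02%).
    confidence
        Level of the confidence interval around the expected count.
        Default 0.99.
    family
        'binomial' (default) models the control count as Binomial(N, eps);
        'poisson' uses a Poisson(eps * N) approximation, convenient for
        very large N.
    one_sided
        If True the threshold is the ``confidence`` quantile instead of
        the two-sided upper bound (the 1 - (1-confidence)/2 quantile).
    """

    rate: float = 0.0002
    confidence: float = 0.99
    family: str = "binomial"
    one_sided: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.rate < 1):
            raise ValueError("rate must lie in (0, 1)")
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must lie in (0, 1)")
        if self.family not in ("binomial", "poisson"):
            raise ValueError("family must be 'binomial' or 'poisson'")

    @property
    def upper_quantile(self) -> float:
        if self.one_sided:
            return self.confidence
        return 1 - (1 - self.confidence) / 2


@dataclass(frozen=True)
class ContaminantCall:
    """Classification of one OTU with the evidence behind it."""

    otu_id: str
    is_contaminant: bool
    rule: str
    category_fractions: dict[str, float]
    total_count: int
    expected_count: float
    upper_threshold: int
    max_control_count: int

    def __post_init__(self) -> None:
        if self.is_contaminant != (self.rule != RULE_NONE):
            raise ValueError("is_contaminant must agree with rule")
        if not (0 <= self.max_control_count <= self.total_count):
            raise ValueError("max_control_count out of range")


@dataclass(frozen=True)
class SpillReport:
    """Outcome of the sample-to-control spill check."""

    reference_otu: str
    expected_count: float
    passed: bool
    offending_controls: tuple[str, ...]


def expected_crosstalk_count(total_count: int, params: CrosstalkParams) -> float:
    """Expected number of reads of an OTU misassigned anywhere: eps * N."""
    if total_count < 0:
        raise ValueError("total_count must be >= 0")
    return params.rate * total_count


def crosstalk_upper_threshold(total_count: int, params: CrosstalkParams) -> int:
    """Upper bound U of the confidence interval around the expected
    cross-talk count.

    U is the smallest integer whose cumulative probability under the null
    count law reaches the upper quantile (0.995 at the default two-sided
    99% level), and never falls below floor(eps * N).
    """
    if total_count < 0:
        raise ValueError("total_count must be >= 0")
    if total_count == 0:
        return 0
    q = params.upper_quantile
    if params.family == "binomial":
        u = stats.binom.ppf(q, total_count, params.rate)
    else:
        u = stats.poisson.ppf(q, params.rate * total_count)
    u = int(u)
    return max(u, math.floor(expected_crosstalk_count(total_count, params)))


def _control_columns(
    table: CountTable, metadata: Mapping[str, SampleInfo]
) -> dict[SampleCategory, list[str]]:
    """Negative-control sample ids grouped by category; positive controls and
    specimens are excluded."""
    missing = [s for s in table.sample_ids if s not in metadata]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    groups: dict[SampleCategory, list[str]] = {c: [] for c in NEGATIVE_CONTROL_CATEGORIES}
    for s in table.sample_ids:
        cat = metadata[s].category
        if cat in groups:
            groups[cat].append(s)
    return {c: ids for c, ids in groups.items() if ids}


def _category_fractions(
    table: CountTable, controls: Mapping[SampleCategory, list[str]]
) -> pd.DataFrame:
    """OTU x control-category matrix of pooled within-category fractions."""
    df = table.data
    out = {}
    for cat, ids in controls.items():
        pooled = df[ids].sum(axis=1)
        total = pooled.sum()
        out[cat.value] = pooled / total if total > 0 else pooled * 0.0
    return pd.DataFrame(out, index=table.otu_ids)


def main_contaminants(
    table: CountTable,
    metadata: Mapping[str, SampleInfo],
    threshold: float = 0.01,
) -> set[str]:
    """OTUs exceeding ``threshold`` (strictly) of the pooled sequences of any
    single negative-control category."""
    controls = _control_columns(table, metadata)
    if not controls:
        raise ValueError(
            "no negative-control samples found: contaminant identification "
            "requires homogenization, extraction or amplification controls"
        )
    fractions = _category_fractions(table, controls)
    mask = (fractions > threshold).any(axis=1)
    return set(fractions.index[mask])


def classify_contaminants(
    table: CountTable,
    metadata: Mapping[str, SampleInfo],
    params: Optional[CrosstalkParams] = None,
    main_threshold: float = 0.01,
) -> list[ContaminantCall]:
    """Classify every OTU in the table as contaminant or genuine.

    For each OTU i the call records its pooled fraction in each
    negative-control category, its dataset-wide total N_i, the expected
    cross-talk count eps * N_i, the interval upper bound U_i, and the
    maximum single-sample count M_i over all negative controls. The rule
    reported is ``main_1pct`` when the 1% rule fires (it takes precedence),
    else ``crosstalk_ci`` when M_i > U_i (strict), else ``none``.
    """
    if params is None:
        params = CrosstalkParams()
    controls = _control_columns(table, metadata)
    if not controls:
        raise ValueError(
            "no negative-control samples found: contaminant identification "
            "requires homogenization, extraction or amplification controls"
        )
    main_set = main_contaminants(table, metadata, threshold=main_threshold)
    fractions = _category_fractions(table, controls)
    control_ids = [s for ids in controls.values() for s in ids]
    df = table.data
    control_max = df[control_ids].max(axis=1)
    totals = table.otu_totals()

    calls: list[ContaminantCall] = []
    for otu in table.otu_ids:
        n_i = int(totals[otu])
        m_i = int(control_max[otu])
        e_i = expected_crosstalk_count(n_i, params)
        u_i = crosstalk_upper_threshold(n_i, params)
        if otu in main_set:
            rule = RULE_MAIN
        elif m_i > u_i:
            rule = RULE_CROSSTALK
        else:
            rule = RULE_NONE
        calls.append(
            ContaminantCall(
                otu_id=otu,
                is_contaminant=rule != RULE_NONE,
                rule=rule,
                category_fractions={
                    c: float(fractions.loc[otu, c]) for c in fractions.columns
                },
                total_count=n_i,
                expected_count=e_i,
                upper_threshold=u_i,
                max_control_count=m_i,
            )
        )
    return calls


def reverse_contamination_check(
    table: CountTable,
    metadata: Mapping[str, SampleInfo],
    reference_otu: str,
    params: Optional[CrosstalkParams] = None,
) -> SpillReport:
    """Check that sample-to-control spill is negligible.

    The reference OTU should be the most abundant genuine OTU (e.g. the
    dominant tick endosymbiont). The check passes when no negative control
    contains more of its reads than the expected cross-talk count
    eps * N_reference; controls exceeding it are listed.
    """
    if params is None:
        params = CrosstalkParams()
    if reference_otu not in set(table.otu_ids):
        raise KeyError(f"unknown OTU {reference_otu!r}")
    controls = _control_columns(table, metadata)
    control_ids = [s for ids in controls.values() for s in ids]
    n_ref = int(table.otu_totals()[reference_otu])
    expected = expected_crosstalk_count(n_ref, params)
    row = table.data.loc[reference_otu, control_ids]
    offending = tuple(row.index[row > expected])
    return SpillReport(
        reference_otu=reference_otu,
        expected_count=expected,
        passed=len(offending) == 0,
        offending_controls=offending,
    )


# ---------------------------------------------------------------------------
# tabular round-trip for CLI workflows
# ---------------------------------------------------------------------------

def calls_to_frame(calls: Sequence[ContaminantCall]) -> pd.DataFrame:
    """Flatten calls into a data frame (one row per OTU)."""
    cats = sorted({c for call in calls for c in call.category_fractions})
    rows = []
    for call in calls:
        row = {
            "otu_id": call.otu_id,
            "is_contaminant": call.is_contaminant,
            "rule": call.rule,
            "N": call.total_count,
            "expected": call.expected_count,
            "upper_threshold": call.upper_threshold,
            "max_control_count": call.max_control_count,
        }
        for c in cats:
            row[f"frac_{c}"] = call.category_fractions.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_calls(df: pd.DataFrame) -> list[ContaminantCall]:
    frac_cols = [c for c in df.columns if c.startswith("frac_")]
    calls = []
    for _, row in df.iterrows():
        calls.append(
            ContaminantCall(
                otu_id=str(row["otu_id"]),
                is_contaminant=bool(row["is_contaminant"]),
                rule=str(row["rule"]),
                category_fractions={
                    c[len("frac_") :]: float(row[c])
                    for c in frac_cols
                    if pd.notna(row[c])
                },
                total_count=int(row["N"]),
                expected_count=float(row["expected"]),
                upper_threshold=int(row["upper_threshold"]),
                max_control_count=int(row["max_control_count"]),
            )
        )
    return calls
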