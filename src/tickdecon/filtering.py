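"""Contaminant removal, depth-based sample dropping, and contamination rates.

A sample's contamination rate is the fraction of its reads belonging to
OTUs classified as contaminants; rates are computed on the table BEFORE
contaminant removal, then samples left with fewer than ``min_depth``
reads after removal are dropped from downstream analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contaminants import RULE_NONE, ContaminantCall
from .io import TICK_CATEGORIES, CountTable, SampleInfo

__all__ = [
    "ContaminationProfile",
    "remove_contaminants",
    "drop_shallow_samples",
    "contamination_rates",
    "bin_contamination",
]

DEFAULT_MIN_DEPTH = 500
DEFAULT_BREAKS = (0.2, 0.5)


@dataclass(frozen=True)
class ContaminationProfile:
    """Per-sample contamination summary.

    ``rate`` is NaN (undefined) when the sample holds no reads at all.
    """

    sample_id: str
    total_count: int
    contaminant_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.contaminant_count <= self.total_count):
            raise ValueError("contaminant_count out of range")

    @property
    def rate(self) -> float:
        if self.total_count == 0:
            return float("nan")
        return self.contaminant_count / self.total_count


def _contaminant_ids(calls: Sequence[ContaminantCall], table: CountTable) -> set[str]:
    by_id = {c.otu_id: c for c in calls}
    missing = [o for o in table.otu_ids if o not in by_id]
    if missing:
        raise ValueError(f"contaminant calls missing for OTUs: {missing}")
    return {o for o in table.otu_ids if by_id[o].rule != RULE_NONE}


def remove_contaminants(
    table: CountTable, calls: Sequence[ContaminantCall]
) -> CountTable:
    """Restrict the table to OTUs not flagged as contaminants.

    All sample columns are preserved, possibly as all-zero columns.
    """
    flagged = _contaminant_ids(calls, table)
    return table.select_otus([o for o in table.otu_ids if o not in flagged])


def drop_shallow_samples(
    table: CountTable, min_depth: int = DEFAULT_MIN_DEPTH
) -> CountTable:
    """Drop sample columns whose total is strictly below ``min_depth``.

    Intended to run after :func:`remove_contaminants`, so that samples
    reduced below the depth floor by the filtering are excluded even if
    they were deep enough beforehand.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    totals = table.sample_totals()
    keep = totals.index[totals >= min_depth]
    return table.select_samples(keep)


def contamination_rates(
    table: CountTable,
    calls: Sequence[ContaminantCall],
    metadata: Mapping[str, SampleInfo],
) -> list[ContaminationProfile]:
    """Per-specimen contamination profiles on the pre-removal table.

    Controls are excluded; one profile per tick sample (nymph, male,
    female), in table column order.
    """
    flagged = _contaminant_ids(calls, table)
    df = table.data
    contaminant_reads = df.loc[sorted(flagged)].sum(axis=0) if flagged else df.sum(axis=0) * 0
    totals = table.sample_totals()
    profiles = []
    for s in table.sample_ids:
        if metadata[s].category not in TICK_CATEGORIES:
            continue
        profiles.append(
            ContaminationProfile(
                sample_id=s,
                total_count=int(totals[s]),
                contaminant_count=int(contaminant_reads[s]),
            )
        )
    return profiles


def bin_contamination(
    profiles: Sequence[ContaminationProfile],
    metadata: Mapping[str, SampleInfo],
    breaks: Sequence[float] = DEFAULT_BREAKS,
) -> pd.DataFrame:
    """Bin per-sample contamination rates per tick category.

    Bins are left-closed, right-open — [0, b1), [b1, b2), ... — with the
    last bin [b_last, 1] closed at both ends, so a rate exactly at a break
    falls in the bin that starts there. Returns one row per category with
    per-bin counts, per-bin fractions, and the two headline fractions:
    share of samples in the top bin (at or above the last break) and in
    the bottom bin (below the first break). Samples with undefined rates
    (zero reads) are ignored.
    """
    breaks = list(breaks)
    if not breaks or any(not (0 < b < 1) for b in breaks):
        raise ValueError("breaks must lie strictly inside (0, 1)")
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    edges = [0.0] + breaks + [1.0]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        closer = "]" if hi == 1.0 else ")"
        labels.append(f"[{lo:g},{hi:g}{closer}")

    rows = []
    by_cat: dict[str, list[float]] = {}
    for p in profiles:
        cat = metadata[p.sample_id].category.value
        if not math.isnan(p.rate):
            by_cat.setdefault(cat, []).append(p.rate)
    for cat, rates in sorted(by_cat.items()):
        arr = np.asarray(rates)
        # np.digitize with right=False gives left-closed bins; clip keeps 1.0
        # inside the final bin.
        idx = np.clip(np.digitize(arr, breaks, right=False), 0, len(labels) - 1)
        counts = np.bincount(idx, minlength=len(labels))
        n = len(arr)
        row = {"category": cat, "n_samples": n}
        for lab, c in zip(labels, counts):
            row[f"count_{lab}"] = int(c)
            row[f"frac_{lab}"] = c / n
        row["frac_above_last_break"] = counts[-1] / n
        row["frac_below_first_break"] = counts[0] / n
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")
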