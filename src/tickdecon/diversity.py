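"""Alpha-diversity measures and the filtered-versus-unfiltered comparison.

Four measures are computed per sample: observed richness (number of OTUs
with nonzero count), Shannon entropy H = -sum p_i ln p_i (natural log by
default), the Gini-Simpson index 1 - sum p_i^2, and Faith's phylogenetic
diversity (total branch length of the subtree spanning the sample's OTUs,
root connection included).

:func:`diversity_impact` computes each measure twice per sample — on the
table before and after contaminant removal — restricted to the samples
deep enough after removal, so the two states can be compared pairwise.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import skbio
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .contaminants import ContaminantCall
from .filtering import DEFAULT_MIN_DEPTH, drop_shallow_samples, remove_contaminants
from .io import CountTable, Dataset

__all__ = [
    "observed_richness",
    "shannon",
    "simpson",
    "faith_pd",
    "alpha_diversity_table",
    "diversity_impact",
]

MEASURES = ("observed", "shannon", "simpson", "faith_pd")


def _as_counts(counts: Sequence[float]) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def observed_richness(counts: Sequence[float]) -> float:
    """Number of OTUs present (count > 0)."""
    return float((_as_counts(counts) > 0).sum())


def shannon(counts: Sequence[float], base: Optional[float] = None) -> float:
    """Shannon entropy -sum p_i log p_i over present OTUs.

    Natural log by default; pass ``base`` to change the logarithm base.
    Raises on an all-zero sample (the index is undefined there).
    """
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        raise ValueError("Shannon index undefined for a zero-total sample")
    p = arr[arr > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def simpson(counts: Sequence[float], variant: str = "gini") -> float:
    """Simpson-family diversity of a sample.

    variant='gini' (default) returns 1 - sum p_i^2, the probability that
    two randomly drawn reads belong to different OTUs; 'dominance' returns
    sum p_i^2; 'inverse' returns 1 / sum p_i^2.
    """
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        raise ValueError("Simpson index undefined for a zero-total sample")
    p = arr / total
    d = float((p**2).sum())
    if variant == "gini":
        return 1.0 - d
    if variant == "dominance":
        return d
    if variant == "inverse":
        return 1.0 / d
    raise ValueError("variant must be 'gini', 'dominance' or 'inverse'")


def faith_pd(
    counts: Sequence[float],
    otu_ids: Sequence[str],
    tree: skbio.TreeNode,
    include_root: bool = True,
) -> float:
    """Faith's phylogenetic diversity of one sample.

    Sum of branch lengths of the minimal subtree connecting the sample's
    present OTUs to the root. With ``include_root=False`` the branches
    between the root and the most recent common ancestor of the present
    OTUs are excluded. Raises if a present OTU is not a leaf of the tree.
    """
    arr = _as_counts(counts)
    if len(arr) != len(otu_ids):
        raise ValueError("counts and otu_ids length mismatch")
    present = [o for o, c in zip(otu_ids, arr) if c > 0]
    if not present:
        return 0.0
    leaf_names = {t.name for t in tree.tips()}
    absent = [o for o in present if o not in leaf_names]
    if absent:
        raise ValueError(f"OTUs present in sample but absent from tree: {absent}")
    value = float(
        _skbio_faith_pd(arr.astype(int), taxa=list(otu_ids), tree=tree, validate=False)
    )
    if not include_root and len(present) >= 1:
        mrca = tree.lca([tree.find(o) for o in present]) if len(present) > 1 else tree.find(present[0])
        node = mrca
        while node.parent is not None:
            value -= node.length or 0.0
            node = node.parent
    return value


def alpha_diversity_table(
    table: CountTable,
    tree: Optional[skbio.TreeNode] = None,
    measures: Sequence[str] = MEASURES,
) -> pd.DataFrame:
    """Long-format diversity table: one row per sample per measure.

    Samples with zero total reads get NaN for Shannon and Simpson. The
    faith_pd measure is skipped (with all others kept) when no tree is
    supplied.
    """
    rows = []
    arr = table.counts
    otus = table.otu_ids
    for j, s in enumerate(table.sample_ids):
        col = arr[:, j]
        total = col.sum()
        for m in measures:
            if m == "faith_pd" and tree is None:
                continue
            if m in ("shannon", "simpson") and total == 0:
                value = float("nan")
            elif m == "observed":
                value = observed_richness(col)
            elif m == "shannon":
                value = shannon(col)
            elif m == "simpson":
                value = simpson(col)
            elif m == "faith_pd":
                value = faith_pd(col, otus, tree)
            else:
                raise ValueError(f"unknown measure {m!r}")
            rows.append({"sample_id": s, "measure": m, "value": value})
    return pd.DataFrame(rows)


def diversity_impact(
    dataset: Dataset,
    calls: Sequence[ContaminantCall],
    tree: Optional[skbio.TreeNode] = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    measures: Sequence[str] = MEASURES,
) -> pd.DataFrame:
    """Paired diversity before and after contaminant removal.

    The eligible sample set is fixed first — samples retaining at least
    ``min_depth`` reads after contaminant removal — and every measure is
    then computed on that same set in both states, enabling a paired
    comparison. Columns: sample_id, category, measure, value, filtered.
    """
    if tree is None:
        tree = dataset.tree
    table = dataset.table
    filtered = remove_contaminants(table, calls)
    eligible = drop_shallow_samples(filtered, min_depth=min_depth).sample_ids
    before = table.select_samples(eligible)
    after = filtered.select_samples(eligible)

    frames = []
    for state, tab in ((False, before), (True, after)):
        df = alpha_diversity_table(tab, tree=tree, measures=measures)
        df["filtered"] = state
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["category"] = out["sample_id"].map(
        lambda s: dataset.metadata[s].category.value
    )
    return out[["sample_id", "category", "measure", "value", "filtered"]]
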