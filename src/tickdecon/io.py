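"""Dataset model, tabular I/O, and table-level pre-filters.

The central container is :class:`CountTable`, an integer OTU x sample
matrix with ordered identifiers, backed by a :class:`pandas.DataFrame`.
Sample roles are described by :class:`SampleInfo` records whose category
distinguishes tick specimens (nymph, male, female) from the three
negative-control categories (homogenization, extraction, amplification)
and from positive controls.

Two table-level pre-filters are provided: removal of rare OTUs below a
fraction of the dataset-wide sequence total, and removal of OTUs that are
organellar (mitochondria / chloroplast) or lack a domain-level
affiliation.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import skbio
from skbio.table import Table as _BiomTable

__all__ = [
    "SampleCategory",
    "SampleInfo",
    "Lineage",
    "CountTable",
    "Dataset",
    "ParseError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "filter_rare_otus",
    "filter_nonprokaryotic",
    "summarize_by_category",
]

N_RANKS = 7
RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")
#: sentinel lineage values that are not taxon names
SENTINELS = frozenset({"unknown", "multi-affiliated"})


class ParseError(ValueError):
    """Raised when an input file violates the expected dialect."""


class SampleCategory(str, enum.Enum):
    """Role of a library in the processing chain."""

    NYMPH = "nymph"
    MALE = "male"
    FEMALE = "female"
    HOMOGENIZATION_CONTROL = "homogenization_control"
    EXTRACTION_CONTROL = "extraction_control"
    AMPLIFICATION_CONTROL = "amplification_control"
    POSITIVE_CONTROL = "positive_control"

    @property
    def is_negative_control(self) -> bool:
        return self in NEGATIVE_CONTROL_CATEGORIES

    @property
    def is_specimen(self) -> bool:
        return self in TICK_CATEGORIES

    @classmethod
    def parse(cls, text: str) -> "SampleCategory":
        key = text.strip().lower()
        if key in _CATEGORY_ALIASES:
            return _CATEGORY_ALIASES[key]
        allowed = sorted({*(c.value for c in cls), *_SHORT_ALIASES})
        raise ParseError(
            f"unknown sample category {text!r}; allowed values (case-insensitive): "
            + ", ".join(allowed)
        )


NEGATIVE_CONTROL_CATEGORIES = frozenset(
    {
        SampleCategory.HOMOGENIZATION_CONTROL,
        SampleCategory.EXTRACTION_CONTROL,
        SampleCategory.AMPLIFICATION_CONTROL,
    }
)
TICK_CATEGORIES = frozenset(
    {SampleCategory.NYMPH, SampleCategory.MALE, SampleCategory.FEMALE}
)

_SHORT_ALIASES = {
    "hc": SampleCategory.HOMOGENIZATION_CONTROL,
    "ec": SampleCategory.EXTRACTION_CONTROL,
    "ac": SampleCategory.AMPLIFICATION_CONTROL,
    "pc": SampleCategory.POSITIVE_CONTROL,
}
_CATEGORY_ALIASES = {c.value: c for c in SampleCategory} | _SHORT_ALIASES


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample metadata record."""

    sample_id: str
    category: SampleCategory

    @property
    def is_negative_control(self) -> bool:
        return self.category.is_negative_control


@dataclass(frozen=True)
class Lineage:
    """Ranked taxonomic assignment of one OTU (7 ranks, padded with 'unknown')."""

    otu_id: str
    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != N_RANKS:
            raise ValueError(
                f"lineage for {self.otu_id!r} has {len(self.ranks)} ranks, expected {N_RANKS}"
            )

    @classmethod
    def from_parts(cls, otu_id: str, parts: Sequence[str]) -> "Lineage":
        parts = [p.strip() for p in parts if p is not None]
        if len(parts) > N_RANKS:
            parts = parts[:N_RANKS]
        parts = parts + ["unknown"] * (N_RANKS - len(parts))
        parts = [p if p else "unknown" for p in parts]
        return cls(otu_id=otu_id, ranks=tuple(parts))

    @property
    def domain(self) -> str:
        return self.ranks[0]

    def is_organellar(self) -> bool:
        """True if any rank names mitochondria or chloroplast (case-insensitive)."""
        lowered = [r.lower() for r in self.ranks]
        return any(r in ("mitochondria", "chloroplast") for r in lowered)

    def is_domain_unaffiliated(self) -> bool:
        return self.domain.lower() in SENTINELS


class CountTable:
    """Integer OTU x sample count matrix with ordered identifiers.

    Rows are OTUs, columns are samples. Counts are non-negative integers.
    The table is immutable from the caller's perspective: all operations
    return new tables.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate OTU identifiers: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample identifiers: {dupes}")
        arr = data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))
                r, c = bad[0]
                raise ParseError(
                    f"non-integer count at OTU {data.index[r]!r}, sample {data.columns[c]!r}"
                )
        if arr.size and (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative count at OTU {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        self._data = data.astype(np.int64, copy=True)
        self._data.index = self._data.index.astype(str)
        self._data.columns = self._data.columns.astype(str)

    # -- construction ------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        counts: np.ndarray,
        otu_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> "CountTable":
        df = pd.DataFrame(np.asarray(counts), index=list(otu_ids), columns=list(sample_ids))
        return cls(df)

    # -- accessors ---------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data.copy()

    @property
    def otu_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self._data.to_numpy(copy=True)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def otu_totals(self) -> pd.Series:
        """Dataset-wide total per OTU (row sums)."""
        return self._data.sum(axis=1)

    def sample_totals(self) -> pd.Series:
        """Sequencing depth per sample (column sums)."""
        return self._data.sum(axis=0)

    def grand_total(self) -> int:
        return int(self._data.to_numpy().sum())

    def select_otus(self, otu_ids: Iterable[str]) -> "CountTable":
        keep = [o for o in self.otu_ids if o in set(otu_ids)]
        return CountTable(self._data.loc[keep])

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return CountTable(self._data[keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"CountTable({n} OTUs x {m} samples, {self.grand_total()} sequences)"


@dataclass
class Dataset:
    """A count table together with its sample metadata, taxonomy and optional tree."""

    table: CountTable
    metadata: dict[str, SampleInfo]
    taxonomy: dict[str, Lineage]
    tree: Optional[skbio.TreeNode] = None

    def __post_init__(self) -> None:
        missing_meta = [s for s in self.table.sample_ids if s not in self.metadata]
        if missing_meta:
            raise ValueError(f"samples without metadata: {missing_meta}")
        missing_tax = [o for o in self.table.otu_ids if o not in self.taxonomy]
        if missing_tax:
            raise ValueError(f"OTUs without taxonomy: {missing_tax}")

    def negative_control_ids(self) -> list[str]:
        return [
            s for s in self.table.sample_ids if self.metadata[s].is_negative_control
        ]

    def specimen_ids(self) -> list[str]:
        return [
            s for s in self.table.sample_ids if self.metadata[s].category.is_specimen
        ]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, format: str = "tsv", transposed: bool = False) -> CountTable:
    """Read an OTU table.

    TSV dialect: first column = OTU id, header row = sample ids,
    tab-separated. With ``transposed=True`` rows are samples instead.
    BIOM files are read as BIOM 2.1 (HDF5).
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas message forwarded
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        df.index = df.index.astype(str)
        try:
            num = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-numeric cell in {path}: {exc}") from exc
        if transposed:
            num = num.T
        return CountTable(num)
    if format == "biom":
        with h5py.File(path, "r") as fh:
            biom = _BiomTable.from_hdf5(fh)
        dense = np.asarray(biom.matrix_data.todense())
        return CountTable.from_arrays(
            np.rint(dense).astype(np.int64),
            [str(i) for i in biom.ids("observation")],
            [str(i) for i in biom.ids("sample")],
        )
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'biom'")


def write_count_table(table: CountTable, path: str | Path, format: str = "tsv") -> None:
    """Write a count table; the file round-trips to an equal table."""
    path = Path(path)
    if format == "tsv":
        df = table.data
        df.index.name = "otu_id"
        df.to_csv(path, sep="\t")
        return
    if format == "biom":
        biom = _BiomTable(
            table.counts, observation_ids=table.otu_ids, sample_ids=table.sample_ids
        )
        with h5py.File(path, "w") as fh:
            biom.to_hdf5(fh, generated_by="tickdecon")
        return
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'biom'")


def read_metadata(path: str | Path) -> dict[str, SampleInfo]:
    """Read a two-column TSV (sample_id, category) into SampleInfo records.

    Category strings are case-insensitive; the short aliases HC, EC, AC and
    PC are accepted for the control categories.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" not in cols or "category" not in cols:
        raise ParseError(
            f"metadata file {path} must have columns 'sample_id' and 'category'"
        )
    df.columns = cols
    out: dict[str, SampleInfo] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        if sid in out:
            raise ParseError(f"duplicate sample_id {sid!r} in metadata")
        out[sid] = SampleInfo(sample_id=sid, category=SampleCategory.parse(row["category"]))
    return out


def write_metadata(metadata: Mapping[str, SampleInfo], path: str | Path) -> None:
    rows = [(info.sample_id, info.category.value) for info in metadata.values()]
    pd.DataFrame(rows, columns=["sample_id", "category"]).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> dict[str, Lineage]:
    """Read a taxonomy TSV: otu_id then ranks, either as further tab-separated
    columns or as a single semicolon-separated lineage string. Fewer than 7
    ranks are padded with ``unknown``."""
    out: dict[str, Lineage] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if line_no == 1 and parts[0].strip().lower() in ("otu_id", "otu", "#otu id"):
                continue
            otu_id = parts[0].strip()
            rest = parts[1:]
            if len(rest) == 1 and ";" in rest[0]:
                rest = rest[0].split(";")
            if otu_id in out:
                raise ParseError(f"duplicate otu_id {otu_id!r} in taxonomy (line {line_no})")
            out[otu_id] = Lineage.from_parts(otu_id, rest)
    return out


def write_taxonomy(taxonomy: Mapping[str, Lineage], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\t" + "\t".join(RANK_NAMES) + "\n")
        for lineage in taxonomy.values():
            fh.write(lineage.otu_id + "\t" + "\t".join(lineage.ranks) + "\n")


def read_tree(path: str | Path, table: Optional[CountTable] = None) -> skbio.TreeNode:
    """Read a rooted Newick tree. Leaves absent from ``table`` (if given) are
    tolerated with a warning; they are simply ignored by phylogenetic
    diversity."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    if table is not None:
        leaf_names = {t.name for t in tree.tips()}
        extra = leaf_names - set(table.otu_ids)
        if extra:
            warnings.warn(
                f"tree has {len(extra)} leaves not present in the count table; "
                "they are ignored in phylogenetic diversity",
                stacklevel=2,
            )
    return tree


# ---------------------------------------------------------------------------
# table-level pre-filters
# ---------------------------------------------------------------------------

def filter_rare_otus(table: CountTable, fraction: float = 0.00005) -> CountTable:
    """Remove OTUs whose dataset-wide total is below ``fraction`` of the grand
    total.

    The grand total is computed over all samples present (specimens and
    controls alike) before any removal, and an OTU is retained iff its total
    is >= fraction * grand_total; strictly rarer OTUs are dropped. The
    default of 0.005% reflects a commonly applied abundance floor for
    amplicon OTU tables.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    threshold = fraction * table.grand_total()
    totals = table.otu_totals()
    keep = totals[totals >= threshold].index
    return table.select_otus(keep)


def filter_nonprokaryotic(table: CountTable, taxonomy: Mapping[str, Lineage]) -> CountTable:
    """Remove organellar OTUs (mitochondria / chloroplast at any rank) and
    OTUs with no domain-level affiliation ('unknown' or 'multi-affiliated')."""
    missing = [o for o in table.otu_ids if o not in taxonomy]
    if missing:
        raise ValueError(f"taxonomy missing for OTUs: {missing}")
    keep = [
        o
        for o in table.otu_ids
        if not taxonomy[o].is_organellar() and not taxonomy[o].is_domain_unaffiliated()
    ]
    return table.select_otus(keep)


def summarize_by_category(dataset: Dataset) -> pd.DataFrame:
    """Per-category mean and sample (n-1) standard deviation of per-sample
    sequence totals and observed OTU counts.

    The standard deviation is NaN for categories holding a single sample.
    """
    depths = dataset.table.sample_totals()
    richness = (dataset.table.data > 0).sum(axis=0)
    rows = []
    cats = pd.Series(
        {s: dataset.metadata[s].category.value for s in dataset.table.sample_ids}
    )
    for cat, samples in cats.groupby(cats):
        ids = samples.index
        d = depths[ids]
        r = richness[ids]
        rows.append(
            {
                "category": cat,
                "n_samples": len(ids),
                "mean_depth": d.mean(),
                "sd_depth": d.std(ddof=1) if len(ids) > 1 else np.nan,
                "mean_observed_otus": r.mean(),
                "sd_observed_otus": r.std(ddof=1) if len(ids) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")
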