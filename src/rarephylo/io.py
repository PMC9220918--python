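"""Readers and writers for the on-disk artifacts of an amplicon diversity analysis.

The pipeline's currency is a samples x ASVs table of integer read counts
(:class:`CommunityTable`), a rooted Newick phylogeny over the ASVs
(``skbio.TreeNode``), a per-sample transect position table, an optional
ranked-taxonomy table, and labelled TSV distance matrices
(``skbio.DistanceMatrix``, lsmat format).  Everything on disk is plain
delimited text.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTable",
    "TaxonomyTable",
    "SampleMetadata",
    "read_community_table",
    "read_tree",
    "write_tree",
    "read_taxonomy",
    "read_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_report",
]


class TableFormatError(ValueError):
    """Raised when a delimited input file violates the expected schema."""


@dataclass
class CommunityTable:
    """A samples x ASVs matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        Integer array of shape ``(n_samples, n_asvs)``.
    sample_ids, asv_ids
        Unique identifiers for the rows and columns, in order.
    """

    counts: np.ndarray
    sample_ids: list[str]
    asv_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise TableFormatError("counts must be integers")
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableFormatError(
                f"negative count at sample {self.sample_ids[i]!r}, ASV {self.asv_ids[j]!r}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableFormatError("duplicate sample identifiers")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise TableFormatError("duplicate ASV identifiers")
        n_s, n_a = self.counts.shape
        if n_s != len(self.sample_ids) or n_a != len(self.asv_ids):
            raise TableFormatError("identifier lists do not match the count matrix shape")
        if n_s < 1 or n_a < 1:
            raise TableFormatError("need at least one sample and one ASV")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def present_asvs(self, sample_id: str) -> set[str]:
        """ASVs with nonzero count in *sample_id*."""
        row = self.sample_counts(sample_id)
        return {self.asv_ids[j] for j in np.flatnonzero(row)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommunityTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def select_asvs(self, asv_ids: Sequence[str]) -> "CommunityTable":
        idx = [self.asv_ids.index(a) for a in asv_ids]
        return CommunityTable(self.counts[:, idx], list(self.sample_ids), list(asv_ids))

    def write(self, path: str | Path, orientation: str = "samples_as_rows") -> None:
        df = self.to_frame()
        if orientation == "samples_as_columns":
            df = df.T
        df.index.name = "#ID"
        df.to_csv(path, sep="\t")


@dataclass
class TaxonomyTable:
    """ASV -> ranked lineage (kingdom ... genus); ranks may be empty."""

    lineages: pd.DataFrame  # index asv_id, columns ranks (or a single 'Taxon' column)

    def __post_init__(self) -> None:
        if self.lineages.index.has_duplicates:
            raise TableFormatError("duplicate ASV id in taxonomy table")

    def __len__(self) -> int:
        return len(self.lineages)

    def rank_of(self, asv_id: str, rank: str) -> str:
        return str(self.lineages.loc[asv_id, rank])

    def genus_map(self) -> dict[str, str]:
        """Map ASV -> genus label; unclassified ASVs map to 'unclassified'."""
        cols = {c.lower(): c for c in self.lineages.columns}
        if "genus" in cols:
            s = self.lineages[cols["genus"]]
        else:
            # single lineage string: take the last ';'-separated field
            first = self.lineages.columns[0]
            s = self.lineages[first].astype(str).str.split(";").str[-1].str.strip()
        s = s.fillna("").replace("", "unclassified")
        return {str(k): str(v) for k, v in s.items()}


@dataclass
class SampleMetadata:
    """Per-sample positions (metres) along a linear transect."""

    positions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, pos in self.positions.items():
            if not np.isfinite(pos):
                raise TableFormatError(f"non-finite position for sample {sid!r}")

    def position(self, sample_id: str) -> float:
        if sample_id not in self.positions:
            raise KeyError(f"no transect position for sample {sample_id!r}")
        return self.positions[sample_id]


# ---------------------------------------------------------------------------
# community tables

def _is_count_column(col: pd.Series) -> bool:
    vals = pd.to_numeric(col, errors="coerce")
    if vals.isna().any():
        return False
    return bool(((vals >= 0) & (vals == np.round(vals))).all())


def read_community_table(
    path: str | Path,
    orientation: str = "auto",
    tip_labels: Iterable[str] | None = None,
) -> tuple[CommunityTable, TaxonomyTable | None]:
    """Read a TSV community composition table, splitting off taxonomy columns.

    Trailing non-numeric columns (e.g. a ``Taxon`` lineage column) are returned
    as a :class:`TaxonomyTable`; they are never mixed into the counts.

    Parameters
    ----------
    orientation
        ``samples_as_rows``, ``samples_as_columns`` or ``auto``.  Auto-detection
        prefers *tip_labels* (the axis whose labels overlap the tree tips is the
        ASV axis); without tips the shorter axis is taken as samples, the usual
        shape of a deposited ASV table.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise TableFormatError(f"{path}: duplicate row identifiers")
    if df.columns.has_duplicates:
        raise TableFormatError(f"{path}: duplicate column identifiers")

    numeric_mask = [_is_count_column(df[c]) for c in df.columns]
    tax_cols = [c for c, ok in zip(df.columns, numeric_mask) if not ok]
    count_cols = [c for c, ok in zip(df.columns, numeric_mask) if ok]
    if not count_cols:
        raise TableFormatError(f"{path}: no numeric count columns found")
    for c in tax_cols:
        # only trailing, predominantly-text columns are taxonomy; a column
        # amid the counts, or one that is mostly numeric with stray text,
        # signals a malformed count cell
        parsed = pd.to_numeric(df[c], errors="coerce")
        mostly_numeric = parsed.notna().mean() >= 0.5
        if df.columns.get_loc(c) < df.columns.get_loc(count_cols[-1]) or mostly_numeric:
            bad = df[c][parsed.isna() | (parsed < 0) | (parsed != np.round(parsed))]
            raise TableFormatError(
                f"{path}: invalid count cell in column {c!r}, row {bad.index[0]!r}"
            )

    counts = df[count_cols].apply(pd.to_numeric).astype(np.int64)
    taxonomy = None
    if tax_cols:
        taxonomy = TaxonomyTable(df[tax_cols].copy())

    if orientation == "auto":
        orientation = _detect_orientation(counts, tip_labels)
    if orientation == "samples_as_columns":
        counts = counts.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    table = CommunityTable.from_frame(counts)
    logger.info(
        "read %s: %d samples x %d ASVs%s",
        path, table.n_samples, table.n_asvs,
        f", {len(taxonomy)} taxonomy entries" if taxonomy else "",
    )
    return table, taxonomy


def _detect_orientation(counts: pd.DataFrame, tip_labels: Iterable[str] | None) -> str:
    if tip_labels is not None:
        tips = set(map(str, tip_labels))
        row_hits = len(tips & set(map(str, counts.index)))
        col_hits = len(tips & set(map(str, counts.columns)))
        if row_hits > col_hits:
            return "samples_as_columns"  # rows are ASVs
        if col_hits > row_hits:
            return "samples_as_rows"
    return "samples_as_rows" if counts.shape[0] <= counts.shape[1] else "samples_as_columns"


# ---------------------------------------------------------------------------
# trees

def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick phylogeny; missing branch lengths become 0 (warned)."""
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        seen, dups = set(), set()
        for t in tips:
            (dups if t in seen else seen).add(t)
        raise TableFormatError(f"{path}: duplicate tip labels {sorted(dups)!r}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise TableFormatError(f"{path}: negative branch length on {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        warnings.warn(f"{path}: {n_missing} branch lengths missing, set to 0")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# taxonomy / metadata

def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyTable(df)


def read_metadata(path: str | Path) -> SampleMetadata:
    """TSV with columns ``sample_id`` and ``position_m``."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    sid = cols.get("sample_id", df.columns[0])
    pos = cols.get("position_m", df.columns[1])
    if df[sid].duplicated().any():
        raise TableFormatError(f"{path}: duplicate sample_id")
    return SampleMetadata(dict(zip(df[sid].astype(str), df[pos].astype(float))))


# ---------------------------------------------------------------------------
# distance matrices & reports

def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a labelled square TSV; symmetry is guaranteed by the type."""
    dm.write(str(path))


def write_report(results: Iterable, path: str | Path) -> None:
    """Write a TSV report, one row per result record (dataclass or mapping)."""
    rows = []
    for r in results:
        if hasattr(r, "__dataclass_fields__"):
            rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
        else:
            rows.append(dict(r))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
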