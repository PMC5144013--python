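"""Count tables, metadata, trees and distance matrices.

The exchange objects of the pipeline are a sample-by-taxon integer count
table (:class:`TaxonTable`), its row-normalised counterpart
(:class:`RelAbundanceTable`), a pandas DataFrame of per-sample metadata,
a rooted :class:`skbio.TreeNode` with branch lengths, and a
:class:`skbio.DistanceMatrix`.  File formats are the classic dense OTU
TSV (taxa as rows, ``#TaxonID`` header cell), a metadata TSV with
``sample_id``/``group``/optional ``timepoint`` columns, Newick, and a
square distance-matrix TSV with an id header row and column.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode


class FormatError(ValueError):
    """A file or in-memory object violates the expected format."""


TABLE_HEADER = "#TaxonID"


def _check_axis(values, what: str) -> None:
    if len(values) == 0:
        raise FormatError(f"table must have at least one {what}")
    if len(set(values)) != len(values):
        dups = sorted({v for v in values if list(values).count(v) > 1})
        raise FormatError(f"duplicate {what} ids: {dups}")


@dataclass(frozen=True)
class TaxonTable:
    """Integer counts, samples x taxa.

    ``counts`` is a pandas DataFrame indexed by sample id with taxon ids
    as columns; values are non-negative integers.  Zero-count taxa are
    retained — dropping them silently would change UniFrac denominators.
    """

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts
        _check_axis(list(df.index), "sample")
        _check_axis(list(df.columns), "taxon")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.rint(vals), atol=0, rtol=0):
                raise FormatError("counts must be integers")
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            vals = df.to_numpy()
        if (vals < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_relative(self) -> "RelAbundanceTable":
        return to_relative(self)


@dataclass(frozen=True)
class RelAbundanceTable:
    """Relative abundances on the per-sample simplex (rows sum to 1)."""

    fractions: pd.DataFrame

    def __post_init__(self):
        df = self.fractions
        _check_axis(list(df.index), "sample")
        _check_axis(list(df.columns), "taxon")
        vals = df.to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1).any():
            raise FormatError("relative abundances must lie in [0, 1]")
        rowsums = vals.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            bad = df.index[np.abs(rowsums - 1.0) > 1e-9][0]
            raise FormatError(f"row for sample {bad!r} does not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.fractions.columns)


def to_relative(table: TaxonTable) -> RelAbundanceTable:
    """Divide each sample's counts by its library size."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"cannot normalise sample(s) with zero total counts: {list(zero.index)}"
        )
    frac = table.counts.div(totals, axis=0).astype(float)
    return RelAbundanceTable(frac)


# ---------------------------------------------------------------------------
# Count-table TSV (classic dense OTU table dialect)
# ---------------------------------------------------------------------------

def read_taxon_table(path, taxa_as_rows: bool = True,
                     round_counts: bool = False) -> TaxonTable:
    """Read a dense TSV count table.

    Default layout is the classic OTU table: first column taxon ids
    (header cell ``#TaxonID``), remaining columns samples.  Set
    ``taxa_as_rows=False`` for the transposed layout.  Non-integer
    numeric cells are rejected unless ``round_counts`` is set, in which
    case they are rounded to the nearest integer.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"empty table file: {path}")
    header = text.splitlines()[0].rstrip("\n").split("\t")
    _check_axis(header[1:], "column")
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse table {path}: {exc}") from exc
    _check_axis(list(df.index), "row")
    try:
        vals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.isfinite(vals).all():
        raise FormatError(f"non-finite cell in {path}")
    if (vals < 0).any():
        raise FormatError(f"negative count in {path}")
    if not np.array_equal(vals, np.rint(vals)):
        if not round_counts:
            raise FormatError(
                f"non-integer counts in {path} (pass round_counts=True to round)"
            )
        vals = np.rint(vals)
    df = pd.DataFrame(vals.astype(np.int64), index=df.index.astype(str),
                      columns=df.columns.astype(str))
    if taxa_as_rows:
        df = df.T
    df.index.name = None
    df.columns.name = None
    return TaxonTable(df)


def write_taxon_table(table: TaxonTable, path, taxa_as_rows: bool = True) -> None:
    df = table.counts.T if taxa_as_rows else table.counts
    df = df.copy()
    df.index.name = TABLE_HEADER if taxa_as_rows else "#SampleID"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if "group" not in meta.columns:
        raise FormatError("metadata must have a 'group' column")
    _check_axis(list(meta.index), "sample")
    if meta["group"].isna().any():
        raise FormatError("metadata has samples with missing group labels")
    return meta


def read_sample_metadata(path) -> pd.DataFrame:
    """Read metadata TSV with columns sample_id, group[, timepoint]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: first column must be named 'sample_id'")
    df = df.set_index("sample_id")
    return validate_metadata(df)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column ids differ")
    try:
        return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))
    except Exception as exc:
        raise FormatError(f"{path}: not a valid distance matrix: {exc}") from exc


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path_or_str) -> TreeNode:
    """Read a rooted Newick tree with branch lengths.

    Missing branch lengths become 0 with a warning; an unrooted basal
    trifurcation is kept as the root.  Duplicate leaf labels are an
    error.
    """
    src = str(path_or_str)
    try:
        if "(" in src and ")" in src:  # raw newick string
            tree = TreeNode.read(io.StringIO(src), format="newick")
        else:
            tree = TreeNode.read(src, format="newick")
    except Exception as exc:
        raise FormatError(f"cannot parse Newick input: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if any(n is None for n in names):
        raise FormatError("tree has unlabeled leaves")
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate leaf labels: {dups}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif not np.isfinite(node.length) or node.length < 0:
            raise FormatError(f"invalid branch length on node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        warnings.warn(f"{n_missing} missing branch length(s) set to 0")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(n.length or 0.0 for n in tree.traverse(include_self=False)))


def align_to_tree(table: TaxonTable, tree: TreeNode,
                  strict: bool = True) -> TaxonTable:
    """Check that all table taxa are tree leaves.

    In strict mode a missing taxon is an error; otherwise missing taxa
    are pruned from the table with a warning (silent pruning would
    distort UniFrac, so the default is strict).
    """
    leaves = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in leaves]
    if not missing:
        return table
    if strict:
        raise ValueError(f"taxa absent from the tree: {missing}")
    warnings.warn(f"pruning {len(missing)} taxa absent from the tree: {missing}")
    kept = [t for t in table.taxon_ids if t in leaves]
    if not kept:
        raise ValueError("no table taxa remain after pruning against the tree")
    return TaxonTable(table.counts[kept])


# ---------------------------------------------------------------------------
# Rank collapsing
# ---------------------------------------------------------------------------

def collapse_by_prefix(table: TaxonTable, levels: int, sep: str = ";") -> TaxonTable:
    """Sum counts over taxa sharing their first ``levels`` lineage fields.

    Taxon ids are treated as ``sep``-joined lineage strings
    (e.g. ``k__Bacteria;p__...;g__Odoribacter``); ids with fewer fields
    collapse to themselves.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    prefixes = [sep.join(t.split(sep)[:levels]) for t in table.taxon_ids]
    collapsed = table.counts.T.groupby(prefixes, sort=False).sum().T
    return TaxonTable(collapsed)
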