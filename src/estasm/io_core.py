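"""Reading, validation, alignment and rarefaction of the core inputs.

The pipeline operates on three aligned objects: a samples x taxa integer
count table (ASV table), a rooted phylogeny with branch lengths whose tips
cover the taxa, and a per-sample metadata frame carrying the environmental
and nutrient variables plus the salinity-group / season / year labels.
Everything downstream assumes the objects produced here are mutually
consistent: same sample order everywhere, tree pruned to the table's taxa,
all rows rarefied to a common depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("estasm")

#: Nutrient variables entering the multi-nutrient cycling index by default:
#: phosphorus (TP, DIP), nitrogen (NO3-N, NO2-N, NH4-N, DIN, TN) and carbon (TOC).
MNI_FACTORS = ["TP", "DIP", "NO3-N", "NO2-N", "NH4-N", "DIN", "TN", "TOC"]

#: Water-property variables (the PLS-PM "WP" block).
WP_VARIABLES = ["temperature", "salinity", "pH", "Chl-a"]

#: Full numeric metadata schema expected by the association panels.
METADATA_VARIABLES = WP_VARIABLES + ["DO", "COD"] + MNI_FACTORS

CATEGORICAL_LABELS = ["salinity_group", "season", "year"]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer read counts.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers (rows).
    taxon_ids : list of str
        Ordered, unique taxon (ASV) identifiers (columns).
    counts : ndarray of int, shape (n_samples, n_taxa)
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D samples x taxa matrix")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        # column subsets (e.g. a single-taxon subcommunity) may be narrow,
        # but a table needs at least 2 samples to compare
        if counts.shape[0] < 2 or counts.shape[1] < 1:
            raise ValidationError("need at least 2 samples and 1 taxon")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        if np.issubdtype(counts.dtype, np.floating):
            bad = ~np.isfinite(counts)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-finite count at sample {self.sample_ids[i]!r}, "
                    f"taxon {self.taxon_ids[j]!r}"
                )
            if not np.allclose(counts, np.round(counts)):
                i, j = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, "
                    f"taxon {self.taxon_ids[j]!r}: {counts[i, j]!r} "
                    "(relative-abundance tables are rejected; provide raw reads)"
                )
            counts = np.round(counts).astype(np.int64)
        elif not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError(f"counts dtype {counts.dtype} is not numeric integer")
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)

    # -- accessors ----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def depth(self) -> np.ndarray:
        """Per-sample read totals (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        """Grand total of reads in the table."""
        return int(self.counts.sum())

    def relative(self) -> np.ndarray:
        """Row-normalized relative abundances."""
        depth = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / depth[:, None]
        rel[depth == 0] = 0.0
        return rel

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return CountTable(list(ids), list(self.taxon_ids), self.counts[idx])

    def select_taxa(self, ids: Sequence[str]) -> "CountTable":
        pos = {t: k for k, t in enumerate(self.taxon_ids)}
        idx = [pos[t] for t in ids]
        return CountTable(list(self.sample_ids), list(ids), self.counts[:, idx])


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def read_count_table(path, format: str = "tsv", transpose: bool = False) -> CountTable:
    """Read a count table.

    TSV dialect: first column holds sample ids, header row holds taxon ids.
    ``transpose=True`` accepts the taxa x samples orientation. Only integer
    counts are accepted; relative-abundance tables are rejected.
    """
    if format == "biom":
        raise NotImplementedError(
            "BIOM support requires the 'biom-format' package, which is not "
            "installed; convert to TSV"
        )
    if format != "tsv":
        raise ValueError(f"unknown count-table format: {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicate taxon id: {dup!r}")
    if transpose:
        df = df.T
    if df.isna().any().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(
            f"NaN count at sample {df.index[loc[0]]!r}, taxon {df.columns[loc[1]]!r}"
        )
    if df.shape[1] < 2:
        raise ValidationError("count table needs at least 2 taxa")
    return CountTable.from_dataframe(df)


def write_count_table(table: CountTable, path) -> None:
    table.to_dataframe().rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


def read_tree(path, allow_unrooted: bool = False) -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    A trifurcating (unrooted-style) root is rejected unless ``allow_unrooted``
    is set, in which case the tree is midpoint-rooted (logged).
    """
    tree = TreeNode.read(str(path) if not hasattr(path, "read") else path)
    return validate_tree(tree, allow_unrooted=allow_unrooted)


def validate_tree(tree: TreeNode, allow_unrooted: bool = False) -> TreeNode:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            name = node.name or "<internal>"
            raise ValidationError(f"branch without length above node {name!r}")
        if node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    if len(tree.children) > 2:
        if not allow_unrooted:
            raise ValidationError(
                "tree root is not bifurcating (unrooted newick?); pass "
                "allow_unrooted=True to midpoint-root it"
            )
        logger.info("midpoint-rooting unrooted input tree")
        tree = tree.root_at_midpoint()
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


def patristic_matrix(tree: TreeNode):
    """Tip-to-tip (patristic) distance matrix as a skbio DistanceMatrix."""
    return tree.tip_tip_distances()


# ---------------------------------------------------------------------------
# SampleFrame (metadata)
# ---------------------------------------------------------------------------


def read_metadata(path, require_mni: bool = True,
                  numeric: Iterable[str] | None = None) -> pd.DataFrame:
    """Read the per-sample metadata TSV into a frame indexed by sample id.

    Declared numeric columns are coerced; coercion failure is a hard error.
    Unknown columns are carried through untouched as opaque extras.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id in metadata: {dup!r}")
    numeric = list(numeric) if numeric is not None else [
        c for c in METADATA_VARIABLES if c in frame.columns
    ]
    for col in numeric:
        if col not in frame.columns:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            raise ValidationError(
                f"metadata column {col!r} has non-numeric values in samples "
                f"{list(frame.index[bad])[:5]}"
            )
        frame[col] = coerced
    if require_mni:
        missing = [c for c in MNI_FACTORS if c not in frame.columns]
        if missing:
            raise ValidationError(
                f"metadata is missing MNI factor columns: {', '.join(missing)}"
            )
    return frame


def write_metadata(frame: pd.DataFrame, path) -> None:
    frame.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Taxonomy map
# ---------------------------------------------------------------------------


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxon_id -> (phylum, class) TSV; missing ranks allowed."""
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    tax.index = tax.index.astype(str)
    for rank in ("phylum", "class"):
        if rank not in tax.columns:
            raise ValidationError(f"taxonomy file lacks a {rank!r} column")
    return tax


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.rename_axis("taxon_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    """Bookkeeping of what alignment dropped."""

    dropped_samples_table: list[str] = field(default_factory=list)
    dropped_samples_meta: list[str] = field(default_factory=list)
    pruned_tips: list[str] = field(default_factory=list)


def align(table: CountTable, frame: pd.DataFrame | None = None,
          tree: TreeNode | None = None):
    """Align table, metadata and tree to a common, identically ordered sample
    set and prune the tree to the table's taxa.

    Returns ``(table, frame, tree, report)``; ``frame``/``tree`` come back as
    ``None`` when not supplied. Raises if the sample intersection is empty or
    the tree is missing any table taxon.
    """
    report = AlignmentReport()
    sample_ids = list(table.sample_ids)
    if frame is not None:
        meta_ids = set(frame.index)
        keep = [s for s in sample_ids if s in meta_ids]
        if not keep:
            raise ValidationError("no samples shared between table and metadata")
        report.dropped_samples_table = [s for s in sample_ids if s not in meta_ids]
        report.dropped_samples_meta = [s for s in frame.index if s not in set(keep)]
        sample_ids = keep
        frame = frame.loc[sample_ids]
        if report.dropped_samples_table:
            logger.warning(
                "alignment dropped %d table samples without metadata",
                len(report.dropped_samples_table),
            )
    if sample_ids != list(table.sample_ids):
        table = table.select_samples(sample_ids)
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = [t for t in table.taxon_ids if t not in tips]
        if missing:
            raise ValidationError(
                f"tree is missing {len(missing)} table taxa, e.g. {missing[:5]}"
            )
        extra = sorted(tips - set(table.taxon_ids))
        if extra:
            tree = tree.shear(table.taxon_ids)
            report.pruned_tips = extra
            logger.info("pruned %d extra tree tips", len(extra))
    return table, frame, tree, report


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def rarefy(table: CountTable, depth: int | str = "min", seed: int = 0,
           drop_below: bool = False) -> CountTable:
    """Subsample every sample without replacement to a common depth.

    Each row is an exact multivariate-hypergeometric draw (a single draw per
    sample, not an average over draws), reproducible under ``seed``.
    ``depth="min"`` uses the minimum row sum. Samples below the requested
    depth are dropped with a warning when ``drop_below`` is set, otherwise
    they are an error.
    """
    totals = table.depth
    if depth == "min":
        d = int(totals.min())
    else:
        d = int(depth)
        if d <= 0:
            raise ValidationError("rarefaction depth must be positive")
    low = totals < d
    keep = list(table.sample_ids)
    counts = table.counts
    if low.any():
        names = [s for s, flag in zip(table.sample_ids, low) if flag]
        if not drop_below:
            raise ValidationError(
                f"samples below rarefaction depth {d}: {names[:5]} "
                "(pass drop_below=True to drop them)"
            )
        warnings.warn(f"dropping {len(names)} samples below depth {d}")
        keep = [s for s in table.sample_ids if s not in set(names)]
        counts = counts[~low]
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        if row.sum() == d:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, d)
    return CountTable(keep, list(table.taxon_ids), out)
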