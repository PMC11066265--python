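"""Abundant / rare / intermediate subcommunity partitioning.

Taxa are classified by relative abundance: abundant above 0.1%, rare below
0.01%, intermediate in the closed band between (boundary values fall in the
intermediate class because the outer classes are defined by strict
inequalities). The default basis is the dataset-wide fraction — a taxon's
summed reads over all reads — with mean per-sample relative abundance
available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CountTable, ValidationError

CLASSES = ("abundant", "intermediate", "rare")


@dataclass
class PartitionResult:
    """Per-taxon class labels plus the relative abundances that produced them."""

    labels: pd.Series          # taxon_id -> class label
    rel_abundance: pd.Series   # taxon_id -> fraction on the declared basis
    basis: str
    abundant_threshold: float
    rare_threshold: float

    def taxa(self, which: str) -> list[str]:
        if which not in CLASSES:
            raise ValueError(f"unknown class {which!r}")
        return list(self.labels.index[self.labels == which])


def classify_taxa(table: CountTable, abundant_threshold: float = 0.001,
                  rare_threshold: float = 0.0001,
                  basis: str = "dataset_total") -> PartitionResult:
    """Label every taxon abundant (> abundant_threshold), rare
    (< rare_threshold) or intermediate (the closed band between).

    ``basis="dataset_total"`` uses summed reads / all reads;
    ``basis="per_sample_mean"`` uses the mean of per-sample relative
    abundances. All-zero taxa are labeled rare with a warning.
    """
    if not (0.0 < rare_threshold < abundant_threshold < 1.0):
        raise ValidationError(
            "thresholds must satisfy 0 < rare_threshold < abundant_threshold < 1"
        )
    if basis == "dataset_total":
        frac = table.counts.sum(axis=0) / table.total
    elif basis == "per_sample_mean":
        frac = table.relative().mean(axis=0)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    labels = np.full(table.n_taxa, "intermediate", dtype=object)
    labels[frac > abundant_threshold] = "abundant"
    labels[frac < rare_threshold] = "rare"
    zero = table.counts.sum(axis=0) == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero taxa labeled rare", stacklevel=2
        )
        labels[zero] = "rare"
    idx = pd.Index(table.taxon_ids, name="taxon_id")
    return PartitionResult(
        labels=pd.Series(labels, index=idx, name="label"),
        rel_abundance=pd.Series(frac, index=idx, name="rel_abundance"),
        basis=basis,
        abundant_threshold=abundant_threshold,
        rare_threshold=rare_threshold,
    )


def summarize_partition_counts(n_taxa: dict[str, int],
                               n_sequences: dict[str, int]) -> pd.DataFrame:
    """Class-level bookkeeping from raw integer counts.

    Percentages are of the dataset totals, rounded to 2 decimals for
    reporting; the unrounded columns are retained alongside.
    """
    classes = [c for c in CLASSES if c in n_taxa]
    total_taxa = sum(n_taxa[c] for c in classes)
    total_seqs = sum(n_sequences[c] for c in classes)
    rows = []
    for c in classes:
        pct_taxa = 100.0 * n_taxa[c] / total_taxa
        pct_seqs = 100.0 * n_sequences[c] / total_seqs
        rows.append({
            "class": c,
            "n_taxa": int(n_taxa[c]),
            "pct_taxa": round(pct_taxa, 2),
            "n_sequences": int(n_sequences[c]),
            "pct_sequences": round(pct_seqs, 2),
            "pct_taxa_exact": pct_taxa,
            "pct_sequences_exact": pct_seqs,
        })
    return pd.DataFrame(rows).set_index("class")


def partition_summary(partition: PartitionResult, table: CountTable) -> pd.DataFrame:
    """Per-class taxon and sequence totals with dataset-wide percentages."""
    if list(partition.labels.index) != list(table.taxon_ids):
        raise ValidationError("partition does not match table taxa")
    col_sums = table.counts.sum(axis=0)
    n_taxa: dict[str, int] = {}
    n_seqs: dict[str, int] = {}
    for c in CLASSES:
        mask = (partition.labels == c).to_numpy()
        n_taxa[c] = int(mask.sum())
        n_seqs[c] = int(col_sums[mask].sum())
    return summarize_partition_counts(n_taxa, n_seqs)


def subcommunity_table(table: CountTable, partition: PartitionResult,
                       which: str) -> CountTable:
    """Column subset of the table holding one class; samples unchanged.

    Samples with zero reads in the class are retained (with a warning) so the
    sample set stays aligned with the metadata.
    """
    taxa = partition.taxa(which)
    if not taxa:
        raise ValidationError(f"partition class {which!r} is empty")
    sub = table.select_taxa(taxa)
    zero = sub.depth == 0
    if zero.any():
        names = [s for s, z in zip(sub.sample_ids, zero) if z]
        warnings.warn(
            f"{len(names)} samples have zero {which} reads (retained)",
            stacklevel=2,
        )
    return sub


def composition_by_group(table: CountTable, taxonomy: pd.DataFrame,
                         frame: pd.DataFrame, rank: str = "phylum",
                         groupby: list[str] | str = "salinity_group") -> pd.DataFrame:
    """Mean relative abundance per taxonomic rank per sample group.

    Taxa absent from the taxonomy (or with a missing rank) are pooled as
    ``"Unclassified"``. Fractions within each group sum to 1.
    """
    if rank not in ("phylum", "class"):
        raise ValueError(f"unknown rank {rank!r}")
    if isinstance(groupby, str):
        groupby = [groupby]
    rel = pd.DataFrame(table.relative(), index=table.sample_ids,
                       columns=table.taxon_ids)
    assigned = taxonomy[rank].reindex(table.taxon_ids)
    names = assigned.fillna("Unclassified").replace("", "Unclassified")
    # pool taxon columns by rank name, then average within groups
    by_rank = rel.T.groupby(names.to_numpy()).sum().T
    groups = frame.loc[rel.index, groupby]
    key = groups[groupby[0]] if len(groupby) == 1 else list(
        map(tuple, groups.to_numpy())
    )
    mean_rel = by_rank.groupby(pd.Index(key, name="group")).mean()
    out = (
        mean_rel.reset_index()
        .melt(id_vars="group", var_name=rank, value_name="mean_rel_abundance")
        .sort_values(["group", "mean_rel_abundance"],
                     ascending=[True, False])
        .reset_index(drop=True)
    )
    return out
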