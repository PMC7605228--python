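"""Shared in-memory containers used across pipeline stages.

The interchange substrate is deliberately thin: pandas objects with
documented shapes, wrapped only where several arrays must stay aligned.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ALLELES", "BULK_FERTILE", "BULK_STERILE",
           "bulk_depth_columns", "validate_bulk_snp_table"]

#: canonical allele order for 4-vector depths and frequencies
ALLELES = ("A", "C", "G", "T")

BULK_FERTILE = "fertile"
BULK_STERILE = "sterile"


def bulk_depth_columns(bulk: str) -> list[str]:
    """Column names holding the per-allele read depths of one bulk."""
    return [f"{bulk}_{a}" for a in ALLELES]


def validate_bulk_snp_table(table: pd.DataFrame) -> None:
    """Check the structural invariants of a bulk SNP table.

    Required columns: ``chrom``, ``pos`` (1-based int) and eight depth
    columns (two bulks x four alleles).  Positions must be sorted within
    each chromosome and depths nonnegative.
    """
    required = ["chrom", "pos"] + bulk_depth_columns(BULK_FERTILE) + bulk_depth_columns(BULK_STERILE)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"bulk SNP table missing columns: {missing}")
    depth_cols = required[2:]
    if (table[depth_cols].to_numpy() < 0).any():
        raise ValueError("negative allele depth in bulk SNP table")
    for chrom, sub in table.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError(f"positions not sorted within chromosome {chrom}")


@dataclass
class ExpressionMatrix:
    """Gene-level fragment counts with gene lengths and sample metadata.

    Parameters
    ----------
    counts
        genes x samples integer matrix; index are gene ids, columns sample ids.
    gene_lengths
        transcript length in bp per gene, aligned to ``counts.index``.
    samples
        one row per sample (index = sample id) with at least the columns
        ``group`` (e.g. phenotype class T/M/D) and ``tissue``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(
                {"group": "all", "tissue": "unknown"}, index=self.counts.columns
            )
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()].tolist()
            raise ValueError(f"genes without a length: {missing[:5]}")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if not self.samples.index.equals(self.counts.columns):
            self.samples = self.samples.reindex(self.counts.columns)
            if self.samples.isna().any().any():
                raise ValueError("sample metadata does not cover all count columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative fragment counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        """Total mapped fragments per sample (column sums)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts[list(sample_ids)],
            gene_lengths=self.gene_lengths,
            samples=self.samples.loc[list(sample_ids)],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and np.allclose(self.gene_lengths, other.gene_lengths)
            and self.samples.equals(other.samples)
        )
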