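"""Bulked-segregant SNP association by the Euclidean distance statistic.

At each SNP the two bulks' reads are reduced to 4-allele frequency
vectors (A, C, G, T) and compared by their Euclidean distance

    ED = sqrt( sum_i (f_fertile,i - f_sterile,i)^2 ),  ED in [0, sqrt(2)].

A SNP is significant when ED exceeds a flat threshold (default 0.33); the
chromosome carrying the largest share of significant SNPs is the
candidate region.  Raw per-SNP ED is used — no powering or sliding-window
smoothing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ParameterError
from .containers import (ALLELES, BULK_FERTILE, BULK_STERILE,
                         bulk_depth_columns, validate_bulk_snp_table)

__all__ = ["EdResult", "allele_frequencies", "ed_statistic",
           "median_sd_threshold", "threshold_and_summarize",
           "DEFAULT_ED_THRESHOLD", "DEFAULT_MIN_DEPTH"]

logger = logging.getLogger(__name__)

DEFAULT_ED_THRESHOLD = 0.33
#: minimum reads per bulk for a usable frequency estimate
DEFAULT_MIN_DEPTH = 4

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class EdResult:
    """Per-SNP ED table plus the per-chromosome significance summary.

    ``snps`` columns: chrom, pos, the two frequency 4-vectors (f_fertile_*,
    f_sterile_*), ed, significant.  ``summary`` is indexed by chromosome
    with columns n_snps, n_significant, pct_significant (percentages of
    the genome-wide significant total, summing to 100 when any SNP is
    significant).  ``candidate_chromosome`` maximizes pct_significant.
    """

    snps: pd.DataFrame
    summary: pd.DataFrame
    threshold: float
    n_dropped_low_depth: int

    @property
    def candidate_chromosome(self) -> str | None:
        if self.summary["n_significant"].sum() == 0:
            return None
        return self.summary["pct_significant"].idxmax()


def allele_frequencies(depths) -> np.ndarray:
    """Normalize a 4-vector of allele depths to frequencies.

    Accepts one vector or an (n, 4) matrix; rows must have positive total
    depth (zero-depth records are the caller's to drop).
    """
    arr = np.asarray(depths, dtype=float)
    one = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 4 or (arr < 0).any():
        raise ParameterError("expected nonnegative depths over the 4 alleles")
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        raise ParameterError("zero total depth; drop the record before normalizing")
    freqs = arr / totals[:, None]
    return freqs[0] if one else freqs


def ed_statistic(f_a, f_b) -> float | np.ndarray:
    """Euclidean distance between two allele-frequency 4-vectors.

    Symmetric, bounded by sqrt(2) (attained by two disjoint fixed
    alleles).  Inputs must be normalized frequency vectors.
    """
    a = np.atleast_2d(np.asarray(f_a, dtype=float))
    b = np.atleast_2d(np.asarray(f_b, dtype=float))
    for v in (a, b):
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-6) or (v < 0).any():
            raise ParameterError("allele frequencies must be normalized 4-simplices")
    ed = np.sqrt(((a - b) ** 2).sum(axis=1))
    return float(ed[0]) if np.asarray(f_a).ndim == 1 else ed


def median_sd_threshold(ed: np.ndarray, n_sd: float = 3.0) -> float:
    """Data-driven alternative threshold: median(ED) + n_sd * SD(ED)."""
    ed = np.asarray(ed, dtype=float)
    return float(np.median(ed) + n_sd * ed.std(ddof=1))


def threshold_and_summarize(table: pd.DataFrame,
                            threshold: float | None = DEFAULT_ED_THRESHOLD,
                            min_depth: int = DEFAULT_MIN_DEPTH,
                            threshold_mode: str = "fixed") -> EdResult:
    """Compute per-SNP ED, apply the significance threshold, and summarize
    significant-SNP counts and percentages per chromosome.

    Records where either bulk has fewer than ``min_depth`` reads are
    dropped (logged).  With ``threshold_mode='mediansd'`` the threshold is
    recomputed as median + 3 SD of the observed ED distribution.
    """
    validate_bulk_snp_table(table)
    if threshold_mode not in ("fixed", "mediansd"):
        raise ParameterError("threshold_mode must be 'fixed' or 'mediansd'")
    if threshold_mode == "fixed" and not (0.0 < threshold < _SQRT2):
        if threshold != _SQRT2:  # allow the degenerate boundary explicitly
            raise ParameterError(f"threshold must lie in (0, sqrt(2)], got {threshold}")

    f_cols = bulk_depth_columns(BULK_FERTILE)
    s_cols = bulk_depth_columns(BULK_STERILE)
    dep_f = table[f_cols].to_numpy(dtype=float)
    dep_s = table[s_cols].to_numpy(dtype=float)
    ok = (dep_f.sum(axis=1) >= max(min_depth, 1)) & (dep_s.sum(axis=1) >= max(min_depth, 1))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d SNPs below min per-bulk depth %d", n_dropped, min_depth)
    if not ok.any():
        raise ParameterError("no SNPs left after depth filtering")

    kept = table.loc[ok].reset_index(drop=True)
    f_f = allele_frequencies(dep_f[ok])
    f_s = allele_frequencies(dep_s[ok])
    ed = np.sqrt(((f_f - f_s) ** 2).sum(axis=1))
    if threshold_mode == "mediansd":
        threshold = median_sd_threshold(ed)

    snps = kept[["chrom", "pos"]].copy()
    for i, a in enumerate(ALLELES):
        snps[f"f_{BULK_FERTILE}_{a}"] = f_f[:, i]
        snps[f"f_{BULK_STERILE}_{a}"] = f_s[:, i]
    snps["ed"] = ed
    snps["significant"] = ed > threshold

    summary = snps.groupby("chrom").agg(
        n_snps=("ed", "size"), n_significant=("significant", "sum"))
    total_sig = summary["n_significant"].sum()
    summary["pct_significant"] = (
        100.0 * summary["n_significant"] / total_sig if total_sig > 0 else 0.0
    )
    return EdResult(snps=snps, summary=summary, threshold=float(threshold),
                    n_dropped_low_depth=n_dropped)
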