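"""Chromosome-dosage scan from RNA-seq read fractions.

A whole-chromosome loss leaves a dosage footprint in mapped-read shares:
relative to a euploid, a monosomic chromosome carries roughly half its
usual fraction of the library and a nullisomic chromosome essentially
none.  (Exactly, with no dosage compensation, the euploid:monosomic
fraction ratio tends to 2 - f where f is the chromosome's euploid
expression share, because the monosomic library is renormalized over the
remaining expression.)  This module computes per-sample per-chromosome
read fractions, test/reference dosage ratios, and discrete copy-state
calls.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ParameterError
from .containers import ExpressionMatrix

__all__ = ["ChromosomeFractionProfile", "KaryotypeCall", "chromosome_fractions",
           "reference_profile", "dosage_ratio", "call_karyotype",
           "plot_fractions", "DEFAULT_CUTOFFS"]

#: (null_max, mono_max) cutoffs on the test/euploid fraction ratio —
#: midpoints with wide margins between the theoretical states 0, ~0.5, 1
DEFAULT_CUTOFFS = (0.25, 0.75)


@dataclass
class ChromosomeFractionProfile:
    """Per-chromosome read counts and fractions for one sample or group."""

    sample_id: str
    read_counts: pd.Series  # chromosome -> fragments
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ParameterError(f"{self.sample_id}: zero total reads")
        if int(self.read_counts.sum()) != int(self.total_reads):
            raise ValueError("read counts do not sum to total_reads")

    @property
    def fractions(self) -> pd.Series:
        return self.read_counts / self.total_reads


@dataclass
class KaryotypeCall:
    """Discrete copy-state call per chromosome for one sample.

    ``table`` is indexed by chromosome with columns ``ratio_to_reference``
    (NaN where the reference fraction was zero, i.e. undefined) and
    ``state`` in {nullisomic, monosomic, disomic, undefined}.
    """

    sample_id: str
    table: pd.DataFrame
    cutoffs: tuple[float, float]

    def chromosomes_in_state(self, state: str) -> list[str]:
        return self.table.index[self.table["state"] == state].tolist()


def chromosome_fractions(matrix: ExpressionMatrix,
                         gene_map: pd.Series | dict) -> list[ChromosomeFractionProfile]:
    """Fraction of each sample's fragments mapped to each chromosome.

    ``gene_map`` maps gene id -> chromosome and must cover every gene in
    the matrix.  Fractions are invariant to uniform count rescaling.
    """
    gene_map = pd.Series(gene_map)
    missing = matrix.gene_ids.difference(gene_map.index)
    if len(missing):
        raise ParameterError(
            f"{len(missing)} genes missing from gene map, e.g. {missing[:5].tolist()}")
    chrom = gene_map.reindex(matrix.gene_ids)
    by_chrom = matrix.counts.groupby(chrom.to_numpy()).sum()
    profiles = []
    for sample in matrix.sample_ids:
        counts = by_chrom[sample]
        total = int(counts.sum())
        if total == 0:
            raise ParameterError(f"sample {sample} has zero mapped fragments")
        profiles.append(ChromosomeFractionProfile(
            sample_id=sample, read_counts=counts, total_reads=total))
    return profiles


def reference_profile(profiles: list[ChromosomeFractionProfile],
                      euploid_ids: list[str] | None = None) -> pd.Series:
    """Euploid reference fractions.

    Mean of the declared euploid samples' fractions; with none declared,
    the per-chromosome median across all samples (robust to a single
    aberrant chromosome in any one sample).  Replicates are averaged
    after fraction computation, removing library-size leverage.
    """
    frac = pd.DataFrame({p.sample_id: p.fractions for p in profiles})
    if euploid_ids:
        missing = set(euploid_ids) - set(frac.columns)
        if missing:
            raise ParameterError(f"declared euploid samples not found: {sorted(missing)}")
        ref = frac[list(euploid_ids)].mean(axis=1)
    else:
        ref = frac.median(axis=1)
    return ref / ref.sum()


def dosage_ratio(test: ChromosomeFractionProfile | pd.Series,
                 reference: ChromosomeFractionProfile | pd.Series) -> pd.Series:
    """Per-chromosome ratio of test to reference read fractions.

    Chromosomes with zero reference fraction yield NaN (undefined), never
    infinity.
    """
    t = test.fractions if isinstance(test, ChromosomeFractionProfile) else test
    r = reference.fractions if isinstance(reference, ChromosomeFractionProfile) else reference
    if set(t.index) != set(r.index):
        raise ParameterError("test and reference cover different chromosome sets")
    r = r.reindex(t.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = t / r
    return ratio.where(r > 0, np.nan)


def call_karyotype(test: ChromosomeFractionProfile | pd.Series,
                   reference: ChromosomeFractionProfile | pd.Series,
                   cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
                   sample_id: str | None = None) -> KaryotypeCall:
    """Call nullisomic / monosomic / disomic per chromosome by thresholding
    the test/euploid fraction ratio at (null_max, mono_max)."""
    null_max, mono_max = cutoffs
    if not 0.0 < null_max < mono_max < 1.0:
        raise ParameterError("require 0 < null_max < mono_max < 1")
    ratio = dosage_ratio(test, reference)
    state = np.select(
        [ratio.isna(), ratio < null_max, ratio < mono_max],
        ["undefined", "nullisomic", "monosomic"], default="disomic")
    if sample_id is None:
        sample_id = test.sample_id if isinstance(test, ChromosomeFractionProfile) else "test"
    table = pd.DataFrame({"ratio_to_reference": ratio, "state": state})
    return KaryotypeCall(sample_id=sample_id, table=table, cutoffs=tuple(cutoffs))


def plot_fractions(profiles: list[ChromosomeFractionProfile], path: str,
                   reference: pd.Series | None = None) -> None:
    """Grouped per-chromosome bar plot of read fractions (plain stand-in
    for a circular genome plot)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac = pd.DataFrame({p.sample_id: p.fractions for p in profiles})
    ax = frac.plot.bar(figsize=(12, 4), width=0.8)
    if reference is not None:
        ax.plot(np.arange(len(reference)), reference.to_numpy(), "k_",
                markersize=12, label="reference")
    ax.set_xlabel("chromosome")
    ax.set_ylabel("fraction of mapped fragments")
    ax.legend(fontsize=7, ncol=4)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
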