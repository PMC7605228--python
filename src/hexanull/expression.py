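"""Expression screening: the candidate-gene funnel.

Stages, in the order a nullisomic candidate screen runs them:

1. FPKM normalization of gene-level fragment counts.
2. Differential expression between two sample groups by a moment-based
   negative-binomial test with trended dispersion shrinkage and
   Benjamini-Hochberg FDR control.
3. Homeolog specificity: focal-chromosome genes with no homeolog partner
   on another chromosome (in an allopolyploid, genes with surviving
   homeologs are buffered against chromosome loss, so only
   chromosome-specific genes can explain a nullisomic phenotype).
4. Tissue specificity by k-means clustering of per-gene expression
   profiles (Euclidean distance, k = 8 by default).
5. Intersection of the chromosome-specific and tissue-specific sets
   (optionally with a DEG set) into a candidate report.
6. Generic hypergeometric term enrichment over a user-supplied
   gene-to-term map.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ParameterError

__all__ = ["fpkm", "DegResult", "deg_test", "homeolog_specific_genes",
           "KMeansResult", "kmeans", "tissue_specific_genes",
           "CandidateGeneReport", "intersect_candidates", "term_enrichment"]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- FPKM

def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM_gs = counts_gs * 1e9 / (library_size_s * length_g).  Library
    sizes default to the column sums of ``counts``.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ParameterError("every gene needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ParameterError("every sample needs a positive library size")
    return counts * 1e9 / np.outer(lengths.to_numpy(), library_sizes.to_numpy())


# ------------------------------------------- differential expression

@dataclass
class DegResult:
    """Per-gene differential-expression table and the thresholds used.

    ``table`` columns: mean_a, mean_b (normalized counts), log2_fc (on
    FPKM with a 1-FPKM pseudocount, group A relative to B), p, fdr,
    direction in {up, down, ns}.  ``excluded`` lists genes that were
    all-zero in both groups and never entered testing.
    """

    table: pd.DataFrame
    fc_min: float
    fdr_max: float
    excluded: list[str] = field(default_factory=list)

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "down"]

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["direction"] != "ns"]


def _dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit the hyperbolic mean-dispersion trend a1/mean + a0 by least
    squares over genes with a positive raw estimate, then evaluate it."""
    ok = (disp > 0) & (mean > 0)
    if ok.sum() < 10:
        # too few informative genes for a trend; flat fallback
        fallback = float(np.median(disp[ok])) if ok.any() else 0.1
        return np.full_like(mean, max(fallback, 1e-4))
    x = np.column_stack([1.0 / mean[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(x, disp[ok], rcond=None)
    a1, a0 = max(coef[0], 0.0), max(coef[1], 1e-4)
    return a1 / np.maximum(mean, 1e-8) + a0


def deg_test(counts: pd.DataFrame, group_a: list[str], group_b: list[str],
             lengths: pd.Series, fc_min: float = 2.0, fdr_max: float = 0.01,
             shrink_weight: float = 0.5) -> DegResult:
    """Moment-based negative-binomial test of equal means between groups.

    Counts are library-size normalized; the per-gene NB dispersion is
    moment-estimated from within-group variances and shrunk toward a
    fitted mean-dispersion trend (weight ``shrink_weight`` on the trend).
    The test statistic is the difference of group log-means with a
    delta-method variance ((1/m + alpha)/n per group) referred to a t
    distribution with the residual degrees of freedom; p-values are
    BH-corrected.  Fold change is computed on group
    FPKM means with a 1-FPKM pseudocount, and a gene is called up/down
    only when FDR <= fdr_max and |FC| >= fc_min.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ParameterError("need >= 2 replicates per group")
    missing = (set(group_a) | set(group_b)) - set(counts.columns)
    if missing:
        raise ParameterError(f"samples not in count matrix: {sorted(missing)}")

    lib = counts[group_a + group_b].sum(axis=0)
    norm = counts[group_a + group_b] * (lib.mean() / lib)

    zero = (counts[group_a + group_b].sum(axis=1) == 0)
    excluded = counts.index[zero].tolist()
    if excluded:
        logger.info("excluding %d genes with zero counts in both groups", len(excluded))
    norm = norm.loc[~zero]

    a = norm[group_a].to_numpy()
    b = norm[group_b].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)

    pooled_mean = (mean_a * n_a + mean_b * n_b) / (n_a + n_b)
    var_w = (a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)) / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_disp = (var_w - pooled_mean) / pooled_mean**2
    raw_disp = np.where(np.isfinite(raw_disp), np.clip(raw_disp, 0.0, 10.0), 0.0)
    trend = _dispersion_trend(pooled_mean, raw_disp)
    disp = (1.0 - shrink_weight) * raw_disp + shrink_weight * trend

    c = 0.5  # pseudo-fragments stabilizing the log at low means
    var_log_a = (1.0 / (mean_a + c) + disp) / n_a
    var_log_b = (1.0 / (mean_b + c) + disp) / n_b
    z = (np.log(mean_a + c) - np.log(mean_b + c)) / np.sqrt(var_log_a + var_log_b)
    # t reference with the residual df: the plug-in variance is estimated
    # from few replicates, and a normal reference is anticonservative there
    pvals = 2.0 * stats.t.sf(np.abs(z), df=n_a + n_b - 2)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    fpkm_all = fpkm(counts[group_a + group_b].loc[~zero], lengths.reindex(counts.index[~zero]),
                    counts[group_a + group_b].sum(axis=0))
    log2_fc = np.log2(fpkm_all[group_a].mean(axis=1) + 1.0) - np.log2(
        fpkm_all[group_b].mean(axis=1) + 1.0)

    sig = (fdr <= fdr_max) & (np.abs(log2_fc.to_numpy()) >= np.log2(fc_min))
    direction = np.where(~sig, "ns", np.where(log2_fc.to_numpy() > 0, "up", "down"))
    table = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2_fc": log2_fc.to_numpy(),
        "p": pvals, "fdr": fdr, "direction": direction,
    }, index=norm.index)
    return DegResult(table=table, fc_min=fc_min, fdr_max=fdr_max, excluded=excluded)


# ------------------------------------------------ homeolog specificity

def homeolog_specific_genes(focal_genes, homeolog_table: pd.DataFrame) -> set[str]:
    """Focal-chromosome genes with no homeolog partner on another chromosome.

    ``homeolog_table`` is long-format (group_id, gene_id, chromosome).  A
    focal gene absent from the table is treated as specific (warned); a
    gene whose group has members only on its own chromosome is specific.
    """
    focal_genes = set(focal_genes)
    t = homeolog_table
    known = set(t["gene_id"])
    orphans = focal_genes - known
    if orphans:
        logger.warning("%d focal genes absent from homeolog table; treated as specific",
                       len(orphans))
    gene_rows = t[t["gene_id"].isin(focal_genes)]
    specific = set(orphans)
    group_chroms = t.groupby("group_id")["chromosome"].nunique()
    for gene, grp, chrom in gene_rows[["gene_id", "group_id", "chromosome"]].itertuples(index=False):
        if group_chroms.get(grp, 1) <= 1:
            specific.add(gene)
    return specific


# ------------------------------------------------- tissue specificity

@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    objective_path: list[float]


def _farthest_point_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded greedy farthest-point initialization: random first center,
    each next center the point maximizing distance to its nearest chosen
    center."""
    centers = [x[rng.integers(len(x))]]
    for _ in range(1, k):
        d2 = np.min(((x[:, None, :] - np.array(centers)[None]) ** 2).sum(-1), axis=1)
        centers.append(x[int(np.argmax(d2))])
    return np.array(centers)


def kmeans(x: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10,
           max_iter: int = 100) -> KMeansResult:
    """Lloyd's k-means with Euclidean distance.

    Greedy farthest-point initialization, ``n_restarts`` seeded restarts,
    assignment ties broken toward the lowest cluster index (argmin), and
    a monotonically non-increasing within-cluster sum of squares.
    """
    x = np.asarray(x, dtype=float)
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > len(x):
        raise ParameterError(f"k={k} exceeds the number of points ({len(x)})")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(n_restarts):
        centers = _farthest_point_init(x, k, rng)
        labels = np.zeros(len(x), dtype=int)
        path: list[float] = []
        for _ in range(max_iter):
            d2 = ((x[:, None, :] - centers[None]) ** 2).sum(-1)
            new_labels = np.argmin(d2, axis=1)  # ties -> lowest index
            inertia = float(d2[np.arange(len(x)), new_labels].sum())
            path.append(inertia)
            if (new_labels == labels).all() and len(path) > 1:
                break
            labels = new_labels
            for j in range(k):  # empty clusters keep their previous centroid
                if (labels == j).any():
                    centers[j] = x[labels == j].mean(axis=0)
        result = KMeansResult(labels=labels, centroids=centers,
                              inertia=path[-1], objective_path=path)
        if best is None or result.inertia < best.inertia:
            best = result
    assert best is not None
    return best


def tissue_specific_genes(fpkm_matrix: pd.DataFrame, target_tissue: str,
                          k: int = 8, specificity_cutoff: float = 0.5,
                          seed: int = 0, min_fold: float = 3.0
                          ) -> tuple[set[str], pd.Series, pd.DataFrame]:
    """Target-tissue-specific genes by k-means profile clustering.

    Genes whose profiles vary meaningfully across tissues (peak FPKM at
    least ``min_fold`` times the across-tissue median; standardizing a
    flat profile would only amplify replicate noise) are standardized to
    mean 0 / SD 1 and clustered with Euclidean k-means.  A cluster is
    target-specific when its standardized centroid peaks in the target
    tissue and the cluster's mean expression-mass share in the target
    tissue exceeds ``specificity_cutoff``; its member genes form the
    returned set.

    Returns (specific gene set, per-gene cluster assignment, per-cluster
    summary with centroid peak tissue and target mass share).
    """
    if target_tissue not in fpkm_matrix.columns:
        raise ParameterError(f"target tissue {target_tissue!r} not among samples")
    x = fpkm_matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    med = np.median(x, axis=1)
    varying = (x.max(axis=1) >= min_fold * med) & (x.max(axis=1) > 0)
    flat = (sd == 0) | ~varying
    if flat.any():
        logger.info("excluding %d flat/low-variation genes from clustering",
                    int(flat.sum()))
    usable = fpkm_matrix.index[~flat]
    if len(usable) < k:
        raise ParameterError(f"k={k} exceeds the {len(usable)} clusterable genes")
    xs = x[~flat]
    z = (xs - xs.mean(axis=1, keepdims=True)) / xs.std(axis=1, keepdims=True)
    fit = kmeans(z, k=k, seed=seed)

    mass = xs / xs.sum(axis=1, keepdims=True)
    t_ix = list(fpkm_matrix.columns).index(target_tissue)
    rows = []
    specific: set[str] = set()
    assignments = pd.Series(fit.labels, index=usable, name="cluster")
    for j in range(k):
        members = usable[fit.labels == j]
        if len(members) == 0:
            rows.append((j, 0, None, np.nan, False))
            continue
        peak = fpkm_matrix.columns[int(np.argmax(fit.centroids[j]))]
        share = float(mass[fit.labels == j, t_ix].mean())
        is_spec = (peak == target_tissue) and (share > specificity_cutoff)
        if is_spec:
            specific |= set(members)
        rows.append((j, len(members), peak, share, is_spec))
    summary = pd.DataFrame(rows, columns=["cluster", "n_genes", "peak_tissue",
                                          "target_share", "target_specific"]).set_index("cluster")
    return specific, assignments, summary


# --------------------------------------------------- candidate funnel

@dataclass
class CandidateGeneReport:
    """Output of the candidate funnel with per-gene provenance.

    ``candidates`` is the intersection of the chromosome-specific and
    tissue-specific sets (and the DEG set when supplied); ``provenance``
    has one boolean column per stage plus ``candidate``.
    """

    chromosome_specific: set[str]
    tissue_specific: set[str]
    deg: set[str] | None
    candidates: set[str]
    provenance: pd.DataFrame


def intersect_candidates(chromosome_specific, tissue_specific,
                         deg: set[str] | None = None) -> CandidateGeneReport:
    """Exact set intersection of the funnel stages with provenance flags."""
    chromosome_specific = set(chromosome_specific)
    tissue_specific = set(tissue_specific)
    candidates = chromosome_specific & tissue_specific
    if deg is not None:
        deg = set(deg)
        candidates &= deg
    union = chromosome_specific | tissue_specific | (deg or set())
    genes = sorted(union)
    prov = pd.DataFrame({
        "chromosome_specific": [g in chromosome_specific for g in genes],
        "tissue_specific": [g in tissue_specific for g in genes],
    }, index=pd.Index(genes, name="gene_id"))
    if deg is not None:
        prov["deg"] = [g in deg for g in genes]
    prov["candidate"] = [g in candidates for g in genes]
    return CandidateGeneReport(chromosome_specific=chromosome_specific,
                               tissue_specific=tissue_specific, deg=deg,
                               candidates=candidates, provenance=prov)


# ------------------------------------------------------ term enrichment

def term_enrichment(genes, universe, gene_terms: pd.DataFrame) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``genes`` within ``universe``.

    ``gene_terms`` is long-format (gene_id, term).  For each term with at
    least one universe member, the upper-tail hypergeometric p-value of
    the overlap is computed and BH-corrected across terms.  Terms with no
    universe member are skipped.
    """
    genes = set(genes)
    universe = set(universe)
    if not genes:
        raise ParameterError("empty query gene set")
    if not genes <= universe:
        raise ParameterError("query set must be a subset of the universe")
    n_universe, n_set = len(universe), len(genes)
    rows = []
    for term, sub in gene_terms.groupby("term"):
        members = set(sub["gene_id"]) & universe
        if not members:
            continue
        overlap = len(members & genes)
        p = stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_set)
        rows.append((term, len(members), overlap, p))
    if not rows:
        return pd.DataFrame(columns=["term", "n_term", "n_overlap", "p", "fdr"]).set_index("term")
    out = pd.DataFrame(rows, columns=["term", "n_term", "n_overlap", "p"]).set_index("term")
    _, fdr, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["fdr"] = fdr
    return out.sort_values("p")
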