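"""Synthetic allohexaploid dataset generator.

Emulates the data structure of a hexaploid wheat aneuploid study: 21
chromosomes in seven homeologous groups across subgenomes A, B and D; a
selfed monosomic whose null (chromosome-lacking) gametes transmit at
configurable rates through each parent; chromosome-dosage-proportional
negative-binomial expression with optional partial dosage compensation;
two phenotype bulks with per-SNP allele depths; dosage-sensitive marker
band intensities; and a multi-tissue expression matrix containing planted
stamen-specific genes.

All randomness flows through numpy ``Generator`` objects passed
explicitly; a :class:`~hexanull.config.SimulationConfig` seed fully
determines every output via :func:`simulate_dataset`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ParameterError, SimulationConfig
from .containers import (ALLELES, BULK_FERTILE, BULK_STERILE, ExpressionMatrix,
                         bulk_depth_columns)
from .markers import MarkerPanel

__all__ = [
    "SUBGENOMES", "GROUP_NUMBERS", "chromosome_names",
    "GenomeModel", "IndividualGenotype", "SyntheticDataset",
    "build_genome", "simulate_progeny", "focal_copy_numbers",
    "simulate_counts", "simulate_bulk_snps", "simulate_markers",
    "simulate_tissue_matrix", "simulate_dataset", "tissue_names",
]

SUBGENOMES = ("A", "B", "D")
GROUP_NUMBERS = tuple(range(1, 8))

#: genome-wide physical span used to place SNP coordinates (bp)
_GENOME_SPAN_BP = 600_000_000

_TISSUE_POOL = ("stamen", "root", "leaf", "stem", "pistil", "spike", "grain", "seedling")


def chromosome_names() -> list[str]:
    """The 21 chromosome names, ordered by homeologous group then subgenome."""
    return [f"chr{g}{s}" for g in GROUP_NUMBERS for s in SUBGENOMES]


def tissue_names(n_tissues: int) -> list[str]:
    if n_tissues > len(_TISSUE_POOL):
        raise ParameterError(f"at most {len(_TISSUE_POOL)} tissues supported")
    return list(_TISSUE_POOL[:n_tissues])


@dataclass
class GenomeModel:
    """The simulated hexaploid genome.

    ``chromosomes`` maps each chromosome name to its relative expression
    weight (weights sum to 1).  ``genes`` has one row per gene with columns
    ``gene_id``, ``chromosome``, ``length_bp``, ``homeolog_group`` (nullable
    string), ``base_mean`` and ``tissue_profile`` in
    {constitutive, stamen_specific, other_tissue_specific}.
    """

    chromosomes: pd.Series  # name -> weight
    genes: pd.DataFrame
    triad_fraction: float

    def __post_init__(self) -> None:
        if abs(float(self.chromosomes.sum()) - 1.0) > 1e-9:
            raise ValueError("chromosome weights must sum to 1")
        if (self.genes["length_bp"] < 150).any():
            raise ValueError("gene lengths must be >= 150 bp")
        grouped = self.genes.dropna(subset=["homeolog_group"]).groupby("homeolog_group")
        for gid, sub in grouped:
            if len(sub) not in (2, 3) or sub["chromosome"].nunique() != len(sub):
                raise ValueError(
                    f"homeolog group {gid} must span 2 or 3 distinct chromosomes"
                )

    def chromosome_specific_genes(self, chromosome: str) -> set[str]:
        """Planted truth: genes on ``chromosome`` with no homeolog partner."""
        g = self.genes
        mask = (g["chromosome"] == chromosome) & g["homeolog_group"].isna()
        return set(g.loc[mask, "gene_id"])

    def tissue_specific_genes(self, profile: str = "stamen_specific") -> set[str]:
        g = self.genes
        return set(g.loc[g["tissue_profile"] == profile, "gene_id"])

    def homeolog_table(self) -> pd.DataFrame:
        """Long-format (group_id, gene_id, chromosome) truth table."""
        g = self.genes.dropna(subset=["homeolog_group"])
        return pd.DataFrame({
            "group_id": g["homeolog_group"].to_numpy(),
            "gene_id": g["gene_id"].to_numpy(),
            "chromosome": g["chromosome"].to_numpy(),
        })


@dataclass
class IndividualGenotype:
    """One progeny plant: per-chromosome copy number and phenotype class.

    Phenotype follows the focal-chromosome dosage: two copies -> T (tall,
    fertile), one -> M (monosomic, semi-dwarf, fertile), zero -> D (dwarf
    nullisomic, male-sterile).
    """

    sample_id: str
    copy_number: dict[str, int]
    phenotype_class: str = field(init=False)
    focal_chromosome: str = "chr2A"

    def __post_init__(self) -> None:
        focal = self.copy_number[self.focal_chromosome]
        if focal not in (0, 1, 2):
            raise ParameterError(f"copy number must be 0, 1 or 2, got {focal}")
        self.phenotype_class = {2: "T", 1: "M", 0: "D"}[focal]


def build_genome(config: SimulationConfig, rng: np.random.Generator) -> GenomeModel:
    """Construct the genome: near-uniform chromosome weights, genes placed
    proportionally, homeolog triads spanning the A/B/D chromosomes of each
    homeologous group, and planted tissue-specificity labels."""
    names = chromosome_names()
    raw = np.exp(rng.normal(0.0, 0.05, size=len(names)))
    weights = pd.Series(raw / raw.sum(), index=names)

    n_per_chrom = rng.multinomial(config.n_genes - len(names), weights.to_numpy()) + 1
    rows = []
    for chrom, n_c in zip(names, n_per_chrom):
        for i in range(n_c):
            rows.append((f"G{chrom[3:]}_{i:05d}", chrom))
    genes = pd.DataFrame(rows, columns=["gene_id", "chromosome"])
    n = len(genes)
    genes["length_bp"] = rng.integers(200, 4000, size=n)
    genes["base_mean"] = np.exp(rng.normal(np.log(5.0), 1.0, size=n))

    # homeolog triads within each homeologous group number
    genes["homeolog_group"] = pd.array([pd.NA] * n, dtype="string")
    by_chrom = {c: genes.index[genes["chromosome"] == c].to_numpy() for c in names}
    for g in GROUP_NUMBERS:
        trio = [by_chrom[f"chr{g}{s}"] for s in SUBGENOMES]
        trio = [rng.permutation(ix) for ix in trio]
        n_triads = int(round(config.triad_fraction * min(len(ix) for ix in trio)))
        for t in range(n_triads):
            gid = f"HG{g}_{t:05d}"
            for ix in trio:
                genes.loc[ix[t], "homeolog_group"] = gid

    u = rng.random(n)
    profile = np.where(
        u < config.stamen_specific_fraction, "stamen_specific",
        np.where(u < config.stamen_specific_fraction + config.other_tissue_specific_fraction,
                 "other_tissue_specific", "constitutive"),
    )
    genes["tissue_profile"] = profile
    return GenomeModel(chromosomes=weights, genes=genes,
                       triad_fraction=config.triad_fraction)


def _null_gamete_prob(transmission: float) -> float:
    """Probability a transmitted gamete is null, given the null:normal
    success ratio of a monosomic parent (which produces the two gamete
    types in equal numbers at meiosis)."""
    return transmission / (1.0 + transmission)


def focal_copy_numbers(config: SimulationConfig, rng: np.random.Generator,
                       n: int | None = None) -> np.ndarray:
    """Vectorized focal-chromosome copy numbers of selfed-monosomic progeny."""
    n = config.n_progeny if n is None else n
    q_f = _null_gamete_prob(config.female_null_transmission)
    q_m = _null_gamete_prob(config.male_null_transmission)
    female_null = rng.random(n) < q_f
    male_null = rng.random(n) < q_m
    return (2 - female_null.astype(int) - male_null.astype(int))


def simulate_progeny(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> list[IndividualGenotype]:
    """Self a plant monosomic for the focal chromosome.

    Each progeny draws a female and a male gamete independently; a gamete
    is null with probability t/(1+t) where t is the parent-specific
    null:normal transmission ratio.  Focal copy number is the count of
    non-null gametes; all other chromosomes stay disomic.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    copies = focal_copy_numbers(config, rng)
    names = chromosome_names()
    out = []
    for i, c in enumerate(copies):
        cn = {name: 2 for name in names}
        cn[config.focal_chromosome] = int(c)
        out.append(IndividualGenotype(sample_id=f"P{i:04d}", copy_number=cn,
                                      focal_chromosome=config.focal_chromosome))
    return out


def _dosage_factor(copy_number: np.ndarray, compensation: float) -> np.ndarray:
    """Expression scaling for chromosome copy number c: (c/2) plus partial
    compensation pulling the factor back toward 1; a fully lost chromosome
    (c = 0) is always silent regardless of compensation."""
    c = np.asarray(copy_number, dtype=float)
    d = c / 2.0 + compensation * (1.0 - c / 2.0)
    return np.where(c == 0.0, 0.0, d)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = m + dispersion * m^2; exact zeros where
    the mean is zero."""
    mean = np.asarray(mean, dtype=float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    out = rng.negative_binomial(size, np.clip(p, 1e-12, 1.0))
    return np.where(mean == 0.0, 0, out)


def simulate_counts(model: GenomeModel, genotypes: list[IndividualGenotype],
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> ExpressionMatrix:
    """Dosage-proportional RNA-seq counts for each progeny plant.

    Gene g in sample s has expectation proportional to base_mean * dosage
    factor, rescaled so every library's expected total equals
    ``mean_library_size`` (per-sample fractions are unaffected by this
    rescaling).  Genes on a chromosome with zero copies get exactly zero.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = model.genes
    base = genes["base_mean"].to_numpy()
    chrom_of_gene = genes["chromosome"].to_numpy()
    cols = {}
    for g in genotypes:
        copies = np.array([g.copy_number[c] for c in chrom_of_gene])
        mu = base * _dosage_factor(copies, config.dosage_compensation)
        total = mu.sum()
        if total == 0:
            raise ParameterError("all chromosomes silent; cannot normalize library")
        mu = mu * (config.mean_library_size / total)
        cols[g.sample_id] = _nb_draw(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=genes["gene_id"].to_numpy())
    samples = pd.DataFrame(
        {
            "group": [g.phenotype_class for g in genotypes],
            "tissue": "young_spike",
        },
        index=[g.sample_id for g in genotypes],
    )
    lengths = pd.Series(genes["length_bp"].to_numpy(), index=genes["gene_id"].to_numpy())
    return ExpressionMatrix(counts=counts, gene_lengths=lengths, samples=samples)


def partition_bulks(genotypes: list[IndividualGenotype], config: SimulationConfig,
                    rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Split progeny into a fertile (T and M) and a sterile (D) bulk,
    sampling without replacement up to the configured bulk sizes."""
    fertile = [g.sample_id for g in genotypes if g.phenotype_class in ("T", "M")]
    sterile = [g.sample_id for g in genotypes if g.phenotype_class == "D"]
    if not sterile:
        raise ParameterError("no sterile (nullisomic) progeny to bulk; "
                             "increase n_progeny or transmission rates")
    if not fertile:
        raise ParameterError("no fertile progeny to bulk")
    n_f = min(config.bulk_sizes[0], len(fertile))
    n_s = min(config.bulk_sizes[1], len(sterile))
    pick_f = sorted(rng.choice(len(fertile), size=n_f, replace=False))
    pick_s = sorted(rng.choice(len(sterile), size=n_s, replace=False))
    return [fertile[i] for i in pick_f], [sterile[i] for i in pick_s]


def simulate_bulk_snps(model: GenomeModel, genotypes: list[IndividualGenotype],
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-SNP allele depths for the two phenotype bulks.

    SNPs land on chromosomes in proportion to chromosome weight.  On the
    focal chromosome the alternative allele rides on the chromosome that
    the sterile bulk has lost: the fertile bulk reads are all alternative,
    the sterile bulk shows only the reference background, so the allele
    frequency divergence is maximal.  Elsewhere both bulks sample the same
    Beta-distributed population allele frequency and any divergence is
    binomial sampling noise.  Depths are Poisson with the configured mean.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.n_snps < 21:
        raise ParameterError("n_snps must be >= 21")
    # bulk membership is drawn for provenance/reporting parity even though
    # the allele model below only depends on the phenotype split
    partition_bulks(genotypes, config, rng)

    weights = model.chromosomes
    chrom_idx = rng.choice(len(weights), size=config.n_snps, p=weights.to_numpy())
    chroms = weights.index.to_numpy()[chrom_idx]
    chrom_len = np.maximum((weights.to_numpy() * _GENOME_SPAN_BP).astype(int), 10_000)
    pos = rng.integers(1, chrom_len[chrom_idx] + 1)

    allele_pairs = np.array([(i, j) for i in range(4) for j in range(4) if i != j])
    pair_idx = rng.integers(0, len(allele_pairs), size=config.n_snps)
    ref_i = allele_pairs[pair_idx, 0]
    alt_i = allele_pairs[pair_idx, 1]

    depth_f = rng.poisson(config.mean_depth_snp, size=config.n_snps)
    depth_s = rng.poisson(config.mean_depth_snp, size=config.n_snps)
    is_focal = chroms == config.focal_chromosome

    p_shared = rng.beta(config.snp_beta_a, config.snp_beta_a, size=config.n_snps)
    alt_f = rng.binomial(depth_f, p_shared)
    alt_s = rng.binomial(depth_s, p_shared)
    # focal chromosome: alternative allele fixed in the fertile bulk,
    # absent (zero copies) in the sterile bulk
    alt_f = np.where(is_focal, depth_f, alt_f)
    alt_s = np.where(is_focal, 0, alt_s)

    depths = {f"{b}_{a}": np.zeros(config.n_snps, dtype=int)
              for b in (BULK_FERTILE, BULK_STERILE) for a in ALLELES}
    f_cols = bulk_depth_columns(BULK_FERTILE)
    s_cols = bulk_depth_columns(BULK_STERILE)
    for i in range(4):
        depths[f_cols[i]] += np.where(alt_i == i, alt_f, 0)
        depths[f_cols[i]] += np.where(ref_i == i, depth_f - alt_f, 0)
        depths[s_cols[i]] += np.where(alt_i == i, alt_s, 0)
        depths[s_cols[i]] += np.where(ref_i == i, depth_s - alt_s, 0)

    table = pd.DataFrame({"chrom": chroms, "pos": pos,
                          "ref": np.array(list(ALLELES))[ref_i],
                          "alt": np.array(list(ALLELES))[alt_i], **depths})
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    # collapse coincidental duplicate coordinates (vanishingly rare)
    table = table.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    return table


def simulate_markers(genotypes: list[IndividualGenotype], config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> MarkerPanel:
    """Dosage-sensitive marker band intensities per plant.

    Intensity is copy_number/2 plus truncated Gaussian noise, normalized so
    a euploid (two-copy) band reads ~1.  Focal-chromosome markers track the
    segregating chromosome; off-focal markers are constant-dose controls.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    marker_rows = [(f"M{config.focal_chromosome[3:]}_{i}", config.focal_chromosome)
                   for i in range(config.n_markers_focal)]
    others = [c for c in chromosome_names() if c != config.focal_chromosome]
    for i in range(config.n_markers_other):
        marker_rows.append((f"Mctl_{i}", others[i % len(others)]))
    markers = pd.DataFrame(marker_rows, columns=["marker_id", "chromosome"])

    plants = [g.sample_id for g in genotypes]
    inten = np.empty((len(plants), len(markers)))
    for j, (_, chrom) in enumerate(marker_rows):
        copies = np.array([g.copy_number[chrom] for g in genotypes], dtype=float)
        noise = rng.normal(0.0, config.marker_noise_sd, size=len(plants))
        inten[:, j] = np.maximum(copies / 2.0 + noise, 0.0)
    intensities = pd.DataFrame(inten, index=plants, columns=markers["marker_id"])
    return MarkerPanel(markers=markers, intensities=intensities)


def simulate_tissue_matrix(model: GenomeModel, config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           specific_fold: float = 50.0) -> ExpressionMatrix:
    """Multi-tissue expression matrix of a euploid reference plant.

    Constitutive genes share one mean across tissues; planted
    stamen-specific genes concentrate their expression in the stamen
    sample (and other-tissue-specific genes in one random non-stamen
    tissue), with an on/off contrast of ``specific_fold``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tissues = tissue_names(config.n_tissues)
    genes = model.genes
    n = len(genes)
    base = genes["base_mean"].to_numpy()

    profile = np.ones((n, len(tissues)))
    stamen_ix = tissues.index("stamen")
    non_stamen = [i for i in range(len(tissues)) if i != stamen_ix]
    is_stamen_spec = (genes["tissue_profile"] == "stamen_specific").to_numpy()
    is_other_spec = (genes["tissue_profile"] == "other_tissue_specific").to_numpy()
    profile[is_stamen_spec] = 1.0 / specific_fold
    profile[is_stamen_spec, stamen_ix] = 1.0
    target_other = rng.choice(non_stamen, size=n)
    for g in np.flatnonzero(is_other_spec):
        profile[g] = 1.0 / specific_fold
        profile[g, target_other[g]] = 1.0

    cols = {}
    for t_ix, tissue in enumerate(tissues):
        mu = base * profile[:, t_ix]
        mu = mu * (config.mean_library_size / mu.sum())
        cols[tissue] = _nb_draw(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=genes["gene_id"].to_numpy())
    samples = pd.DataFrame({"group": "euploid_atlas", "tissue": tissues},
                           index=tissues)
    lengths = pd.Series(genes["length_bp"].to_numpy(), index=genes["gene_id"].to_numpy())
    return ExpressionMatrix(counts=counts, gene_lengths=lengths, samples=samples)


@dataclass
class SyntheticDataset:
    """Bundle of every simulated input the pipeline consumes."""

    config: SimulationConfig
    model: GenomeModel
    genotypes: list[IndividualGenotype]
    counts: ExpressionMatrix
    snps: pd.DataFrame | None
    markers: MarkerPanel
    tissue_matrix: ExpressionMatrix


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full dataset under one seed.

    Each stage gets an independent child generator spawned from the config
    seed, so regenerating any single stage with the same seed reproduces
    it byte-identically regardless of the others.
    """
    children = np.random.SeedSequence(config.seed).spawn(7)
    rngs = [np.random.default_rng(s) for s in children]
    model = build_genome(config, rngs[0])
    genotypes = simulate_progeny(config, rngs[1])
    while not any(g.phenotype_class == "D" for g in genotypes):
        # a selfed monosomic family with no nullisomic recovery cannot form
        # a sterile bulk; redraw the progeny from a dedicated substream
        if config.male_null_transmission == 0 or config.female_null_transmission == 0:
            break
        genotypes = simulate_progeny(config, rngs[6])
    counts = simulate_counts(model, genotypes, config, rngs[2])
    if any(g.phenotype_class == "D" for g in genotypes):
        snps = simulate_bulk_snps(model, genotypes, config, rngs[3])
    else:
        snps = None  # no sterile bulk exists; BSA stage is not applicable
    markers = simulate_markers(genotypes, config, rngs[4])
    tissue = simulate_tissue_matrix(model, config, rngs[5])
    return SyntheticDataset(config=config, model=model, genotypes=genotypes,
                            counts=counts, snps=snps, markers=markers,
                            tissue_matrix=tissue)
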