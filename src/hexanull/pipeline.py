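"""End-to-end pipeline: simulate (or load) inputs, run every stage, and
check the concordance of the three independent lines of evidence.

Stage order mirrors how a nullisomic is pinned down in practice: the
bulked-segregant ED scan names a candidate chromosome, the read-dosage
scan calls its copy state per sample, marker genotyping confirms the
loss in individual plants, the expression screen funnels the candidate
genes, and segregation genetics ties the progeny ratios to gamete
transmission.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsa, dosage, expression, genetics, io, markers
from .config import ParameterError, PipelineConfig
from .containers import ExpressionMatrix
from .synthetic import SyntheticDataset, simulate_dataset

__all__ = ["PipelineReport", "run_pipeline", "configure_logging"]

logger = logging.getLogger("hexanull")


def configure_logging(level: str = "INFO") -> None:
    """Log to stderr only; stdout stays machine-readable."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hexanull")
    root.handlers[:] = [handler]
    root.setLevel(level)


@dataclass
class PipelineReport:
    """Everything the pipeline concluded, plus where it wrote the files."""

    out_dir: Path
    ed_candidate: str | None
    dosage_nullisomic: str | None
    marker_null: str | None
    concordant: bool
    evidence_chromosome: str | None
    n_candidate_genes: int | None
    files: dict[str, Path]

    def summary_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["files"] = {k: str(v) for k, v in self.files.items()}
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
        return wrapped
    return deco


@_stage("bsa_ed")
def _run_bsa(snps, config: PipelineConfig, out: Path, files: dict) -> str | None:
    if snps is None or len(snps) == 0:
        logger.info("no bulk SNP table; skipping ED scan")
        return None
    result = bsa.threshold_and_summarize(
        snps, threshold=config.ed_threshold, min_depth=config.min_depth,
        threshold_mode=config.ed_threshold_mode)
    files["ed_snps"] = out / "ed_snps.tsv"
    result.snps.to_csv(files["ed_snps"], sep="\t", index=False, float_format="%.6g")
    files["ed_summary"] = out / "ed_summary.tsv"
    result.summary.to_csv(files["ed_summary"], sep="\t", float_format="%.6g")
    return result.candidate_chromosome


@_stage("dosage_scan")
def _run_dosage(matrix: ExpressionMatrix, gene_map: pd.Series,
                config: PipelineConfig, out: Path, files: dict) -> tuple[str | None, pd.DataFrame]:
    profiles = dosage.chromosome_fractions(matrix, gene_map)
    euploid = config.reference_samples
    if euploid is None and "group" in matrix.samples.columns:
        declared = matrix.samples.index[matrix.samples["group"] == "T"].tolist()
        euploid = declared or None
    reference = dosage.reference_profile(profiles, euploid)
    frac = pd.DataFrame({p.sample_id: p.fractions for p in profiles})
    files["fractions"] = out / "chromosome_fractions.tsv"
    frac.to_csv(files["fractions"], sep="\t", float_format="%.6g")

    calls = []
    for p in profiles:
        call = dosage.call_karyotype(p, reference, (config.null_max, config.mono_max))
        t = call.table.copy()
        t.insert(0, "sample_id", p.sample_id)
        calls.append(t.reset_index(names="chromosome"))
    call_table = pd.concat(calls, ignore_index=True)
    files["karyotype"] = out / "karyotype_calls.tsv"
    call_table.to_csv(files["karyotype"], sep="\t", index=False, float_format="%.6g")

    files["fractions_plot"] = out / "chromosome_fractions.png"
    dosage.plot_fractions(profiles, str(files["fractions_plot"]), reference)

    nulls = call_table.loc[call_table["state"] == "nullisomic", "chromosome"]
    null_chrom = nulls.mode().iloc[0] if len(nulls) else None
    return null_chrom, call_table


@_stage("marker_genotyping")
def _run_markers(panel: markers.MarkerPanel, config: PipelineConfig,
                 out: Path, files: dict) -> tuple[str | None, pd.DataFrame]:
    calls = markers.genotype_plants(panel, config.focal_chromosome,
                                    (config.absent_max, config.half_max))
    files["marker_calls"] = out / "marker_genotypes.tsv"
    calls.to_csv(files["marker_calls"], sep="\t")
    # which chromosome do the marker nulls implicate? scan every
    # chromosome with markers for plants whose bands vanish
    null_counts = {}
    for chrom in panel.markers["chromosome"].unique():
        c = markers.genotype_plants(panel, chrom, (config.absent_max, config.half_max))
        null_counts[chrom] = int((c["call"] == "D").sum())
    best = max(null_counts, key=lambda c: (null_counts[c], c))
    return (best if null_counts[best] > 0 else None), calls


@_stage("expression_screen")
def _run_screen(matrix: ExpressionMatrix, tissue_matrix: ExpressionMatrix | None,
                gene_map: pd.Series, homeologs: pd.DataFrame | None,
                config: PipelineConfig, out: Path, files: dict) -> int | None:
    if tissue_matrix is None or homeologs is None:
        logger.info("tissue matrix or homeolog table missing; skipping screen")
        return None
    focal_genes = gene_map.index[gene_map == config.focal_chromosome]
    chrom_specific = expression.homeolog_specific_genes(focal_genes, homeologs)

    tissue_fpkm = expression.fpkm(tissue_matrix.counts, tissue_matrix.gene_lengths)
    tissue_specific, assignments, cluster_summary = expression.tissue_specific_genes(
        tissue_fpkm, config.target_tissue, k=config.k,
        specificity_cutoff=config.specificity_cutoff, seed=config.seed)
    files["clusters"] = out / "tissue_clusters.tsv"
    assignments.to_frame().to_csv(files["clusters"], sep="\t")
    files["cluster_summary"] = out / "tissue_cluster_summary.tsv"
    cluster_summary.to_csv(files["cluster_summary"], sep="\t", float_format="%.6g")

    deg_set = None
    groups = matrix.samples["group"]
    a = groups.index[groups == "T"].tolist()
    b = groups.index[groups == "D"].tolist()
    if len(a) >= 2 and len(b) >= 2:
        deg_result = expression.deg_test(matrix.counts, a, b, matrix.gene_lengths,
                                         fc_min=config.fc_min, fdr_max=config.fdr_max)
        files["deg"] = out / "deg.tsv"
        deg_result.table.to_csv(files["deg"], sep="\t", float_format="%.6g")
        deg_set = set(deg_result.significant)

    report = expression.intersect_candidates(chrom_specific, tissue_specific, deg_set)
    files["candidates"] = out / "candidate_genes.tsv"
    report.provenance.to_csv(files["candidates"], sep="\t")
    return len(report.candidates)


@_stage("segregation_genetics")
def _run_segregation(progeny_classes: pd.Series, config: PipelineConfig,
                     out: Path, files: dict) -> None:
    counts = progeny_classes.value_counts()
    t, m, d = int(counts.get("T", 0)), int(counts.get("M", 0)), int(counts.get("D", 0))
    rows = []
    for name, ratio, labels, obs in [
        ("T:M:D_1:2:1", [1, 2, 1], ["T", "M", "D"], [t, m, d]),
        ("fertile:sterile_3:1", [3, 1], ["T+M", "D"], [t + m, d]),
    ]:
        chi2, df, p = genetics.chisq_gof(genetics.SegregationTable(labels, obs, ratio))
        rows.append((name, ":".join(map(str, obs)), chi2, df, p))
    sim = config.simulation
    exp = genetics.expected_progeny(sim.female_null_transmission, sim.male_null_transmission)
    if all(e > 0 for e in exp):
        scaled = [e * (t + m + d) for e in exp]
        chi2, df, p = genetics.chisq_gof(genetics.SegregationTable(
            ["T", "M", "D"], [t, m, d], list(exp)))
        rows.append(("transmission_model", f"{t}:{m}:{d} vs expected "
                     + ":".join(f"{e:.1f}" for e in scaled), chi2, df, p))
    else:
        logger.info("transmission model puts zero mass on a class; GOF skipped")
    files["segregation"] = out / "segregation_tests.tsv"
    pd.DataFrame(rows, columns=["test", "observed", "chi2", "df", "p"]).to_csv(
        files["segregation"], sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage on simulated or user-supplied inputs and report the
    concordance of the ED scan, the dosage scan and the marker calls."""
    configure_logging(config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    if config.simulate:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed,
                                      focal_chromosome=config.focal_chromosome)
        dataset: SyntheticDataset | None = simulate_dataset(sim_cfg)
        input_files = io.write_dataset(dataset, out / "inputs")
        files.update({f"input_{k}": v for k, v in input_files.items()})
        snps = dataset.snps
        matrix = dataset.counts
        gene_map = dataset.model.genes.set_index("gene_id")["chromosome"]
        homeologs = dataset.model.homeolog_table()
        panel = dataset.markers
        tissue_matrix = dataset.tissue_matrix
        progeny = pd.Series([g.phenotype_class for g in dataset.genotypes],
                            index=[g.sample_id for g in dataset.genotypes])
    else:
        if not (config.counts and config.gene_map):
            raise ParameterError("non-simulated runs need counts and gene_map paths")
        snps = io.read_vcf_bulks(config.vcf) if config.vcf else None
        matrix = io.load_expression_matrix(config.counts, config.gene_map,
                                           config.sample_metadata)
        gmap_table = io.read_gene_map(config.gene_map)
        gene_map = gmap_table["chromosome"]
        homeologs = (io.read_homeolog_table(config.homeolog_table)
                     if config.homeolog_table else None)
        panel = None
        if config.marker_table:
            inten = pd.read_csv(config.marker_table, sep="\t", index_col=0)
            marker_map = pd.DataFrame({"marker_id": inten.columns,
                                       "chromosome": config.focal_chromosome})
            panel = markers.MarkerPanel(markers=marker_map, intensities=inten)
        tissue_matrix = None
        if config.tissue_counts:
            tc = io.read_counts(config.tissue_counts)
            tissue_matrix = ExpressionMatrix(
                counts=tc, gene_lengths=gmap_table["length_bp"].reindex(tc.index))
        progeny = matrix.samples["group"]

    ed_candidate = _run_bsa(snps, config, out, files)
    dosage_null, _ = _run_dosage(matrix, gene_map, config, out, files)
    marker_null = (None, None)
    if panel is not None:
        marker_null = _run_markers(panel, config, out, files)
    n_candidates = _run_screen(matrix, tissue_matrix, gene_map, homeologs,
                               config, out, files)
    _run_segregation(progeny, config, out, files)

    lines = [ed_candidate, dosage_null, marker_null[0]]
    named = [c for c in lines if c is not None]
    concordant = len(named) >= 2 and len(set(named)) == 1
    evidence = named[0] if concordant else None

    report = PipelineReport(
        out_dir=out, ed_candidate=ed_candidate, dosage_nullisomic=dosage_null,
        marker_null=marker_null[0], concordant=concordant,
        evidence_chromosome=evidence, n_candidate_genes=n_candidates, files=files)
    summary_path = out / "report.json"
    summary_path.write_text(json.dumps(report.summary_dict(), indent=2, sort_keys=True) + "\n")
    files["report"] = summary_path
    io.write_manifest(out, [p for p in files.values() if p.is_file()])
    return report
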