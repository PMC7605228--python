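"""File formats: VCF with per-bulk allele depths, TSV tables, GFF3/BED
gene maps, and the output manifest.

TSV with a header row is the interchange format for everything tabular;
SNP allele depths travel as VCF 4.2 with a mandatory per-sample AD field.
All coordinates are 1-based inclusive (VCF/GFF convention).
"""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .config import ParameterError
from .containers import (ALLELES, BULK_FERTILE, BULK_STERILE, ExpressionMatrix,
                         bulk_depth_columns)

__all__ = ["write_vcf_bulks", "read_vcf_bulks", "write_counts", "read_counts",
           "write_gene_map_gff3", "read_gene_map", "read_homeolog_table",
           "write_manifest", "write_dataset", "load_expression_matrix"]

logger = logging.getLogger(__name__)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{fertile}\t{sterile}
"""


def write_vcf_bulks(table: pd.DataFrame, path: str | Path,
                    fertile_name: str = "fertile_bulk",
                    sterile_name: str = "sterile_bulk") -> None:
    """Write a bulk SNP table as VCF 4.2 with two bulk samples carrying AD.

    The table needs ``chrom``, ``pos``, ``ref``, ``alt`` plus the eight
    per-bulk allele-depth columns.  ALT lists the declared alt allele
    first, then any further allele observed in either bulk.
    """
    f_cols = bulk_depth_columns(BULK_FERTILE)
    s_cols = bulk_depth_columns(BULK_STERILE)
    contigs = "".join(f"##contig=<ID={c}>\n" for c in pd.unique(table["chrom"]))
    lines = [_VCF_HEADER.format(contigs=contigs, fertile=fertile_name,
                                sterile=sterile_name)]
    allele_ix = {a: i for i, a in enumerate(ALLELES)}
    for row in table.itertuples(index=False):
        dep_f = [getattr(row, c) for c in f_cols]
        dep_s = [getattr(row, c) for c in s_cols]
        ref, alt = row.ref, row.alt
        alts = [alt] + [a for a in ALLELES
                        if a not in (ref, alt)
                        and (dep_f[allele_ix[a]] or dep_s[allele_ix[a]])]
        order = [ref] + alts
        ad_f = ",".join(str(int(dep_f[allele_ix[a]])) for a in order)
        ad_s = ",".join(str(int(dep_s[allele_ix[a]])) for a in order)
        lines.append(
            f"{row.chrom}\t{int(row.pos)}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\t"
            f"AD:DP\t{ad_f}:{int(sum(dep_f))}\t{ad_s}:{int(sum(dep_s))}\n")
    Path(path).write_text("".join(lines))


def read_vcf_bulks(path: str | Path) -> pd.DataFrame:
    """Read a two-sample VCF into a bulk SNP table of 4-allele depths.

    The first sample is taken as the fertile bulk, the second as the
    sterile bulk.  A missing AD FORMAT field is fatal.  Records whose REF
    is not a single A/C/G/T base are dropped (logged); non-ACGT ALT
    alleles are ignored within a record.
    """
    vcf = pysam.VariantFile(str(path))
    if "AD" not in vcf.header.formats:
        raise ParameterError("VCF lacks the AD FORMAT field (per-allele depths required)")
    sample_names = list(vcf.header.samples)
    if len(sample_names) != 2:
        raise ParameterError(f"expected exactly 2 bulk samples, found {len(sample_names)}")
    allele_ix = {a: i for i, a in enumerate(ALLELES)}
    rows, n_dropped = [], 0
    for rec in vcf:
        alleles = (rec.ref,) + tuple(rec.alts or ())
        if rec.ref not in allele_ix:
            n_dropped += 1
            continue
        depths = {bulk: np.zeros(4, dtype=int) for bulk in (BULK_FERTILE, BULK_STERILE)}
        ok = True
        for bulk, sample in zip((BULK_FERTILE, BULK_STERILE), sample_names):
            ad = rec.samples[sample].get("AD")
            if ad is None:
                raise ParameterError(
                    f"record {rec.chrom}:{rec.pos} sample {sample} lacks AD")
            for allele, depth in zip(alleles, ad):
                if depth is None:
                    continue
                if allele in allele_ix:
                    depths[bulk][allele_ix[allele]] += int(depth)
                elif allele == rec.ref:
                    ok = False  # indel reference: no SNP frequency possible
        if not ok:
            n_dropped += 1
            continue
        rows.append((rec.chrom, rec.pos, rec.ref,
                     alleles[1] if len(alleles) > 1 and alleles[1] in allele_ix else rec.ref,
                     *depths[BULK_FERTILE], *depths[BULK_STERILE]))
    if n_dropped:
        logger.info("dropped %d non-SNP (indel) records", n_dropped)
    cols = (["chrom", "pos", "ref", "alt"] + bulk_depth_columns(BULK_FERTILE)
            + bulk_depth_columns(BULK_STERILE))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_counts(matrix: ExpressionMatrix, counts_path: str | Path,
                 samples_path: str | Path | None = None) -> None:
    """Write counts as TSV (gene_id first column) and sample metadata."""
    df = matrix.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(counts_path, sep="\t")
    if samples_path is not None:
        s = matrix.samples.copy()
        s.index.name = "sample_id"
        s.to_csv(samples_path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count TSV; duplicate gene ids are fatal."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParameterError(f"duplicate gene ids in {path}: {dup[:5]}")
    bad = df.columns[~df.dtypes.apply(lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        raise ParameterError(f"non-numeric count columns in {path}: {bad.tolist()}")
    return df


def write_gene_map_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a minimal GFF3 gene map.

    ``genes`` needs gene_id, chromosome and length_bp; genes are laid end
    to end along each chromosome so that end - start + 1 round-trips the
    length.
    """
    lines = ["##gff-version 3\n"]
    cursor: dict[str, int] = {}
    for row in genes.itertuples(index=False):
        start = cursor.get(row.chromosome, 1)
        end = start + int(row.length_bp) - 1
        cursor[row.chromosome] = end + 1
        lines.append(f"{row.chromosome}\thexanull\tgene\t{start}\t{end}\t.\t+\t.\t"
                     f"ID={row.gene_id}\n")
    Path(path).write_text("".join(lines))


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Read a gene map from GFF3 (``gene`` features, 1-based inclusive) or
    BED (0-based half-open; detected by the .bed extension).

    Returns a frame indexed by gene_id with columns ``chromosome`` and
    ``length_bp``.  Malformed lines are reported with their line number.
    """
    path = Path(path)
    rows = []
    if path.suffix.lower() == ".bed":
        for ln, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParameterError(f"{path}:{ln}: BED line needs >= 4 columns")
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            except ValueError as err:
                raise ParameterError(f"{path}:{ln}: {err}") from None
            rows.append((name, chrom, end - start))
    else:
        for ln, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParameterError(f"{path}:{ln}: GFF3 line needs 9 columns")
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as err:
                raise ParameterError(f"{path}:{ln}: {err}") from None
            attrs = _parse_gff3_attributes(parts[8])
            if "ID" not in attrs:
                raise ParameterError(f"{path}:{ln}: gene feature lacks an ID attribute")
            rows.append((attrs["ID"], parts[0], end - start + 1))
    out = pd.DataFrame(rows, columns=["gene_id", "chromosome", "length_bp"])
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParameterError(f"duplicate gene ids in {path}: {dup[:5]}")
    return out.set_index("gene_id")


def read_homeolog_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format homeolog table (group_id, gene_id, chromosome)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"group_id", "gene_id", "chromosome"} - set(df.columns)
    if missing:
        raise ParameterError(f"homeolog table missing columns: {sorted(missing)}")
    return df


def load_expression_matrix(counts_path: str | Path, gene_map_path: str | Path,
                           samples_path: str | Path | None = None) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from a count TSV, a gene map and
    optional sample metadata."""
    counts = read_counts(counts_path)
    gmap = read_gene_map(gene_map_path)
    missing = counts.index.difference(gmap.index)
    if len(missing):
        raise ParameterError(f"{len(missing)} genes absent from gene map, "
                             f"e.g. {missing[:5].tolist()}")
    samples = None
    if samples_path is not None:
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionMatrix(counts=counts,
                            gene_lengths=gmap["length_bp"].reindex(counts.index),
                            samples=samples)


def write_manifest(out_dir: str | Path, files: list[str | Path]) -> Path:
    """Write a manifest TSV listing every output with its sha256 digest."""
    out_dir = Path(out_dir)
    rows = []
    for f in files:
        f = Path(f)
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        rows.append((f.name, f.stat().st_size, digest))
    manifest = out_dir / "MANIFEST.tsv"
    pd.DataFrame(rows, columns=["file", "bytes", "sha256"]).to_csv(
        manifest, sep="\t", index=False)
    return manifest


def write_dataset(dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every simulated input to ``out_dir`` and return the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["config"] = out / "simulation.yaml"
    dataset.config.to_yaml(paths["config"])

    if dataset.snps is not None:
        paths["vcf"] = out / "bulks.vcf"
        write_vcf_bulks(dataset.snps, paths["vcf"])

    paths["counts"] = out / "counts.tsv"
    paths["samples"] = out / "samples.tsv"
    write_counts(dataset.counts, paths["counts"], paths["samples"])

    paths["gene_map"] = out / "genes.gff3"
    write_gene_map_gff3(dataset.model.genes, paths["gene_map"])

    paths["homeologs"] = out / "homeologs.tsv"
    dataset.model.homeolog_table().to_csv(paths["homeologs"], sep="\t", index=False)

    paths["markers"] = out / "marker_intensities.tsv"
    mi = dataset.markers.intensities.copy()
    mi.index.name = "plant"
    mi.to_csv(paths["markers"], sep="\t", float_format="%.6g")
    paths["marker_map"] = out / "marker_map.tsv"
    dataset.markers.markers.to_csv(paths["marker_map"], sep="\t", index=False)

    paths["tissue_counts"] = out / "tissue_counts.tsv"
    paths["tissue_samples"] = out / "tissue_samples.tsv"
    write_counts(dataset.tissue_matrix, paths["tissue_counts"], paths["tissue_samples"])

    paths["truth"] = out / "truth_labels.tsv"
    truth = dataset.model.genes[["gene_id", "chromosome", "homeolog_group",
                                 "tissue_profile"]].copy()
    focal = dataset.config.focal_chromosome
    truth["chromosome_specific"] = truth["gene_id"].isin(
        dataset.model.chromosome_specific_genes(focal))
    truth.to_csv(paths["truth"], sep="\t", index=False)

    paths["progeny"] = out / "progeny.tsv"
    pd.DataFrame({
        "sample_id": [g.sample_id for g in dataset.genotypes],
        "focal_copy_number": [g.copy_number[focal] for g in dataset.genotypes],
        "phenotype_class": [g.phenotype_class for g in dataset.genotypes],
    }).to_csv(paths["progeny"], sep="\t", index=False)

    write_manifest(out, list(paths.values()))
    return paths
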