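"""Readers and writers for the pipeline's file formats.

Coordinate dialects are the standard ones: FASTA wrapped at 60 columns,
GFF3 and VCF 1-based inclusive, BED 0-based half-open, TSV with a header
row. The cow's genotype is written phased as maternal|paternal (documented
in the VCF header); the sire's genotype is unphased. Reading goes through
Biopython (FASTA), pyranges (GFF3) and pysam (VCF).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qc import RoHRegion
from .simulate import SimulationConfig, SyntheticBundle

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_bundle",
    "load_bundle",
]


def write_fasta(genome: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    """Genes and exons as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exons_by_gene = dict(tuple(exons.groupby("gene_id")))
        for g in genes.itertuples():
            fh.write(
                f"{g.chrom}\tase_atlas\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for e in exons_by_gene.get(g.gene_id, pd.DataFrame()).itertuples():
                fh.write(
                    f"{e.chrom}\tase_atlas\texon\t{e.start}\t{e.end}\t.\t{g.strand}\t.\t"
                    f"ID={e.exon_id};Parent={g.gene_id}\n"
                )


def read_gff3(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (genes, exons) frames with 1-based inclusive start/end."""
    df = pyranges.read_gff3(str(path)).df
    genes = df[df["Feature"] == "gene"].copy()
    exons = df[df["Feature"] == "exon"].copy()
    genes_out = pd.DataFrame(
        {
            "gene_id": genes["ID"].to_numpy(),
            "chrom": genes["Chromosome"].astype(str).to_numpy(),
            "start": genes["Start"].to_numpy() + 1,
            "end": genes["End"].to_numpy(),
            "strand": genes["Strand"].astype(str).to_numpy(),
        }
    ).sort_values("gene_id").reset_index(drop=True)
    exon_ids = exons["ID"].astype(str)
    exons_out = pd.DataFrame(
        {
            "gene_id": exons["Parent"].astype(str).to_numpy(),
            "exon_id": exon_ids.to_numpy(),
            "exon_index": exon_ids.str.extract(r"\.e(\d+)$")[0].astype("Int64").to_numpy(),
            "chrom": exons["Chromosome"].astype(str).to_numpy(),
            "start": exons["Start"].to_numpy() + 1,
            "end": exons["End"].to_numpy(),
        }
    ).sort_values(["gene_id", "exon_index"]).reset_index(drop=True)
    return genes_out, exons_out


_VCF_HEADER_EXTRA = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene whose exon contains the SNP">',
    '##INFO=<ID=EXON,Number=1,Type=String,Description="Exon containing the SNP">',
    '##INFO=<ID=PRIV,Number=1,Type=Integer,Description="Rediscovered in private variant detection (1/0)">',
    '##INFO=<ID=POPHET,Number=1,Type=Integer,Description="Heterozygous in at least one other animal (1/0)">',
    '##INFO=<ID=ERR,Number=1,Type=Integer,Description="Simulation truth: false-heterozygous error SNP (1/0)">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype; COW is phased maternal|paternal">',
]


def write_vcf(variants: pd.DataFrame, contig_lengths: dict, path) -> None:
    """Cow (phased maternal|paternal) and sire genotypes as VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ase_atlas_synthetic\n")
        fh.write("##phasing=COW genotype phased as maternal|paternal\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for line in _VCF_HEADER_EXTRA:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCOW\tSIRE\n")
        for v in variants.itertuples():
            cow_gt = "0|1" if v.maternal_allele == v.ref_allele else "1|0"
            alleles = {v.ref_allele: "0", v.alt_allele: "1"}
            sire_gt = f"{alleles[v.sire_allele1]}/{alleles[v.sire_allele2]}"
            info = (
                f"GENE={v.gene_id};EXON={v.exon_id};"
                f"PRIV={int(v.private_detected)};POPHET={int(v.pop_het)};ERR={int(v.is_error)}"
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.snp_id}\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t"
                f"{info}\tGT\t{cow_gt}\t{sire_gt}\n"
            )


def read_vcf(path, require_phased: bool = True) -> pd.DataFrame:
    """Load cow+sire genotypes back into the variant table layout."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if samples[:1] != ["COW"]:
            raise ValueError("expected first VCF sample to be COW")
        for rec in vf:
            cow = rec.samples["COW"]
            if require_phased and not cow.phased:
                raise ValueError(f"unphased cow genotype at {rec.chrom}:{rec.pos}")
            ref, alt = rec.ref, rec.alts[0]
            alleles = [ref, alt]
            maternal = alleles[cow["GT"][0]]
            paternal = alleles[cow["GT"][1]]
            sire = rec.samples["SIRE"]["GT"] if "SIRE" in rec.samples else None
            info = rec.info
            if sire is not None:
                s1, s2 = alleles[sire[0]], alleles[sire[1]]
                origin = "ambiguous" if s1 != s2 else "definitive"
            else:
                s1 = s2 = None
                origin = "ambiguous"
            rows.append(
                {
                    "snp_id": rec.id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref_allele": ref,
                    "alt_allele": alt,
                    "maternal_allele": maternal,
                    "paternal_allele": paternal,
                    "origin_status": origin,
                    "sire_allele1": s1,
                    "sire_allele2": s2,
                    "gene_id": info.get("GENE"),
                    "exon_id": info.get("EXON"),
                    "is_error": bool(info.get("ERR", 0)),
                    "private_detected": bool(info.get("PRIV", 1)),
                    "pop_het": bool(info.get("POPHET", 1)),
                }
            )
    return pd.DataFrame(rows)


def write_bed(regions, path) -> None:
    """RoH regions as BED (0-based half-open)."""
    rows = [{"chrom": r.chrom, "start": r.start, "end": r.end} for r in regions]
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> list[RoHRegion]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
    return [RoHRegion(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]


_BUNDLE_FILES = {
    "genome": "genome.fa",
    "annotation": "genes.gff3",
    "vcf": "variants.vcf",
    "counts": "allele_counts.tsv",
    "truth": "truth.tsv",
    "exon_counts": "exon_counts.tsv",
    "config": "config.yaml",
}


def write_bundle(bundle: SyntheticBundle, directory) -> dict:
    """Write the full synthetic input set; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _BUNDLE_FILES.items()}
    write_fasta(bundle.genome, paths["genome"])
    write_gff3(bundle.genes, bundle.exons, paths["annotation"])
    write_vcf(bundle.variants, {c: len(s) for c, s in bundle.genome.items()}, paths["vcf"])
    bundle.counts.to_csv(paths["counts"], sep="\t", index=False)
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    if bundle.exon_counts is not None:
        bundle.exon_counts.to_csv(paths["exon_counts"], sep="\t", index=False)
    else:
        paths.pop("exon_counts")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)
    return paths


def load_bundle(directory) -> SyntheticBundle:
    """Re-load a written bundle; reproduces the in-memory objects."""
    directory = Path(directory)
    with open(directory / _BUNDLE_FILES["config"]) as fh:
        config = SimulationConfig.from_dict(yaml.safe_load(fh))
    genome = read_fasta(directory / _BUNDLE_FILES["genome"])
    genes, exons = read_gff3(directory / _BUNDLE_FILES["annotation"])
    variants = read_vcf(directory / _BUNDLE_FILES["vcf"])
    counts = pd.read_csv(directory / _BUNDLE_FILES["counts"], sep="\t")
    truth = pd.read_csv(
        directory / _BUNDLE_FILES["truth"], sep="\t", keep_default_na=False,
        dtype={"cluster_id": str},
    )
    exon_path = directory / _BUNDLE_FILES["exon_counts"]
    exon_counts = pd.read_csv(exon_path, sep="\t") if exon_path.exists() else None
    return SyntheticBundle(config, genome, genes, exons, variants, truth, counts, exon_counts)
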