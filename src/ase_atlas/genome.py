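"""Parental genome construction and SNP-to-exon mapping.

Reads from a heterozygous individual are aligned to two personalised copies
of the reference: one carrying the maternal allele at every phased SNP, one
carrying the paternal allele. Building those genomes is a pure sequence of
single-base substitutions (SNPs only, so coordinates stay shared across all
three genomes). The parent of origin of each allele is resolved from the
sire's genotype: a sire homozygous for one of the cow's two alleles pins
that allele as paternal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhasedVariant",
    "ParentalGenomePair",
    "build_parental_genomes",
    "assign_allele_parent",
    "map_snps_to_exons",
]


@dataclass
class PhasedVariant:
    """A heterozygous SNP with parental allele assignment and QC flags."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    maternal_allele: str | None = None
    paternal_allele: str | None = None
    origin_status: str = "definitive"  # definitive | ambiguous | inconsistent
    gene_id: str | None = None
    private_detected: bool = True
    pop_het: bool = True
    in_roh: bool = False


@dataclass
class ParentalGenomePair:
    """Maternal and paternal sequences plus the substitution log."""

    maternal: dict[str, str]
    paternal: dict[str, str]
    substitutions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "pos", "maternal", "paternal"])
    )


def assign_allele_parent(
    cow_genotype: tuple[str, str], sire_genotype: tuple[str, str]
) -> tuple[str | None, str | None, str]:
    """Resolve parent of origin of a heterozygous cow genotype from the sire.

    Returns (maternal_allele, paternal_allele, status). A sire homozygous
    X/X with X among the cow's alleles transmits X, so paternal = X and
    maternal = the other allele (definitive). A heterozygous sire leaves
    the origin ambiguous; a sire homozygous for an allele the cow lacks is
    Mendelian-inconsistent.
    """
    c1, c2 = cow_genotype
    s1, s2 = sire_genotype
    if c1 == c2:
        raise ValueError("cow genotype must be heterozygous")
    if s1 != s2:
        return None, None, "ambiguous"
    if s1 == c1:
        return c2, c1, "definitive"
    if s1 == c2:
        return c1, c2, "definitive"
    return None, None, "inconsistent"


def build_parental_genomes(
    reference: Mapping[str, str], variants: Sequence[PhasedVariant] | pd.DataFrame
) -> ParentalGenomePair:
    """Substitute each phased SNP's parental allele into a reference copy.

    ``variants`` rows need chrom, pos (1-based), ref/alt and definitive
    maternal/paternal alleles; non-definitive variants are passed over (both
    genomes keep the reference base, matching how the original alignment
    treats unphased sites). Raises ValueError when a variant's stated
    reference allele disagrees with the genome or lies out of range.
    """
    if isinstance(variants, pd.DataFrame):
        records = variants.to_dict("records")
    else:
        records = [v.__dict__ for v in variants]

    maternal = {c: bytearray(s, "ascii") for c, s in reference.items()}
    paternal = {c: bytearray(s, "ascii") for c, s in reference.items()}
    log_rows = []
    for v in records:
        chrom, pos = v["chrom"], int(v["pos"])
        if chrom not in maternal:
            raise ValueError(f"variant on unknown chromosome {chrom!r}")
        if not (1 <= pos <= len(maternal[chrom])):
            raise ValueError(f"variant position {chrom}:{pos} out of range")
        ref_here = reference[chrom][pos - 1]
        ref_allele = v.get("ref_allele") or v.get("ref")
        if ref_allele is not None and ref_here.upper() != str(ref_allele).upper():
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: genome has {ref_here}, variant says {ref_allele}"
            )
        mat = v.get("maternal_allele") or v.get("maternal")
        pat = v.get("paternal_allele") or v.get("paternal")
        if v.get("origin_status", "definitive") != "definitive" or mat is None or pat is None:
            continue
        maternal[chrom][pos - 1] = ord(str(mat))
        paternal[chrom][pos - 1] = ord(str(pat))
        log_rows.append({"chrom": chrom, "pos": pos, "maternal": str(mat), "paternal": str(pat)})

    return ParentalGenomePair(
        maternal={c: s.decode("ascii") for c, s in maternal.items()},
        paternal={c: s.decode("ascii") for c, s in paternal.items()},
        substitutions=pd.DataFrame(log_rows, columns=["chrom", "pos", "maternal", "paternal"]),
    )


def map_snps_to_exons(variants: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Annotate SNPs with the gene whose exon they fall in.

    ``exons`` needs columns chrom, start, end (1-based inclusive), gene_id.
    A SNP at an exon boundary coordinate is included. Strand is ignored —
    counting is positional. SNPs outside every exon get gene_id NA and are
    excluded downstream. Overlapping genes each produce a row (the SNP is
    duplicated) and a warning is logged.
    """
    out_rows = []
    exons_by_chrom = {c: g.sort_values("start") for c, g in exons.groupby("chrom")}
    n_multi = 0
    for row in variants.to_dict("records"):
        ex = exons_by_chrom.get(row["chrom"])
        if ex is None:
            hits = []
        else:
            inside = (ex["start"] <= row["pos"]) & (row["pos"] <= ex["end"])
            hits = ex.loc[inside, "gene_id"].unique().tolist()
        if not hits:
            out_rows.append({**row, "gene_id": pd.NA})
        else:
            if len(hits) > 1:
                n_multi += 1
            for g in hits:
                out_rows.append({**row, "gene_id": g})
    if n_multi:
        logger.warning("%d SNPs overlap exons of multiple genes; all gene assignments kept", n_multi)
    return pd.DataFrame(out_rows)
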