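"""Allele-specific expression testing on dual parental-genome allele counts.

Each heterozygous exonic SNP is covered by two alignments of the same RNA-seq
reads: one against the maternal genome (which carries the maternal allele at
the site) and one against the paternal genome. Per SNP and tissue four counts
are kept:

    r_m  reads matching the maternal genome's allele in the maternal alignment
    a_m  reads mismatching in the maternal alignment
    r_p  reads matching the paternal genome's allele in the paternal alignment
    a_p  reads mismatching in the paternal alignment

Because mismatching reads are the ones exposed to allele-specific mapping
loss, the cross-product statistic below is insensitive to a symmetric loss of
mismatching reads, and with no loss it reduces exactly to the 50:50
goodness-of-fit chi-square. The statistic is halved because the two
alignments count the same reads twice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "chi_square_ase",
    "maternal_fraction",
    "ase_test",
    "classify_mae",
    "summarize_gene_level",
    "classify_imprinting",
    "imprinting_status",
    "IMPRINTING_STATUSES",
]

IMPRINTING_STATUSES = (
    "NotImprinted",
    "Imprinted",
    "PartiallyImprinted",
    "TissueSpecificallyImprinted",
    "TissueSpecificPartiallyImprinted",
)


def _as_float_arrays(*cols):
    return [np.asarray(c, dtype=float) for c in cols]


def chi_square_ase(r_m, a_m, r_p, a_p):
    """Halved 2x2 chi-square for allelic imbalance.

    chi2_half = ((r_m*a_p - a_m*r_p)^2 * N / (r*a*m*p)) / 2 with
    r = r_m + r_p, a = a_m + a_p, m = r_m + a_m, p = r_p + a_p, N = m + p.
    Equal to the Pearson independence chi-square of the 2x2 table
    (rows = alignment, columns = match status) divided by two.

    Returns NaN where any marginal is zero (statistic undefined).
    Accepts scalars or arrays.
    """
    r_m, a_m, r_p, a_p = _as_float_arrays(r_m, a_m, r_p, a_p)
    if np.any(r_m < 0) or np.any(a_m < 0) or np.any(r_p < 0) or np.any(a_p < 0):
        raise ValueError("allele counts must be non-negative")
    r = r_m + r_p
    a = a_m + a_p
    m = r_m + a_m
    p = r_p + a_p
    n = m + p
    denom = r * a * m * p
    with np.errstate(divide="ignore", invalid="ignore"):
        cross = r_m * a_p - a_m * r_p
        chi2 = np.where(denom > 0, cross * cross * n / np.where(denom > 0, denom, 1.0), np.nan)
    out = chi2 / 2.0
    if out.ndim == 0:
        return float(out)
    return out


def maternal_fraction(r_m, a_m, r_p, a_p):
    """Maternal-allele share, averaged over the two alignments.

    The maternal alignment estimates it as r_m/m (matching reads carry the
    maternal allele there); the paternal alignment as a_p/p (mismatching
    reads carry the maternal allele). Averaging the two partially cancels
    allele-specific mapping loss. NaN where either alignment has no reads.
    """
    r_m, a_m, r_p, a_p = _as_float_arrays(r_m, a_m, r_p, a_p)
    m = r_m + a_m
    p = r_p + a_p
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 0.5 * (r_m / m + a_p / p)
    out = np.where((m > 0) & (p > 0), frac, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def classify_mae(significant, major_freq, threshold: float = 0.9):
    """Mono-allelic expression: significant ASE with major-allele frequency
    at or above ``threshold`` (inclusive)."""
    significant = np.asarray(significant, dtype=bool)
    major_freq = np.asarray(major_freq, dtype=float)
    out = significant & (major_freq >= threshold)
    if out.ndim == 0:
        return bool(out)
    return out


def ase_test(
    counts: pd.DataFrame,
    alpha: float = 0.01,
    mae_threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-SNP, per-tissue ASE test.

    Parameters
    ----------
    counts
        Table with columns ``snp_id, tissue, r_m, a_m, r_p, a_p`` (extra
        columns such as ``gene_id`` are carried through).
    alpha
        Significance level on the raw p-value (no multiplicity correction;
        calls are threshold-based).
    mae_threshold
        Major-allele frequency at which significant ASE is called
        mono-allelic (inclusive).

    Returns
    -------
    DataFrame with the input columns plus ``chi2_half, p_value, significant,
    maternal_fraction, major_parent, major_freq, mae, reason``. SNPs with a
    zero marginal carry reason ``degenerate_margin`` and NaN statistics.
    """
    out = counts.copy()
    r_m = out["r_m"].to_numpy(dtype=float)
    a_m = out["a_m"].to_numpy(dtype=float)
    r_p = out["r_p"].to_numpy(dtype=float)
    a_p = out["a_p"].to_numpy(dtype=float)

    chi2_half = chi_square_ase(r_m, a_m, r_p, a_p)
    chi2_half = np.atleast_1d(chi2_half)
    p_value = np.where(np.isnan(chi2_half), np.nan, stats.chi2.sf(chi2_half, df=1))
    significant = (p_value < alpha) & ~np.isnan(p_value)

    frac = np.atleast_1d(maternal_fraction(r_m, a_m, r_p, a_p))
    major_freq = np.maximum(frac, 1.0 - frac)
    major_parent = np.where(
        np.isnan(frac), "unknown", np.where(frac > 0.5, "maternal", np.where(frac < 0.5, "paternal", "tie"))
    )
    mae = classify_mae(significant, np.where(np.isnan(major_freq), 0.0, major_freq), mae_threshold)

    out["chi2_half"] = chi2_half
    out["p_value"] = p_value
    out["significant"] = significant
    out["maternal_fraction"] = frac
    out["major_parent"] = major_parent
    out["major_freq"] = major_freq
    out["mae"] = np.atleast_1d(mae)
    out["reason"] = np.where(np.isnan(chi2_half), "degenerate_margin", "")
    return out


def _collapse_samples(results: pd.DataFrame) -> pd.DataFrame:
    """Union significance over a ``sample`` column when present, so multi-
    animal runs count a SNP/gene as ASE if significant in any sample."""
    if "sample" not in results.columns:
        return results
    keys = ["snp_id", "tissue"]
    extra = [c for c in ("gene_id", "exon_id") if c in results.columns]
    agg = {"significant": "any", "mae": "any", "major_freq": "max"}
    grouped = results.groupby(keys + extra, as_index=False).agg(agg)
    return grouped


def summarize_gene_level(results: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue and overall ASE summary.

    ``results`` must carry ``snp_id, tissue, gene_id, significant, mae`` for
    tested SNPs only (drop degenerate/filtered rows upstream). Returns one
    row per tissue plus a ``Total`` row with columns:

    snps_tested, ase_snps, genes_tested, genes_multi_snp, genes_ase,
    genes_multi_ase, mae_snps, genes_mae, genes_multi_mae, genes_ts_ase

    where ``genes_ts_ase`` counts genes (tested in that tissue) showing
    significant ASE in at least one but not all tissues in which the gene
    was tested.
    """
    results = _collapse_samples(results)
    results = results[results["significant"].notna()]

    # gene-level across-tissue flags
    per_gene_tissue = results.groupby(["gene_id", "tissue"])["significant"].any()
    n_tissues_tested = per_gene_tissue.groupby("gene_id").size()
    n_tissues_sig = per_gene_tissue.groupby("gene_id").sum()
    ts_ase_genes = set(
        n_tissues_sig[(n_tissues_sig >= 1) & (n_tissues_sig < n_tissues_tested)].index
    )

    rows = []

    def _summary(df: pd.DataFrame, label: str) -> dict:
        by_gene = df.groupby("gene_id")
        n_snps = by_gene["snp_id"].nunique()
        n_sig = by_gene.apply(lambda g: g.loc[g["significant"], "snp_id"].nunique(), include_groups=False)
        n_mae = by_gene.apply(lambda g: g.loc[g["mae"], "snp_id"].nunique(), include_groups=False)
        genes_here = set(by_gene.groups)
        return {
            "tissue": label,
            "snps_tested": df["snp_id"].nunique(),
            "ase_snps": df.loc[df["significant"], "snp_id"].nunique(),
            "genes_tested": len(genes_here),
            "genes_multi_snp": int((n_snps > 1).sum()),
            "genes_ase": int((n_sig >= 1).sum()),
            "genes_multi_ase": int((n_sig > 1).sum()),
            "mae_snps": df.loc[df["mae"], "snp_id"].nunique(),
            "genes_mae": int((n_mae >= 1).sum()),
            "genes_multi_mae": int((n_mae > 1).sum()),
            "genes_ts_ase": len(genes_here & ts_ase_genes),
        }

    for tissue, df in results.groupby("tissue"):
        rows.append(_summary(df, str(tissue)))
    rows.append(_summary(results, "Total"))
    return pd.DataFrame(rows)


def classify_imprinting(
    results: pd.DataFrame,
    candidate_genes=None,
    min_reads: int = 10,
    maf_threshold: float = 0.9,
) -> pd.DataFrame:
    """Classify candidate genes by imprinting status across tissues.

    A gene is testable in a tissue when it is expressed there with at least
    ``min_reads`` reads over its heterozygous SNPs and at least one SNP was
    testable. Per testable tissue the gene is *imprinted* when it shows
    significant ASE with major-allele frequency above ``maf_threshold``
    (strict, full silencing of one allele) and *partially imprinted* when
    ASE is significant but the silenced allele is still detectably
    expressed.

    The across-tissue status is a pure function of three booleans:
    whether the gene shows ASE at all, whether every ASE tissue exceeds the
    major-allele-frequency gate, and whether ASE covers all testable
    tissues:

    ========================  ====  =========  ===========
    status                    ASE   MAF gate   all tissues
    ========================  ====  =========  ===========
    NotImprinted              no    --         --
    Imprinted                 yes   yes        yes
    PartiallyImprinted        yes   no         yes
    TissueSpecificallyImprinted  yes  yes      no
    TissueSpecificPartiallyImprinted  yes  no  no
    ========================  ====  =========  ===========
    """
    df = results
    if candidate_genes is not None:
        df = df[df["gene_id"].isin(set(candidate_genes))]
    if "depth" not in df.columns:
        df = df.assign(depth=df["r_m"] + df["a_m"] + df["r_p"] + df["a_p"])
        # depth over both alignments double-counts reads; halve for the gate
        df["depth"] = df["depth"] / 2.0

    calls = []
    for gene_id, g in df.groupby("gene_id"):
        per_tissue = g.groupby("tissue").agg(
            reads=("depth", "sum"),
            sig=("significant", "any"),
            maf=("major_freq", "max"),
        )
        testable = per_tissue[per_tissue["reads"] >= min_reads]
        if testable.empty:
            continue
        sig = testable[testable["sig"]]
        ase = len(sig) > 0
        n_imprinted = int((sig["maf"] > maf_threshold).sum())
        n_partial = int((sig["maf"] <= maf_threshold).sum())
        maf_gate = ase and n_partial == 0
        all_tissues = ase and len(sig) == len(testable)
        status = imprinting_status(ase, maf_gate, all_tissues)
        calls.append(
            {
                "gene_id": gene_id,
                "ase": ase,
                "maf_gt_90": maf_gate,
                "all_tissues": all_tissues,
                "n_tissues_expressed": len(testable),
                "n_tissues_imprinted": n_imprinted,
                "n_tissues_partial": n_partial,
                "status": status,
            }
        )
    return pd.DataFrame(
        calls,
        columns=[
            "gene_id",
            "ase",
            "maf_gt_90",
            "all_tissues",
            "n_tissues_expressed",
            "n_tissues_imprinted",
            "n_tissues_partial",
            "status",
        ],
    )


def imprinting_status(ase: bool, maf_gt_90: bool, all_tissues: bool) -> str:
    """Truth-table mapping from the three gene-level booleans to a status."""
    if not ase:
        return "NotImprinted"
    if maf_gt_90 and all_tissues:
        return "Imprinted"
    if not maf_gt_90 and all_tissues:
        return "PartiallyImprinted"
    if maf_gt_90:
        return "TissueSpecificallyImprinted"
    return "TissueSpecificPartiallyImprinted"
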