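"""Gene-level parent-of-origin classification and genomic clustering.

Once SNP-level ASE calls carry a definitive maternal/paternal assignment,
each gene x tissue is classified by majority vote over its significant
SNPs (75 % majority or "undecided"), and the ordered sequence of classified
genes along the genome is tested for fewer maternal/paternal runs than
random ordering would give (Wald-Wolfowitz), which is the signature of
co-regulated or imprinted gene clusters. Heat-map matrix constructions for
cross-tissue comparison live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_gene_parent",
    "snp_concordance",
    "runs_test",
    "runs_test_by_tissue",
    "run_membership",
    "RunsTestResult",
    "paternal_summary",
    "build_matrices",
    "tissue_similarity",
    "find_runs",
]


@dataclass(frozen=True)
class RunsTestResult:
    """Wald-Wolfowitz runs test on a two-class ordered sequence."""

    n1: int
    n2: int
    r_observed: int
    expected_runs: float
    variance_runs: float
    z: float
    p_one_sided: float  # clustering: fewer runs than expected
    p_two_sided: float


def _classified(results: pd.DataFrame) -> pd.DataFrame:
    keep = (
        results["significant"].astype(bool)
        & results["major_parent"].isin(["maternal", "paternal"])
    )
    if "origin_status" in results.columns:
        keep &= results["origin_status"] == "definitive"
    return results[keep]


def classify_gene_parent(results: pd.DataFrame, ratio_threshold: float = 0.75) -> pd.DataFrame:
    """Majority-vote parent-of-origin call per gene x tissue.

    Uses significant SNPs with definitive origin; the gene is called for
    the parent holding at least ``ratio_threshold`` of its classified SNPs
    (inclusive), otherwise "undecided". Genes with no classified
    significant SNP are absent from the output.
    """
    df = _classified(results)
    if df.empty:
        return pd.DataFrame(
            columns=["gene_id", "tissue", "n_classified", "n_paternal", "n_maternal", "ratio", "class"]
        )
    counts = (
        df.groupby(["gene_id", "tissue"])["major_parent"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["maternal", "paternal"], fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    counts = counts.rename(columns={"maternal": "n_maternal", "paternal": "n_paternal"})
    counts["n_classified"] = counts["n_maternal"] + counts["n_paternal"]
    counts["ratio"] = (
        np.maximum(counts["n_maternal"], counts["n_paternal"]) / counts["n_classified"]
    )
    cls = np.where(
        counts["ratio"] >= ratio_threshold,
        np.where(counts["n_paternal"] >= counts["n_maternal"], "paternal", "maternal"),
        "undecided",
    )
    # an exact 50:50 split can only be undecided for thresholds > 0.5
    counts["class"] = cls
    return counts[["gene_id", "tissue", "n_classified", "n_paternal", "n_maternal", "ratio", "class"]]


def snp_concordance(results: pd.DataFrame, unit: str = "gene_id") -> pd.DataFrame:
    """Per-tissue agreement of the favoured parent between SNPs of a unit.

    Considers units (genes or exons, ``unit`` column) with more than one
    significant, definitively classified SNP; a unit is concordant when all
    its SNPs favour the same parent.
    """
    df = _classified(results)
    rows = []
    for tissue, g in df.groupby("tissue"):
        per_unit = g.groupby(unit)["major_parent"].agg(["nunique", "count"])
        multi = per_unit[per_unit["count"] > 1]
        concordant = int((multi["nunique"] == 1).sum())
        rows.append(
            {
                "tissue": tissue,
                "units_multi_snp": len(multi),
                "units_concordant": concordant,
                "prop_concordant": concordant / len(multi) if len(multi) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def find_runs(labels) -> list[tuple[int, int, object]]:
    """Maximal runs of equal consecutive labels as (start, end_exclusive, label)."""
    labels = list(labels)
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        runs.append((i, j + 1, labels[i]))
        i = j + 1
    return runs


def runs_test(sequence) -> RunsTestResult:
    """Wald-Wolfowitz runs test for clustering of a two-class sequence.

    ``sequence`` is the ordered list of gene classes (undecided genes
    already excluded). With n1 and n2 of each class, n = n1 + n2 and R the
    observed number of maximal runs:

        E[R]   = 2 n1 n2 / n + 1
        Var[R] = 2 n1 n2 (2 n1 n2 - n) / (n^2 (n - 1))

    z = (R - E[R]) / sd; the primary one-sided p-value Phi(z) is small when
    there are fewer runs than expected, i.e. same-parent genes cluster.
    """
    seq = list(sequence)
    values = sorted(set(seq), key=str)
    if len(values) != 2:
        raise ValueError("runs test requires exactly two classes present")
    n1 = sum(1 for s in seq if s == values[0])
    n2 = len(seq) - n1
    r = len(find_runs(seq))
    n = n1 + n2
    expected = 2.0 * n1 * n2 / n + 1.0
    variance = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    z = (r - expected) / np.sqrt(variance) if variance > 0 else np.nan
    p_one = float(stats.norm.cdf(z))
    p_two = float(2 * min(stats.norm.cdf(z), stats.norm.sf(z)))
    return RunsTestResult(n1, n2, r, expected, variance, float(z), p_one, p_two)


def runs_test_by_tissue(
    classes: pd.DataFrame,
    gene_order: pd.DataFrame,
    per_chromosome: bool = False,
) -> pd.DataFrame:
    """Run the runs test per tissue on genes ordered along the genome.

    ``classes`` from :func:`classify_gene_parent`; ``gene_order`` has
    gene_id, chrom, start. Undecided genes are excluded (they do not break
    runs). By default chromosomes are concatenated into one ordered list
    per tissue; ``per_chromosome`` tests each chromosome separately.
    """
    order = gene_order.sort_values(["chrom", "start"]).reset_index(drop=True)
    order["rank"] = np.arange(len(order))
    merged = classes.merge(order[["gene_id", "chrom", "rank"]], on="gene_id")
    merged = merged[merged["class"].isin(["maternal", "paternal"])]
    rows = []
    group_keys = ["tissue", "chrom"] if per_chromosome else ["tissue"]
    for keys, g in merged.groupby(group_keys):
        g = g.sort_values("rank")
        labels = g["class"].tolist()
        row = dict(zip(group_keys, keys if isinstance(keys, tuple) else (keys,)))
        if len(set(labels)) < 2:
            row.update({"n1": np.nan, "n2": np.nan, "r_observed": np.nan, "z": np.nan,
                        "p_one_sided": np.nan, "p_two_sided": np.nan, "testable": False})
        else:
            res = runs_test(labels)
            row.update(
                {
                    "n1": res.n1,
                    "n2": res.n2,
                    "r_observed": res.r_observed,
                    "expected_runs": res.expected_runs,
                    "variance_runs": res.variance_runs,
                    "z": res.z,
                    "p_one_sided": res.p_one_sided,
                    "p_two_sided": res.p_two_sided,
                    "testable": True,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def paternal_summary(
    classes: pd.DataFrame,
    results: pd.DataFrame | None = None,
    exclude_extreme: bool = False,
) -> pd.DataFrame:
    """Per-tissue share of classified genes favouring the paternal allele.

    Optionally also the share favouring the reference allele when
    ``results`` carries a ``major_is_ref`` column (majority vote over the
    gene's classified SNPs). ``exclude_extreme`` recomputes the gene
    classes after dropping fully mono-allelic SNPs (major frequency 1.0),
    which is how the contribution of MAE genes to the paternal excess is
    isolated.
    """
    if exclude_extreme:
        if results is None:
            raise ValueError("exclude_extreme requires SNP-level results")
        kept = results[results["major_freq"] < 1.0]
        classes = classify_gene_parent(kept)

    rows = []
    ref_by_gene_tissue = None
    if results is not None and "major_is_ref" in results.columns:
        df = _classified(results)
        if exclude_extreme:
            df = df[df["major_freq"] < 1.0]
        ref_by_gene_tissue = df.groupby(["gene_id", "tissue"])["major_is_ref"].mean()

    for tissue, g in classes.groupby("tissue"):
        decided = g[g["class"].isin(["maternal", "paternal"])]
        n = len(decided)
        n_pat = int((decided["class"] == "paternal").sum())
        row = {
            "tissue": tissue,
            "genes_classified": n,
            "paternal_genes": n_pat,
            "pct_paternal": 100.0 * n_pat / n if n else np.nan,
        }
        if ref_by_gene_tissue is not None and n:
            idx = pd.MultiIndex.from_arrays([decided["gene_id"], decided["tissue"]])
            share = ref_by_gene_tissue.reindex(idx)
            row["reference_genes"] = int((share > 0.5).sum())
            row["pct_reference"] = 100.0 * (share > 0.5).mean()
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        avg = {"tissue": "Average", "genes_classified": out["genes_classified"].sum(),
               "paternal_genes": out["paternal_genes"].sum(),
               "pct_paternal": out["pct_paternal"].mean()}
        if "pct_reference" in out.columns:
            avg["reference_genes"] = out["reference_genes"].sum()
            avg["pct_reference"] = out["pct_reference"].mean()
        out = pd.concat([out, pd.DataFrame([avg])], ignore_index=True)
    return out


def run_membership(
    classes: pd.DataFrame, gene_order: pd.DataFrame, run_min: int = 5
) -> pd.DataFrame:
    """Genes lying in same-parent runs of >= run_min consecutive classified genes."""
    order = gene_order.sort_values(["chrom", "start"]).reset_index(drop=True)
    order["rank"] = np.arange(len(order))
    merged = classes.merge(order[["gene_id", "rank"]], on="gene_id")
    merged = merged[merged["class"].isin(["maternal", "paternal"])]
    out_rows = []
    for tissue, g in merged.groupby("tissue"):
        g = g.sort_values("rank")
        labels = g["class"].tolist()
        in_run = np.zeros(len(g), dtype=bool)
        for start, end, _ in find_runs(labels):
            if end - start >= run_min:
                in_run[start:end] = True
        for (_, row), flag in zip(g.iterrows(), in_run):
            out_rows.append({"gene_id": row["gene_id"], "tissue": tissue, "in_run": bool(flag)})
    return pd.DataFrame(out_rows, columns=["gene_id", "tissue", "in_run"])


def build_matrices(
    results: pd.DataFrame | None = None,
    classes: pd.DataFrame | None = None,
    gene_order: pd.DataFrame | None = None,
    kind: str = "snp_freq",
    run_min: int = 5,
) -> pd.DataFrame:
    """Heat-map matrix constructions for cross-tissue comparison.

    kind:
      * ``snp_freq`` — SNP x tissue paternal-allele frequency of classified
        ASE SNPs.
      * ``snp_signed`` — SNP x tissue major-allele frequency, multiplied by
        -1 when the major allele is maternal.
      * ``mae_binary`` — SNP x tissue, 1 where mono-allelic.
      * ``gene_signed`` — gene x tissue: paternal +0.5, maternal -0.5,
        undecided/untested 0.
      * ``run_membership`` — gene x tissue, 1 where the gene lies in a
        same-parent run of >= ``run_min`` consecutive classified genes.
    """
    if kind == "snp_freq":
        df = _classified(results)
        df = df.assign(paternal_freq=1.0 - df["maternal_fraction"])
        return df.pivot_table(index="snp_id", columns="tissue", values="paternal_freq")
    if kind == "snp_signed":
        df = _classified(results)
        signed = np.where(df["major_parent"] == "maternal", -df["major_freq"], df["major_freq"])
        df = df.assign(signed_freq=signed)
        return df.pivot_table(index="snp_id", columns="tissue", values="signed_freq")
    if kind == "mae_binary":
        df = results[results["significant"].notna()]
        return (
            df.assign(mae_val=df["mae"].astype(float))
            .pivot_table(index="snp_id", columns="tissue", values="mae_val")
            .fillna(0.0)
        )
    if kind == "gene_signed":
        if classes is None:
            raise ValueError("gene_signed requires gene classifications")
        val = classes["class"].map({"paternal": 0.5, "maternal": -0.5}).fillna(0.0)
        df = classes.assign(signed=val)
        return df.pivot_table(index="gene_id", columns="tissue", values="signed").fillna(0.0)
    if kind == "run_membership":
        if classes is None or gene_order is None:
            raise ValueError("run_membership requires gene classifications and gene order")
        member = run_membership(classes, gene_order, run_min=run_min)
        return (
            member.assign(val=member["in_run"].astype(float))
            .pivot_table(index="gene_id", columns="tissue", values="val")
            .fillna(0.0)
        )
    raise ValueError(f"unknown matrix kind {kind!r}")


def tissue_similarity(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue x tissue similarity (M^T M on complete-case rows) and
    euclidean distances between tissue columns for clustering."""
    complete = matrix.dropna(axis=0, how="any")
    if complete.empty:
        raise ValueError("no SNPs/genes are complete across the compared tissues")
    m = complete.to_numpy(dtype=float)
    sim = pd.DataFrame(m.T @ m, index=complete.columns, columns=complete.columns)
    diff = m.T[:, None, :] - m.T[None, :, :]
    dist = pd.DataFrame(
        np.sqrt((diff**2).sum(axis=2)), index=complete.columns, columns=complete.columns
    )
    return sim, dist
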