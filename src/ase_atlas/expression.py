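"""Expression-level summaries: RNA-molecule proportions, tissue-specific
expression calls, and variance-component decomposition of exon-level log
counts.

The variance model for exon counts is

    y = mu + tissue + replicate + tissue.replicate + exon_order.tissue
        + gene + gene.tissue + gene.exon + error,    y = ln(1 + count)

with tissue/replicate terms and a per-tissue linear trend in exon order
(exon index as a fraction of the gene's exon count, capturing 3' coverage
bias) as fixed effects, and gene, gene.tissue, gene.exon and residual as
independent random effects. On a balanced design the random-effect
variances are estimated by a closed-form method-of-moments decomposition of
the means over each stratum, which is deterministic and directly checkable
against the generative truth; an unbalanced design raises, pointing users
to mixed-model tooling instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "rna_proportion",
    "tse_classify",
    "fit_variance_components",
    "VarianceComponents",
]


def rna_proportion(counts, lengths, gene_ids=None) -> pd.DataFrame:
    """Proportion of RNA molecules attributable to each gene.

    RNA_i = ((Counts_i + 10) / Length_i) / T with
    T = sum_genes (Counts_gene + 10) / Length_gene. The +10 pseudocount
    keeps unexpressed genes at a small nonzero proportion; lengths are the
    summed exon lengths in bases. Proportions sum to one.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must align")
    per_gene = (counts + 10.0) / lengths
    total = per_gene.sum()
    rna = per_gene / total
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(len(counts))]
    return pd.DataFrame(
        {"gene_id": gene_ids, "counts": counts, "length": lengths, "rna_proportion": rna}
    )


def tse_classify(
    expression: pd.DataFrame,
    p_values: pd.DataFrame,
    alpha: float = 0.01,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Tissue-specific expression calls from a gene x tissue matrix.

    ``expression`` is a wide normalised gene x tissue table and
    ``p_values`` a like-shaped table of externally computed differential-
    expression p-values. Per gene and tissue the fold change against the
    mean of all *other* tissues is computed; the gene is TSE-up in a tissue
    when p < ``alpha`` and fold > ``fold_threshold``, TSE-down when
    p < ``alpha`` and fold < 1/``fold_threshold``. The rule is invariant to
    rescaling all tissues by a common factor. Tissues where the other-mean
    is zero are excluded with a reason.
    """
    if expression.shape[1] < 2:
        raise ValueError("TSE needs at least two tissues")
    expr = expression.astype(float)
    n_t = expr.shape[1]
    other_mean = (expr.sum(axis=1).to_numpy()[:, None] - expr.to_numpy()) / (n_t - 1)
    rows = []
    for j, tissue in enumerate(expr.columns):
        for i, gene in enumerate(expr.index):
            om = other_mean[i, j]
            val = expr.iat[i, j]
            p = float(p_values.loc[gene, tissue])
            if om == 0:
                rows.append(
                    {"gene_id": gene, "tissue": tissue, "expression": val, "other_mean": om,
                     "fold": np.nan, "p_value": p, "call": "", "reason": "undefined_fold"}
                )
                continue
            fold = val / om
            call = ""
            if p < alpha and fold > fold_threshold:
                call = "tse_up"
            elif p < alpha and fold < 1.0 / fold_threshold:
                call = "tse_down"
            rows.append(
                {"gene_id": gene, "tissue": tissue, "expression": val, "other_mean": om,
                 "fold": fold, "p_value": p, "call": call, "reason": ""}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect variance estimates and their proportions of total."""

    var_gene: float
    var_gene_tissue: float
    var_gene_exon: float
    var_error: float

    @property
    def total(self) -> float:
        return self.var_gene + self.var_gene_tissue + self.var_gene_exon + self.var_error

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {"gene": 0.0, "gene_tissue": 0.0, "gene_exon": 0.0, "error": 0.0}
        return {
            "gene": self.var_gene / t,
            "gene_tissue": self.var_gene_tissue / t,
            "gene_exon": self.var_gene_exon / t,
            "error": self.var_error / t,
        }


def _remove_fixed_effects(records: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """OLS-project out tissue, replicate, tissue.replicate and the
    per-tissue linear exon-order trend; return residuals."""
    cell = records["tissue"].astype(str) + "~" + records["replicate"].astype(str)
    dummies = pd.get_dummies(cell, dtype=float)
    tissue_dummies = pd.get_dummies(records["tissue"].astype(str), dtype=float)
    trend = tissue_dummies.to_numpy() * records["exon_fraction"].to_numpy()[:, None]
    design = np.column_stack([dummies.to_numpy(), trend])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def fit_variance_components(records: pd.DataFrame, use_y_column: bool = True) -> VarianceComponents:
    """Method-of-moments variance components on a balanced exon-count table.

    ``records`` needs columns tissue, replicate, gene_id, exon_index,
    exon_fraction and count (or a precomputed ``y`` column, preferred when
    present and ``use_y_column``). The design must be balanced: every gene
    observed for every exon index in every tissue x replicate, with a
    common exon count per gene.

    After removing fixed effects, variances are read off the nested means:
    within-cell replicate scatter gives the error variance, the
    between-tissue scatter of per-gene means gives gene.tissue, the
    between-exon scatter gives gene.exon, and the between-gene scatter of
    whole-gene means gives the gene variance, each corrected for the
    noise its mean inherits from lower strata. Estimates are clipped at 0.
    """
    df = records.copy()
    if use_y_column and "y" in df.columns:
        yvals = df["y"].to_numpy(dtype=float)
    else:
        yvals = np.log1p(df["count"].to_numpy(dtype=float))

    genes = df["gene_id"].unique()
    tissues = df["tissue"].unique()
    reps = df["replicate"].unique()
    exons = df["exon_index"].unique()
    n_g, n_t, n_r, n_e = len(genes), len(tissues), len(reps), len(exons)
    if len(df) != n_g * n_t * n_r * n_e or df.duplicated(
        ["gene_id", "tissue", "replicate", "exon_index"]
    ).any():
        raise ValueError(
            "unbalanced exon-count design: method-of-moments estimation requires every "
            "gene x exon x tissue x replicate cell exactly once; use the balanced "
            "generator or external mixed-model tooling (e.g. lme4/statsmodels MixedLM)"
        )

    z = _remove_fixed_effects(df, yvals)
    arr = np.full((n_g, n_e, n_t, n_r), np.nan)
    g_idx = pd.Categorical(df["gene_id"], categories=genes).codes
    e_idx = pd.Categorical(df["exon_index"], categories=exons).codes
    t_idx = pd.Categorical(df["tissue"], categories=tissues).codes
    r_idx = pd.Categorical(df["replicate"], categories=reps).codes
    arr[g_idx, e_idx, t_idx, r_idx] = z

    # error: replicate scatter within (gene, exon, tissue) cells
    if n_r > 1:
        var_error = float(arr.var(axis=3, ddof=1).mean())
    else:
        var_error = 0.0

    m_get = arr.mean(axis=3)                      # gene x exon x tissue
    m_gt = m_get.mean(axis=1)                     # gene x tissue
    m_ge = m_get.mean(axis=2)                     # gene x exon
    m_g = m_gt.mean(axis=1)                       # gene

    s_gt = float(m_gt.var(axis=1, ddof=1).mean()) if n_t > 1 else 0.0
    s_ge = float(m_ge.var(axis=1, ddof=1).mean()) if n_e > 1 else 0.0
    s_g = float(m_g.var(ddof=1)) if n_g > 1 else 0.0

    var_gt = max(0.0, s_gt - var_error / (n_e * n_r))
    var_ge = max(0.0, s_ge - var_error / (n_t * n_r))
    var_g = max(0.0, s_g - var_gt / n_t - var_ge / n_e - var_error / (n_e * n_t * n_r))
    return VarianceComponents(var_g, var_gt, var_ge, var_error)
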