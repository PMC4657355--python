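"""Synthetic diploid transcriptome generator with known ground truth.

Emulates the inputs of a multi-tissue allele-specific-expression study on a
single outbred individual with a sequenced sire: a small multi-gene genome,
exonic heterozygous SNPs with phased parental alleles, per-SNP per-tissue
read counts from alignments against both parental genomes, and an exon-level
count table with planted variance components. Every planted quantity (the
maternal expression fraction f of each gene x tissue, mapping-loss bias,
false-heterozygous error SNPs inside runs of homozygosity, same-parent gene
clusters) is recorded in a truth table so downstream calls can be scored.

Counts at a SNP follow a shared-read model: the same D reads are "aligned"
to both parental genomes. A read carrying the maternal allele always
matches in the maternal alignment but mismatches in the paternal alignment,
where it is lost with probability b (and symmetrically for paternal reads).
This makes the halved cross-product chi-square exactly insensitive to the
bias at f = 0.5 while still producing the depth loss real aligners show.

All randomness flows from one seed through independent named substreams, so
generating one stage never perturbs another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticBundle",
    "simulate_reference",
    "simulate_variants",
    "simulate_ase_profiles",
    "simulate_allele_counts",
    "simulate_exon_counts",
    "simulate_bundle",
]

ASE_CLASSES = ("balanced", "moderate_ase", "mae", "imprinted", "tissue_divergent")

# substream indices: adding a stage never changes earlier draws
_STREAMS = {
    "reference": 0,
    "variants": 1,
    "profiles": 2,
    "counts": 3,
    "exon_counts": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],)))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``ase_class_mix`` gives the gene-class proportions; ``paternal_share``
    is the fraction of ASE gene x tissue pairs favouring the paternal
    allele (default 0.5417, a mild genome-wide paternal excess).
    ``cluster_runs`` plants same-parent runs of consecutive genes as
    (tissue_index, run_length) pairs. ``bias_loss`` is the probability a
    read carrying the non-matching allele is lost from an alignment.
    ``error_snp_rate`` adds false-heterozygous SNPs (the cow is truly
    homozygous) inside ``roh_segments``, given as (chrom, start, end)
    half-open intervals.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 60
    exons_per_gene: int = 4
    exon_length: int = 300
    intron_length: int = 200
    n_tissues: int = 18
    snps_per_gene_mean: float = 3.0
    depth_mean: float = 60.0
    depth_dispersion: float = 8.0
    depth_gene_sigma: float = 0.4
    ase_class_mix: dict = field(
        default_factory=lambda: {
            "balanced": 0.35,
            "moderate_ase": 0.30,
            "mae": 0.10,
            "imprinted": 0.05,
            "tissue_divergent": 0.20,
        }
    )
    paternal_share: float = 0.5417
    cluster_runs: tuple = ()
    sire_het_fraction: float = 0.5
    bias_loss: float = 0.1
    error_snp_rate: float = 0.0
    error_contamination: float = 0.005
    roh_segments: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if sorted(self.ase_class_mix) != sorted(ASE_CLASSES):
            raise ValueError(f"ase_class_mix must cover exactly {ASE_CLASSES}")
        probs = np.array([self.ase_class_mix[c] for c in ASE_CLASSES], dtype=float)
        if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("ase_class_mix entries must be in [0,1] and sum to 1")
        for name in ("paternal_share", "sire_het_fraction", "error_snp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.bias_loss < 1.0:
            raise ValueError("bias_loss must be in [0,1)")
        if self.snps_per_gene_mean > self.exons_per_gene * self.exon_length:
            raise ValueError(
                f"snps_per_gene_mean {self.snps_per_gene_mean} exceeds the "
                f"{self.exons_per_gene * self.exon_length} exonic bases per gene"
            )
        if self.gene_span > self.chrom_length:
            raise ValueError(
                f"gene span {self.gene_span} exceeds chromosome length {self.chrom_length}"
            )

    @property
    def gene_span(self) -> int:
        return self.exons_per_gene * self.exon_length + (self.exons_per_gene - 1) * self.intron_length

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_runs"] = [list(x) for x in self.cluster_runs]
        d["roh_segments"] = [list(x) for x in self.roh_segments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["cluster_runs"] = tuple(tuple(x) for x in d.get("cluster_runs", ()))
        d["roh_segments"] = tuple(
            (str(c), int(s), int(e)) for c, s, e in d.get("roh_segments", ())
        )
        return cls(**d)


@dataclass
class SyntheticBundle:
    """All generated inputs plus the truth they were generated from."""

    config: SimulationConfig
    genome: dict
    genes: pd.DataFrame
    exons: pd.DataFrame
    variants: pd.DataFrame
    truth: pd.DataFrame
    counts: pd.DataFrame
    exon_counts: pd.DataFrame | None = None


def simulate_reference(config: SimulationConfig):
    """Random genome with an evenly spaced, non-overlapping gene grid.

    Genes are laid out round-robin over chromosomes; each has
    ``exons_per_gene`` ordered, disjoint exons. Coordinates are 1-based
    inclusive. Raises when the requested genes cannot fit.
    """
    config.validate()
    rng = _rng(config.seed, "reference")
    genome = {
        f"chr{c + 1}": "".join(rng.choice(list("ACGT"), size=config.chrom_length))
        for c in range(config.n_chromosomes)
    }

    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    gene_rows, exon_rows = [], []
    gid = 0
    for c, n_here in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        if n_here == 0:
            continue
        spacing = config.chrom_length // n_here
        if spacing < config.gene_span + 2:
            raise ValueError(
                f"{n_here} genes of span {config.gene_span} cannot fit on a "
                f"{config.chrom_length} bp chromosome"
            )
        for i in range(n_here):
            start = i * spacing + 1
            gene_id = f"gene{gid:04d}"
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": start,
                    "end": start + config.gene_span - 1,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            for e in range(config.exons_per_gene):
                ex_start = start + e * (config.exon_length + config.intron_length)
                exon_rows.append(
                    {
                        "gene_id": gene_id,
                        "exon_id": f"{gene_id}.e{e + 1}",
                        "exon_index": e + 1,
                        "chrom": chrom,
                        "start": ex_start,
                        "end": ex_start + config.exon_length - 1,
                    }
                )
            gid += 1
    return genome, pd.DataFrame(gene_rows), pd.DataFrame(exon_rows)


def _in_roh(chrom: str, pos: int, segments) -> bool:
    return any(c == chrom and s <= pos - 1 < e for c, s, e in segments)


def simulate_variants(genome, exons: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Exonic heterozygous SNPs with phased parental alleles.

    True heterozygous SNPs avoid the planted RoH segments so those stay
    zero-het; false-heterozygous error SNPs (cow truly homozygous for the
    reference base) are planted only inside them, at a count of
    ``error_snp_rate`` times the true SNP count. A fraction
    ``sire_het_fraction`` of sites gets a heterozygous sire, leaving the
    parental origin ambiguous; the rest have the sire homozygous for the
    paternal allele.
    """
    rng = _rng(config.seed, "variants")
    bases = np.array(list("ACGT"))
    rows = []
    snp_idx = 0

    def _mk_variant(chrom, pos, gene_id, exon_id, is_error):
        nonlocal snp_idx
        ref = genome[chrom][pos - 1]
        alt = str(rng.choice(bases[bases != ref]))
        # phase assignment is arbitrary; error SNPs are truly homozygous ref,
        # the "het" call and its phase are the artefact being planted
        mat_is_ref = bool(rng.random() < 0.5)
        maternal, paternal = (ref, alt) if mat_is_ref else (alt, ref)
        sire_het = bool(rng.random() < config.sire_het_fraction)
        if sire_het:
            sire_gt = (ref, alt)
            origin = "ambiguous"
        else:
            sire_gt = (paternal, paternal)
            origin = "definitive"
        rows.append(
            {
                "snp_id": f"snp{snp_idx:05d}",
                "chrom": chrom,
                "pos": int(pos),
                "ref_allele": ref,
                "alt_allele": alt,
                "maternal_allele": maternal,
                "paternal_allele": paternal,
                "origin_status": origin,
                "sire_allele1": sire_gt[0],
                "sire_allele2": sire_gt[1],
                "gene_id": gene_id,
                "exon_id": exon_id,
                "is_error": is_error,
                "private_detected": True,
                "pop_het": not is_error,
            }
        )
        snp_idx += 1

    # true het SNPs, per gene, outside RoH
    for gene_id, g_ex in exons.groupby("gene_id", sort=True):
        chrom = g_ex["chrom"].iloc[0]
        positions, exon_ids = [], []
        for ex in g_ex.itertuples():
            for p in range(ex.start, ex.end + 1):
                if not _in_roh(chrom, p, config.roh_segments):
                    positions.append(p)
                    exon_ids.append(ex.exon_id)
        if not positions:
            continue
        n_snps = 1 + rng.poisson(max(config.snps_per_gene_mean - 1.0, 0.0))
        # genes truncated by an RoH segment offer fewer eligible bases
        n_snps = min(n_snps, len(positions))
        pick = np.sort(rng.choice(len(positions), size=n_snps, replace=False))
        for i in pick:
            _mk_variant(chrom, positions[i], gene_id, exon_ids[i], is_error=False)

    n_true = snp_idx
    n_err = int(round(config.error_snp_rate * n_true))
    if n_err > 0:
        # exonic bases inside RoH segments
        err_pool = []
        for ex in exons.itertuples():
            for p in range(ex.start, ex.end + 1):
                if _in_roh(ex.chrom, p, config.roh_segments):
                    err_pool.append((ex.chrom, p, ex.gene_id, ex.exon_id))
        if not err_pool:
            raise ValueError("error_snp_rate > 0 requires roh_segments overlapping exons")
        pick = rng.choice(len(err_pool), size=min(n_err, len(err_pool)), replace=False)
        for i in np.sort(pick):
            chrom, p, gene_id, exon_id = err_pool[i]
            _mk_variant(chrom, p, gene_id, exon_id, is_error=True)

    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def simulate_ase_profiles(genes: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Assign every gene x tissue an ASE class and a maternal fraction f.

    Classes: ``balanced`` (f = 0.5), ``moderate_ase`` (major allele at
    0.6-0.85), ``mae`` (>= 0.9), ``imprinted`` (near-complete silencing of
    one parent in every tissue), ``tissue_divergent`` (at least one tissue
    favouring each parent). Among ASE pairs the favoured parent is paternal
    with probability ``paternal_share``. Planted cluster runs override the
    affected gene x tissue cells with consecutive same-parent ASE.
    """
    config.validate()
    rng = _rng(config.seed, "profiles")
    genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    n_genes = len(genes)
    tissues = [f"tissue{t + 1:02d}" for t in range(config.n_tissues)]
    probs = [config.ase_class_mix[c] for c in ASE_CLASSES]
    gene_class = rng.choice(ASE_CLASSES, size=n_genes, p=probs)

    f = np.full((n_genes, config.n_tissues), 0.5)
    cls = np.empty((n_genes, config.n_tissues), dtype=object)
    for gi in range(n_genes):
        c = gene_class[gi]
        cls[gi, :] = c
        if c == "balanced":
            continue
        if c == "moderate_ase":
            maj = rng.uniform(0.6, 0.85, size=config.n_tissues)
            pat = rng.random(config.n_tissues) < config.paternal_share
            f[gi, :] = np.where(pat, 1.0 - maj, maj)
        elif c == "mae":
            maj = rng.uniform(0.9, 1.0, size=config.n_tissues)
            pat = rng.random(config.n_tissues) < config.paternal_share
            f[gi, :] = np.where(pat, 1.0 - maj, maj)
        elif c == "imprinted":
            maj = rng.uniform(0.95, 1.0, size=config.n_tissues)
            pat = rng.random() < config.paternal_share
            f[gi, :] = 1.0 - maj if pat else maj
        elif c == "tissue_divergent":
            maj = rng.uniform(0.6, 0.95, size=config.n_tissues)
            pat = rng.random(config.n_tissues) < 0.5
            # force at least one tissue on each side
            if pat.all():
                pat[rng.integers(config.n_tissues)] = False
            elif not pat.any():
                pat[rng.integers(config.n_tissues)] = True
            f[gi, :] = np.where(pat, 1.0 - maj, maj)

    # planted same-parent runs of consecutive genes within one tissue
    cluster_id = np.full((n_genes, config.n_tissues), "", dtype=object)
    genes_by_chrom = {c: g.index.to_numpy() for c, g in genes.groupby("chrom")}
    chrom_cycle = sorted(genes_by_chrom)
    occupied: dict[tuple, set] = {}
    for run_idx, (tissue_idx, run_len) in enumerate(config.cluster_runs):
        chrom = chrom_cycle[run_idx % len(chrom_cycle)]
        idx_here = genes_by_chrom[chrom]
        if run_len > len(idx_here):
            raise ValueError(
                f"cluster run of {run_len} genes exceeds the {len(idx_here)} genes on {chrom}"
            )
        taken = occupied.setdefault((chrom, tissue_idx), set())
        free_starts = [
            s
            for s in range(len(idx_here) - run_len + 1)
            if not any(i in taken for i in range(s, s + run_len))
        ]
        if not free_starts:
            raise ValueError(
                f"cannot place a {run_len}-gene run on {chrom}: no room left between planted runs"
            )
        start = int(rng.choice(free_starts))
        taken.update(range(start, start + run_len))
        members = idx_here[start : start + run_len]
        pat = bool(rng.random() < 0.5)
        maj = rng.uniform(0.75, 0.95, size=run_len)
        f[members, tissue_idx] = 1.0 - maj if pat else maj
        cls[members, tissue_idx] = "cluster"
        cluster_id[members, tissue_idx] = f"run{run_idx}"

    rows = []
    for gi, gene_id in enumerate(genes["gene_id"]):
        for ti, tissue in enumerate(tissues):
            fv = f[gi, ti]
            favoured = "maternal" if fv > 0.5 else ("paternal" if fv < 0.5 else "none")
            rows.append(
                {
                    "gene_id": gene_id,
                    "tissue": tissue,
                    "class": cls[gi, ti],
                    "f": fv,
                    "favoured_parent": favoured,
                    "cluster_id": cluster_id[gi, ti],
                }
            )
    return pd.DataFrame(rows)


def simulate_allele_counts(
    truth: pd.DataFrame,
    variants: pd.DataFrame,
    config: SimulationConfig,
    depth: float | None = None,
) -> pd.DataFrame:
    """Per-SNP, per-tissue counts from both parental alignments.

    For a SNP in a gene with maternal fraction f and depth D, the same D
    reads feed both alignments: n ~ Binomial(D, f) reads carry the maternal
    allele, giving (r_m, a_m) = (n, Binomial(D-n, 1-b)) in the maternal
    alignment and (r_p, a_p) = (D-n, Binomial(n, 1-b)) in the paternal one,
    with b the mismatching-read loss. Error SNPs are truly homozygous: all
    reads carry the reference base apart from a small contamination rate.
    ``depth`` overrides the negative-binomial depth model with a constant.
    """
    rng = _rng(config.seed, "counts")
    tissues = sorted(truth["tissue"].unique())
    f_map = truth.set_index(["gene_id", "tissue"])["f"]
    b = config.bias_loss

    gene_ids = variants["gene_id"].to_numpy()
    uniq_genes = pd.unique(gene_ids)
    size_factor = dict(
        zip(uniq_genes, np.exp(rng.normal(0.0, config.depth_gene_sigma, size=len(uniq_genes))))
    )

    rows = []
    for v in variants.itertuples():
        mat_is_ref = v.maternal_allele == v.ref_allele
        for tissue in tissues:
            mean_depth = (depth if depth is not None else config.depth_mean) * (
                1.0 if depth is not None else size_factor[v.gene_id]
            )
            if depth is not None:
                d = int(depth)
            else:
                p_nb = config.depth_dispersion / (config.depth_dispersion + mean_depth)
                d = int(rng.negative_binomial(config.depth_dispersion, p_nb))
            if v.is_error:
                n_alt = rng.binomial(d, config.error_contamination)
                n_ref = d - n_alt
                n_mat = n_ref if mat_is_ref else n_alt
            else:
                fv = float(f_map.loc[(v.gene_id, tissue)])
                n_mat = rng.binomial(d, fv)
            r_m = n_mat
            a_m = rng.binomial(d - n_mat, 1.0 - b)
            r_p = d - n_mat
            a_p = rng.binomial(n_mat, 1.0 - b)
            rows.append(
                {
                    "snp_id": v.snp_id,
                    "gene_id": v.gene_id,
                    "tissue": tissue,
                    "r_m": int(r_m),
                    "a_m": int(a_m),
                    "r_p": int(r_p),
                    "a_p": int(a_p),
                }
            )
    return pd.DataFrame(rows)


def simulate_exon_counts(
    n_genes: int = 100,
    n_exons: int = 8,
    n_tissues: int = 6,
    n_replicates: int = 3,
    var_gene: float = 0.34,
    var_gene_tissue: float = 0.12,
    var_gene_exon: float = 0.40,
    var_error: float = 0.14,
    mu: float = 4.0,
    tissue_effect_sd: float = 0.3,
    replicate_effect_sd: float = 0.1,
    exon_trend: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced exon-level count table with planted variance components.

    y = mu + tissue + replicate + tissue.replicate + exon_order.tissue
        + gene + gene.tissue + gene.exon + error,

    all random effects independent normal with the given variances, and a
    positive ``exon_trend`` producing larger counts for later exons (3'
    coverage bias); per-tissue trend slopes are jittered around it. Counts
    are round(exp(y) - 1) clipped at 0; the generating ``y`` is kept in the
    table for exact decomposition checks.
    """
    for name, v in (
        ("var_gene", var_gene),
        ("var_gene_tissue", var_gene_tissue),
        ("var_gene_exon", var_gene_exon),
        ("var_error", var_error),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = _rng(seed, "exon_counts")
    tissue_eff = rng.normal(0.0, tissue_effect_sd, size=n_tissues) if tissue_effect_sd else np.zeros(n_tissues)
    rep_eff = rng.normal(0.0, replicate_effect_sd, size=n_replicates) if replicate_effect_sd else np.zeros(n_replicates)
    tr_eff = (
        rng.normal(0.0, replicate_effect_sd / 2.0, size=(n_tissues, n_replicates))
        if replicate_effect_sd
        else np.zeros((n_tissues, n_replicates))
    )
    trend = exon_trend * (1.0 + (rng.normal(0.0, 0.2, size=n_tissues) if exon_trend else np.zeros(n_tissues)))

    g_eff = rng.normal(0.0, np.sqrt(var_gene), size=n_genes)
    gt_eff = rng.normal(0.0, np.sqrt(var_gene_tissue), size=(n_genes, n_tissues))
    ge_eff = rng.normal(0.0, np.sqrt(var_gene_exon), size=(n_genes, n_exons))

    exon_fraction = (np.arange(n_exons) + 1) / n_exons
    # assemble on a (gene, exon, tissue, replicate) grid
    y = np.zeros((n_genes, n_exons, n_tissues, n_replicates))
    y += mu
    y += tissue_eff[None, None, :, None]
    y += rep_eff[None, None, None, :]
    y += tr_eff[None, None, :, :]
    y += (exon_fraction[:, None] * trend[None, :])[None, :, :, None]
    y += g_eff[:, None, None, None]
    y += gt_eff[:, None, :, None]
    y += ge_eff[:, :, None, None]
    y += rng.normal(0.0, np.sqrt(var_error), size=y.shape)

    counts = np.clip(np.round(np.expm1(y)), 0, None).astype(np.int64)
    g, e, t, r = np.meshgrid(
        np.arange(n_genes), np.arange(n_exons), np.arange(n_tissues), np.arange(n_replicates),
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:04d}" for i in g.ravel()],
            "exon_index": e.ravel() + 1,
            "exon_fraction": exon_fraction[e.ravel()],
            "tissue": [f"tissue{i + 1:02d}" for i in t.ravel()],
            "replicate": r.ravel() + 1,
            "y": y.ravel(),
            "count": counts.ravel(),
        }
    )


def simulate_bundle(config: SimulationConfig, with_exon_counts: bool = False) -> SyntheticBundle:
    """Generate the complete synthetic input set with its truth table."""
    genome, genes, exons = simulate_reference(config)
    variants = simulate_variants(genome, exons, config)
    truth = simulate_ase_profiles(genes, config)
    counts = simulate_allele_counts(truth, variants, config)
    exon_counts = None
    if with_exon_counts:
        exon_counts = simulate_exon_counts(
            n_genes=min(config.n_genes, 100),
            n_tissues=min(config.n_tissues, 6),
            seed=config.seed,
        )
    return SyntheticBundle(config, genome, genes, exons, variants, truth, counts, exon_counts)
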