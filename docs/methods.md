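# Methods

## The ASE test on dual parental alignments

The same RNA-seq reads are aligned once to a maternal and once to a
paternal genome; at each phased exonic SNP the 2x2 table (rows = alignment,
columns = matching/mismatching the aligned-to genome's allele) is summarised
by half the Pearson chi-square,

    chi2_half = ((r_m*a_p - a_m*r_p)^2 * N / (r*a*m*p)) / 2 .

Halving accounts for N being the sum over both alignments of the same
reads. Two algebraic identities pin the statistic's behaviour and are
asserted in the test suite:

* With no allele-specific loss, `r_m = a_p = R` and `a_m = r_p = A`, and
  chi2_half collapses to the 50:50 goodness-of-fit statistic
  `(R - A)^2 / (R + A)`.
* A symmetric multiplicative loss applied to the mismatching cell of each
  alignment scales `a_m` and `a_p` by the same factor, so the cross-product
  `r_m*a_p - a_m*r_p` at balanced expression stays exactly zero: residual
  mapping bias alone can never trigger the test.

One naming ambiguity had to be resolved: the four counts are read as
"matching the aligned-to parental genome's own allele", not "matching the
global reference allele". Under the global-reference reading the
cross-product is identically near zero for any expression imbalance and
the test would detect nothing; under the adopted reading it reduces to the
goodness-of-fit form above. Both count layouts live in the data model, so
the literal variant can still be tabulated for comparison.

p-values use the chi-square distribution with 1 df on the halved
statistic. Calls are threshold-based on the raw p-value (alpha = 0.01, no
multiplicity correction — configurable). At per-alignment depths around
50 the statistic is a function of a binomial lattice and the test is
conservative: its exact size at the 1 % rule is ~0.0065 at D = 50,
oscillating with depth and approaching 0.01 only for depths of several
hundred. The suite asserts this conservative behaviour; users should read
"significant at p < 0.01" as at most a 1 % false-positive rate, not
exactly 1 %.

The maternal expression fraction is estimated as the average of the two
alignments' views, `(r_m/m + a_p/p)/2`, which partially cancels
allele-specific loss. Significant SNPs with major-allele frequency >= 0.9
(inclusive; configurable) are called mono-allelic (MAE).

## Quality control

False-heterozygous genotypes are the dominant artefact behind spurious MAE
(they present as pure expression of the reference allele). Three pure
per-SNP predicates remove them, so the kept set is order-independent:

* not rediscovered in the individual's private variant detection;
* not heterozygous in any other animal of the reference population
  (both consumed as identifier sets — re-running a population variant
  caller is out of scope);
* inside a run of homozygosity (RoH).

RoH detection steps through each chromosome in 100 kb windows offset by
50 kb (anchored at coordinate 0; the final partial window is still
evaluated). Windows with fewer than 6 heterozygous SNPs are flagged; a
flagged window is deemed homozygous when an immediately adjacent window is
also flagged (a run of >= 2 consecutive flagged windows; requiring both
neighbours is available behind a flag), and deemed windows are merged by
union. Regions are reported as BED (0-based half-open).

Per SNP x tissue, testing additionally requires a read depth of at least
10 in both parental alignments and that the most abundant *allele* (in
allele space, after translating match counts back through the phase) be
identical across the two alignments; ties count as agreement.

For multi-animal validation-style data a mapping-bias metric
`BIAS = sqrt((n_APA * n_BPB) / (n_APB * n_BPA))` is computed from allele x
carrying-genome counts; SNPs are kept when `max(BIAS, 1/BIAS) < 2`. The
symmetric form is the default because the direction of the ratio is
arbitrary under allele relabelling; the literal one-sided `BIAS < 2` rule
is available behind a flag. An undefined BIAS (zero denominator) always
fails.

## Parent of origin, clustering, imprinting

A SNP's alleles are phased through the sire: a sire homozygous for one of
the cow's two alleles pins that allele as paternal; a heterozygous sire
leaves the SNP ambiguous (excluded from parent-of-origin summaries);
a sire homozygous for an allele the cow lacks is Mendelian-inconsistent
and excluded with a logged reason.

Per gene x tissue, significant definitively phased SNPs vote; the gene is
called for a parent when that parent holds >= 0.75 of the votes (inclusive),
otherwise "undecided". Clustering of same-parent genes along the genome is
tested per tissue with the Wald-Wolfowitz runs test on the ordered list of
classified genes (undecided genes are skipped and do not break runs;
chromosomes are concatenated by default, per-chromosome testing behind a
flag). With n1 + n2 = n classified genes and R observed runs,
E[R] = 2 n1 n2 / n + 1 and Var[R] = 2 n1 n2 (2 n1 n2 - n) / (n^2 (n-1));
the one-sided p = Phi(z) (fewer runs = clustering) is primary, using the
normal approximation; tests validate the moments against exhaustive
enumeration for n <= 12.

Imprinting candidates are classified per gene from three booleans — any
significant ASE; whether every ASE tissue exceeds a 90 % major-allele
frequency (strict); and whether ASE covers all tissues in which the gene
was testable (expressed with >= 10 reads over a heterozygous SNP) — into
NotImprinted, Imprinted, PartiallyImprinted, TissueSpecificallyImprinted
or TissueSpecificPartiallyImprinted. "All tissues" means all *testable*
tissues, the stricter and better-defined of the two possible readings.
Imprinting cannot be distinguished from strong cis-eQTL effects in a
single individual; the status labels describe expression patterns only.

Heat-map matrix constructions for cross-tissue comparison: SNP x tissue
paternal-allele frequencies; the signed variant (maternal-major SNPs carry
minus the major frequency); MAE indicators; gene x tissue +0.5/-0.5/0 for
paternal/maternal/other; and membership in same-parent runs of >= 5
consecutive classified genes. Tissue x tissue similarity is the
transpose-product of the complete-case matrix, with a euclidean distance
variant for clustering.

## Expression summaries

RNA-molecule proportions per gene use
`RNA_i = ((Counts_i + 10)/Length_i) / T` with
`T = sum((Counts+10)/Length)`; the +10 pseudocount keeps silent genes at a
small positive share and proportions sum to one exactly.

Tissue-specific expression takes externally computed differential-
expression p-values as input (fitting the DE model itself is out of
scope): a gene is TSE in a tissue when p < 0.01 and its expression is more
than two-fold different from its mean across all other tissues, read
symmetrically (fold > 2 up, fold < 0.5 down).

Exon-level log counts `y = ln(1 + count)` follow

    y = mu + tissue + replicate + tissue.replicate + exon_order.tissue
        + gene + gene.tissue + gene.exon + error

with tissue/replicate terms and a per-tissue linear trend in exon order
(exon index as a fraction of the gene's exon count, capturing 3' coverage
bias) as fixed effects and independent normal random effects. On a
balanced design the variances are estimated by closed-form
method-of-moments: fixed effects are removed by least squares, the
within-cell replicate scatter gives the error variance, and the
between-tissue / between-exon / between-gene scatters of the nested means
give gene.tissue, gene.exon and gene after subtracting the noise each mean
inherits from lower strata (estimates clipped at zero). This was chosen
over REML because it is deterministic, closed-form and directly checkable
against the generative truth; in the balanced case the strata are
orthogonal so the estimator is unbiased. Unbalanced designs raise with a
pointer to mixed-model tooling. The per-tissue exon-order trend is linear
by default (categorical behind a flag).

## The synthetic generator

The generator emulates the inputs of a deeply sequenced trio-phased
individual: a small random genome with an evenly spaced gene grid; exonic
heterozygous SNPs with phased alleles and a sire genotype (heterozygous
for half the sites by default, leaving those origin-ambiguous, matching a
setting where roughly half the tested SNPs can be phased); per-gene
x tissue maternal fractions f drawn by class — balanced (f = 0.5),
moderate ASE (major allele 0.6-0.85), MAE (>= 0.9), imprinted
(near-complete one-parent silencing in every tissue), tissue-divergent (at
least one tissue favouring each parent) — with the favoured parent
paternal with probability 0.5417 (a mild genome-wide paternal excess);
planted same-parent runs of consecutive genes within one tissue; planted
false-heterozygous SNPs confined to configured runs of homozygosity (true
het SNPs avoid them, so the segments are genuinely zero-het); and
negative-binomial per-SNP depths around a per-gene expression level
(mean 60, dispersion 8, gene-level lognormal sigma 0.4 by default — the
depth law is a modelling choice, nothing in the analysis depends on it).

Counts use a shared-read model: the same D reads feed both alignments;
n ~ Binomial(D, f) carry the maternal allele; matching reads always
survive, mismatching reads are lost with probability b (default 0.1) per
alignment. This is the model under which the statistic's bias-insensitivity
identity holds exactly, and it reproduces the depth loss real aligners
show. Error SNPs are truly homozygous reference with a 0.005
cross-contamination rate, so they surface as reference-skewed MAE unless
filtered — the artefact the QC stage exists to remove.

All randomness flows from one seed through independent named substreams,
so generating one stage never perturbs another, and a fixed config
reproduces the written bundle byte for byte.

What the generator does *not* emulate: read-level sequencing (FASTQ),
alignment and its error modes, indels, base-quality error models,
overlapping genes, alternative isoforms, or correlated ASE between
neighbouring SNPs beyond the shared gene-level f. Passing tests therefore
demonstrate correctness of the statistics, filters and classifications
given allele counts — not robustness to upstream alignment artefacts
beyond the multiplicative-loss bias model.

## Problem sizes and numerical choices

The test suite and acceptance script run at these sizes: statistic
identities on a 200 x 200 grid and 10^4 random tables (tolerance 1e-10);
null calibration at D = 50, b = 0.3 with 10^5 replicates; power at f = 0.8,
D = 100 with 10^4 replicates against the noncentral chi-square oracle with
ncp = D(2f-1)^2; RoH recovery on two 1 Mb chromosomes with planted 200-500
kb zero-het segments; runs-test enumeration up to n = 12 and 500
planted-cluster replicates (200 genes, 30 % classified background, six
planted runs of six genes — a configuration chosen by a power calculation
to give ~95 % expected detection); parent-of-origin recovery on 125 genes
x 18 tissues (2250 ASE pairs) at depth 200; variance components at 500
genes x 8 exons x 6 tissues x 3 replicates.

Degenerate inputs are handled explicitly: zero marginals make the
statistic not-evaluable (reason `degenerate_margin`); zero alignment
totals make the maternal fraction undefined; a maternal fraction of
exactly 0.5 leaves the major parent undefined and the SNP out of
parent-of-origin summaries; a zero other-tissue mean leaves the TSE fold
undefined; variance estimates are clipped at zero; an undefined BIAS fails
its filter.
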