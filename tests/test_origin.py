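"""Gene parent-of-origin classes, runs testing and matrix constructions."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ase_atlas.origin import (
    build_matrices,
    classify_gene_parent,
    find_runs,
    paternal_summary,
    run_membership,
    runs_test,
    runs_test_by_tissue,
    snp_concordance,
    tissue_similarity,
)


def _snp_results(rows):
    out = []
    for i, (gene, tissue, parent, sig) in enumerate(rows):
        out.append(
            {
                "snp_id": f"s{i}",
                "gene_id": gene,
                "tissue": tissue,
                "significant": sig,
                "major_parent": parent,
                "origin_status": "definitive",
                "maternal_fraction": 0.8 if parent == "maternal" else 0.2,
                "major_freq": 0.8,
                "mae": False,
            }
        )
    return pd.DataFrame(out)


@pytest.mark.parametrize(
    "parents, expected_class, expected_ratio",
    [
        (["paternal"] * 3 + ["maternal"], "paternal", 0.75),  # boundary inclusive
        (["paternal"] * 2 + ["maternal"] * 2, "undecided", 0.5),
        (["paternal"] * 5, "paternal", 1.0),
    ],
)
def test_classify_gene_parent(parents, expected_class, expected_ratio):
    res = _snp_results([("g", "t", p, True) for p in parents])
    out = classify_gene_parent(res)
    assert out.loc[0, "class"] == expected_class
    assert out.loc[0, "ratio"] == pytest.approx(expected_ratio)
    assert out.loc[0, "n_paternal"] + out.loc[0, "n_maternal"] == out.loc[0, "n_classified"]


def test_classify_excludes_nonsignificant_and_matches_recount():
    rng = np.random.default_rng(2)
    rows = []
    for g in range(20):
        for _ in range(rng.integers(1, 6)):
            rows.append(
                (f"g{g}", "t", rng.choice(["paternal", "maternal"]), bool(rng.random() < 0.7))
            )
    res = _snp_results(rows)
    out = classify_gene_parent(res).set_index("gene_id")
    for g, grp in res[res["significant"]].groupby("gene_id"):
        n_pat = (grp["major_parent"] == "paternal").sum()
        n_mat = (grp["major_parent"] == "maternal").sum()
        assert out.loc[g, "n_paternal"] == n_pat
        assert out.loc[g, "n_maternal"] == n_mat


def test_snp_concordance():
    res = _snp_results(
        [
            ("g1", "t", "paternal", True),
            ("g1", "t", "paternal", True),
            ("g2", "t", "paternal", True),
            ("g2", "t", "maternal", True),
            ("g3", "t", "paternal", True),  # single SNP: not counted
        ]
    )
    out = snp_concordance(res)
    assert out.loc[0, "units_multi_snp"] == 2
    assert out.loc[0, "units_concordant"] == 1
    assert out.loc[0, "prop_concordant"] == pytest.approx(0.5)


def test_runs_test_worked_example():
    res = runs_test(list("PPPMMM"))
    assert res.r_observed == 2
    assert res.expected_runs == pytest.approx(4.0)
    assert res.variance_runs == pytest.approx(1.2)
    assert res.z == pytest.approx(-1.8257, abs=1e-4)
    assert res.p_one_sided < 0.05


def test_runs_test_alternating_sequence():
    res = runs_test(list("PMPMPM"))
    assert res.r_observed == 6
    assert res.z > 0
    assert res.p_one_sided > 0.5


def test_runs_moments_match_exhaustive_enumeration():
    """Enumerate every ordering for n <= 12 and compare the run-count
    distribution's moments to the closed-form expressions."""
    for n1, n2 in [(3, 3), (4, 2), (5, 5), (6, 6), (2, 7)]:
        n = n1 + n2
        run_counts = []
        for ones in itertools.combinations(range(n), n1):
            seq = np.zeros(n, dtype=int)
            seq[list(ones)] = 1
            run_counts.append(len(find_runs(seq.tolist())))
        run_counts = np.array(run_counts)
        expected = 2 * n1 * n2 / n + 1
        variance = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n**2 * (n - 1))
        assert run_counts.mean() == pytest.approx(expected, abs=1e-12)
        assert run_counts.var(ddof=0) == pytest.approx(variance, abs=1e-12)
    # exact tail for the 3+3 worked example: P(R <= 2) = 2/20
    counts = Counter(
        len(find_runs(["P" if i in ones else "M" for i in range(6)]))
        for ones in itertools.combinations(range(6), 3)
    )
    assert counts[2] / 20 == pytest.approx(0.1)


def test_runs_test_one_sided_p_roughly_uniform_under_null():
    rng = np.random.default_rng(8)
    base = ["P"] * 50 + ["M"] * 50
    pvals = []
    for _ in range(2000):
        seq = list(base)
        rng.shuffle(seq)
        pvals.append(runs_test(seq).p_one_sided)
    # normal approximation on a lattice: allow a generous KS tolerance
    d = stats.kstest(pvals, "uniform").statistic
    assert d < 0.08


def test_runs_test_requires_both_classes():
    with pytest.raises(ValueError):
        runs_test(["P", "P", "P"])


def test_runs_test_by_tissue_orders_by_genome_position():
    gene_order = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(6)],
            "chrom": ["chr1"] * 3 + ["chr2"] * 3,
            "start": [100, 200, 300, 100, 200, 300],
        }
    )
    classes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(6)],
            "tissue": ["t"] * 6,
            "class": ["paternal"] * 3 + ["maternal"] * 3,
        }
    )
    out = runs_test_by_tissue(classes, gene_order)
    assert out.loc[0, "r_observed"] == 2  # concatenated PPPMMM
    per_chrom = runs_test_by_tissue(classes, gene_order, per_chromosome=True)
    assert not per_chrom["testable"].any()  # one class per chromosome


def test_paternal_summary_all_paternal():
    res = _snp_results([(f"g{i}", "t", "paternal", True) for i in range(5)])
    classes = classify_gene_parent(res)
    out = paternal_summary(classes).set_index("tissue")
    assert out.loc["t", "pct_paternal"] == pytest.approx(100.0)


def test_paternal_summary_mae_exclusion():
    # non-MAE genes balanced between parents; MAE genes all paternal
    rows = []
    for i in range(10):
        rows.append((f"gm{i}", "t", "paternal" if i % 2 else "maternal", True))
    res = _snp_results(rows)
    mae_rows = _snp_results([(f"ge{i}", "t", "paternal", True) for i in range(10)])
    mae_rows["major_freq"] = 1.0
    all_rows = pd.concat([res, mae_rows], ignore_index=True)
    all_rows["snp_id"] = [f"s{i}" for i in range(len(all_rows))]
    classes = classify_gene_parent(all_rows)
    full = paternal_summary(classes, all_rows).set_index("tissue")
    reduced = paternal_summary(classes, all_rows, exclude_extreme=True).set_index("tissue")
    assert full.loc["t", "pct_paternal"] == pytest.approx(75.0)
    assert reduced.loc["t", "pct_paternal"] == pytest.approx(50.0)


def test_build_matrices_kinds():
    res = _snp_results(
        [
            ("g1", "t1", "maternal", True),
            ("g1", "t2", "paternal", True),
            ("g2", "t1", "paternal", True),
        ]
    )
    res["mae"] = [True, False, False]
    classes = classify_gene_parent(res)
    gene_order = pd.DataFrame(
        {"gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"], "start": [1, 2]}
    )

    freq = build_matrices(results=res, kind="snp_freq")
    assert freq.loc["s0", "t1"] == pytest.approx(0.2)  # maternal-major SNP
    assert freq.loc["s2", "t1"] == pytest.approx(0.8)

    signed = build_matrices(results=res, kind="snp_signed")
    assert signed.loc["s0", "t1"] == pytest.approx(-0.8)
    assert signed.loc["s2", "t1"] == pytest.approx(0.8)

    mae = build_matrices(results=res, kind="mae_binary")
    assert mae.loc["s0", "t1"] == 1.0

    gs = build_matrices(results=res, classes=classes, kind="gene_signed")
    assert gs.loc["g1", "t1"] == -0.5
    assert gs.loc["g1", "t2"] == 0.5
    assert gs.loc["g2", "t2"] == 0.0  # untested cell

    with pytest.raises(ValueError):
        build_matrices(results=res, kind="nope")


def test_run_membership_marks_planted_run():
    genes = [f"g{i}" for i in range(10)]
    gene_order = pd.DataFrame({"gene_id": genes, "chrom": "chr1", "start": range(10)})
    cls = ["paternal"] * 6 + ["maternal"] * 4
    classes = pd.DataFrame({"gene_id": genes, "tissue": "t", "class": cls})
    mat = build_matrices(classes=classes, gene_order=gene_order, kind="run_membership", run_min=5)
    assert mat.loc[[f"g{i}" for i in range(6)], "t"].eq(1.0).all()
    assert mat.loc[[f"g{i}" for i in range(6, 10)], "t"].eq(0.0).all()


def test_tissue_similarity_identical_and_orthogonal_columns():
    mat = pd.DataFrame(
        {"t1": [1.0, 0.0, 1.0], "t2": [1.0, 0.0, 1.0], "t3": [0.0, 1.0, 0.0]},
        index=["s1", "s2", "s3"],
    )
    sim, dist = tissue_similarity(mat)
    assert sim.loc["t1", "t2"] == pytest.approx(sim.loc["t1", "t1"])
    assert dist.loc["t1", "t2"] == pytest.approx(0.0)
    assert sim.loc["t1", "t3"] == pytest.approx(0.0)
    assert dist.loc["t1", "t3"] > 0


def test_tissue_similarity_recovers_block_structure():
    rng = np.random.default_rng(4)
    base_a = rng.random(40)
    base_b = rng.random(40)
    cols = {}
    for i in range(3):
        cols[f"a{i}"] = base_a + rng.normal(0, 0.05, 40)
    for i in range(3):
        cols[f"b{i}"] = base_b + rng.normal(0, 0.05, 40)
    sim, dist = tissue_similarity(pd.DataFrame(cols))
    within = np.mean([dist.loc[f"a{i}", f"a{j}"] for i in range(3) for j in range(3) if i != j])
    between = np.mean([dist.loc[f"a{i}", f"b{j}"] for i in range(3) for j in range(3)])
    assert within < between
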