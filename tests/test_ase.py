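"""The halved chi-square ASE statistic, its calls and gene summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ase_atlas.ase import (
    ase_test,
    chi_square_ase,
    classify_imprinting,
    classify_mae,
    imprinting_status,
    maternal_fraction,
    summarize_gene_level,
)


@pytest.mark.parametrize(
    "cells, expected",
    [
        ((25, 25, 25, 25), 0.0),  # perfectly balanced
        ((80, 20, 20, 80), 36.0),  # strong imbalance; equals (80-20)^2/100
        ((50, 25, 50, 25), 0.0),  # f=0.5 with 50% mismatch loss: bias alone is invisible
    ],
)
def test_chi_square_worked_examples(cells, expected):
    assert chi_square_ase(*cells) == pytest.approx(expected, abs=1e-12)


def test_chi_square_reduces_to_goodness_of_fit():
    """Without mapping loss the table is (R, A; A, R) and the halved
    statistic collapses to the 50:50 goodness-of-fit chi-square."""
    R, A = np.meshgrid(np.arange(1, 101), np.arange(1, 101))
    got = chi_square_ase(R, A, A, R)
    want = (R - A) ** 2 / (R + A)
    np.testing.assert_allclose(got, want, atol=1e-10, rtol=0)


def test_chi_square_matches_pearson_oracle():
    """Twice the halved statistic equals the Pearson 2x2 chi-square
    computed from observed and expected cells."""
    rng = np.random.default_rng(42)
    tables = rng.integers(1, 500, size=(2000, 4))
    got = 2.0 * chi_square_ase(*tables.T)
    for t, g in zip(tables, got):
        obs = t.reshape(2, 2)
        pearson = stats.chi2_contingency(obs, correction=False)[0]
        assert g == pytest.approx(pearson, abs=1e-10)


def test_chi_square_degenerate_margins_are_nan():
    assert np.isnan(chi_square_ase(10, 0, 10, 0))  # a == 0
    assert np.isnan(chi_square_ase(0, 10, 0, 10))  # r == 0
    assert np.isnan(chi_square_ase(0, 0, 10, 10))  # m == 0


def test_chi_square_rejects_negative_counts():
    with pytest.raises(ValueError):
        chi_square_ase(-1, 2, 3, 4)


def test_chi_square_monotone_in_imbalance():
    """On expected counts with no loss, the statistic grows with |f-0.5|."""
    D = 100
    fs = np.linspace(0.5, 0.99, 25)
    vals = [chi_square_ase(D * f, D * (1 - f), D * (1 - f), D * f) for f in fs]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


def test_bias_insensitive_at_half_on_expected_counts():
    D = 200
    for b in np.linspace(0, 0.9, 10):
        cells = (D * 0.5, D * 0.5 * (1 - b), D * 0.5, D * 0.5 * (1 - b))
        assert chi_square_ase(*cells) == pytest.approx(0.0, abs=1e-12)


@given(
    r=st.integers(min_value=1, max_value=1000),
    a=st.integers(min_value=1, max_value=1000),
    scale=st.floats(min_value=0.05, max_value=1.0),
)
@settings(deadline=None, max_examples=200)
def test_symmetric_loss_preserves_goodness_of_fit_form(r, a, scale):
    """Scaling both mismatch cells by a common survival factor never creates
    imbalance out of nothing: the statistic stays zero iff r == a."""
    stat = chi_square_ase(r, a * scale, a, r * scale)
    if r == a:
        assert stat == pytest.approx(0.0, abs=1e-9)
    else:
        assert stat > 0


@pytest.mark.parametrize(
    "cells, expected",
    [
        ((80, 20, 20, 80), 0.8),
        ((50, 50, 50, 50), 0.5),
        ((80, 10, 20, 40), (80 / 90 + 40 / 60) / 2),  # averaging partially cancels loss
    ],
)
def test_maternal_fraction_examples(cells, expected):
    assert maternal_fraction(*cells) == pytest.approx(expected, abs=1e-12)


def test_ase_test_pvalues_and_boundary():
    df = pd.DataFrame(
        {
            "snp_id": ["a", "b"],
            "tissue": ["t", "t"],
            "r_m": [25, 80],
            "a_m": [25, 20],
            "r_p": [25, 20],
            "a_p": [25, 80],
        }
    )
    res = ase_test(df)
    assert res.loc[0, "p_value"] == pytest.approx(1.0)
    assert not res.loc[0, "significant"]
    assert res.loc[1, "chi2_half"] == pytest.approx(36.0)
    assert res.loc[1, "p_value"] < 1e-8
    assert res.loc[1, "significant"]

    # significance is strict p < alpha around the chi-square 0.01 quantile
    crit = stats.chi2.isf(0.01, 1)
    assert stats.chi2.sf(crit, 1) == pytest.approx(0.01)
    below, above = crit - 1e-3, crit + 1e-3
    assert stats.chi2.sf(below, 1) >= 0.01  # would not be called
    assert stats.chi2.sf(above, 1) < 0.01


def test_null_rejection_rate_is_conservative_at_moderate_depth():
    """At depth 50 the discrete statistic rejects below the nominal 1 %
    (exact size ~0.0065); mismatch loss does not inflate it."""
    rng = np.random.default_rng(3)
    D, n_rep = 50, 50_000
    for b in (0.0, 0.3):
        n = rng.binomial(D, 0.5, n_rep)
        a_m = rng.binomial(D - n, 1 - b)
        a_p = rng.binomial(n, 1 - b)
        chi = chi_square_ase(n, a_m, D - n, a_p)
        rej = np.mean(stats.chi2.sf(chi, 1) < 0.01)
        assert 0.003 < rej < 0.012


@pytest.mark.parametrize(
    "significant, freq, expected",
    [
        (True, 0.90, True),  # boundary inclusive
        (True, 0.89, False),
        (False, 0.95, False),  # gated on significance
        (True, 1.0, True),
    ],
)
def test_classify_mae(significant, freq, expected):
    assert classify_mae(significant, freq) is expected


def test_summarize_gene_level_tissue_specificity():
    rows = []
    # g1: tested in 3 tissues, significant in 1 -> tissue-specific ASE
    for t, sig in (("t1", True), ("t2", False), ("t3", False)):
        rows.append({"snp_id": "s1", "tissue": t, "gene_id": "g1", "significant": sig, "mae": False})
    # g2: significant wherever tested -> not tissue-specific
    for t in ("t1", "t2"):
        rows.append({"snp_id": "s2", "tissue": t, "gene_id": "g2", "significant": True, "mae": t == "t1"})
    # g3: two SNPs in t1, both significant
    rows.append({"snp_id": "s3", "tissue": "t1", "gene_id": "g3", "significant": True, "mae": False})
    rows.append({"snp_id": "s4", "tissue": "t1", "gene_id": "g3", "significant": True, "mae": False})
    res = pd.DataFrame(rows)
    summary = summarize_gene_level(res).set_index("tissue")

    t1 = summary.loc["t1"]
    assert t1["snps_tested"] == 4
    assert t1["ase_snps"] == 4
    assert t1["genes_tested"] == 3
    assert t1["genes_multi_snp"] == 1  # g3
    assert t1["genes_multi_ase"] == 1
    assert t1["genes_mae"] == 1  # g2
    assert t1["genes_ts_ase"] == 1  # g1 only; g3 tested in one tissue only

    total = summary.loc["Total"]
    assert total["snps_tested"] == 4
    assert total["genes_tested"] == 3
    assert total["genes_ase"] == 3
    assert total["genes_ts_ase"] == 1


def test_imprinting_truth_table_exhaustive():
    want = {
        (False, False, False): "NotImprinted",
        (False, False, True): "NotImprinted",
        (False, True, False): "NotImprinted",
        (False, True, True): "NotImprinted",
        (True, True, True): "Imprinted",
        (True, False, True): "PartiallyImprinted",
        (True, True, False): "TissueSpecificallyImprinted",
        (True, False, False): "TissueSpecificPartiallyImprinted",
    }
    for combo in itertools.product([False, True], repeat=3):
        assert imprinting_status(*combo) == want[combo]


def _gene_rows(gene, pattern, depth=50):
    """pattern: list of (tissue, significant, major_freq)."""
    rows = []
    for t, sig, maf in pattern:
        rows.append(
            {
                "snp_id": f"{gene}-{t}",
                "gene_id": gene,
                "tissue": t,
                "significant": sig,
                "major_freq": maf,
                "r_m": depth,
                "a_m": depth,
                "r_p": depth,
                "a_p": depth,
            }
        )
    return rows


def test_classify_imprinting_statuses():
    rows = (
        _gene_rows("gI", [("t1", True, 0.99), ("t2", True, 0.97)])
        + _gene_rows("gPI", [("t1", True, 0.7), ("t2", True, 0.75)])
        + _gene_rows("gTSI", [("t1", True, 0.99), ("t2", False, 0.55)])
        + _gene_rows("gTSPI", [("t1", True, 0.7), ("t2", False, 0.5)])
        + _gene_rows("gNI", [("t1", False, 0.95), ("t2", False, 0.6)])
    )
    calls = classify_imprinting(pd.DataFrame(rows)).set_index("gene_id")
    assert calls.loc["gI", "status"] == "Imprinted"
    assert calls.loc["gPI", "status"] == "PartiallyImprinted"
    assert calls.loc["gTSI", "status"] == "TissueSpecificallyImprinted"
    assert calls.loc["gTSPI", "status"] == "TissueSpecificPartiallyImprinted"
    assert calls.loc["gNI", "status"] == "NotImprinted"
    assert calls.loc["gTSI", "n_tissues_imprinted"] == 1
    assert calls.loc["gPI", "n_tissues_partial"] == 2


def test_classify_imprinting_expression_gate():
    # below the 10-read expression gate in every tissue -> not testable
    rows = _gene_rows("gLow", [("t1", True, 0.99)], depth=2)
    calls = classify_imprinting(pd.DataFrame(rows), min_reads=10)
    assert calls.empty
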