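"""Binning, the Cochran-Armitage trend test, and hypergeometric tails."""

from __future__ import annotations

from fractions import Fraction
from math import comb, log10

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from tomnet.stratification import (
    bin_by_mirna_count,
    chi_square_trend,
    hypergeom_upper_tail,
    repressor_multiplicity_split,
    test_enrichment,
    trend_of,
)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def test_zero_count_with_repressor_edge_goes_to_repressor_only_group():
    counts = pd.Series({"A": 0, "B": 3, "C": 16})
    summary = bin_by_mirna_count(
        ["A", "B", "C"], counts, pc_genes={"A"}, repressor_only_group={"A"}, max_count=31
    )
    frame = summary.bins.set_index("label")
    assert frame.at["repressor-only", "n_genes"] == 1
    assert frame.at["repressor-only", "n_pc"] == 1
    assert frame.at["1-5", "n_genes"] == 1
    assert frame.at["16-31", "n_genes"] == 1  # count 16 lands in the top bin


def test_binning_partitions_and_matches_histogram():
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(300)]
    counts = pd.Series(rng.integers(0, 32, size=300), index=genes)
    pc = {g for g in genes if rng.random() < 0.3}
    summary = bin_by_mirna_count(genes, counts, pc)
    assert summary.total_genes == 300
    # brute-force recount per bin
    edges = [(0, 0), (1, 5), (6, 10), (11, 15), (16, 31)]
    expect = [sum(1 for g in genes if lo <= counts[g] <= hi) for lo, hi in edges]
    assert list(summary.bins["n_genes"]) == expect
    assert (summary.bins["n_pc"] <= summary.bins["n_genes"]).all()


def test_count_exceeding_mirna_set_size_is_an_error():
    counts = pd.Series({"A": 35})
    with pytest.raises(ValueError, match="exceeding"):
        bin_by_mirna_count(["A"], counts, set(), max_count=31)


def test_equal_size_binning_scheme():
    genes = [f"G{i}" for i in range(100)]
    counts = pd.Series(np.arange(1, 101), index=genes)
    summary = bin_by_mirna_count(genes, counts, set(), scheme="equal_size", n_equal_bins=4)
    assert list(summary.bins["n_genes"]) == [25, 25, 25, 25]


# ---------------------------------------------------------------------------
# trend test
# ---------------------------------------------------------------------------


def test_trend_zero_under_identical_proportions():
    x2, p = chi_square_trend([10, 10, 10], [100, 100, 100])
    assert x2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_trend_matches_score_regression_identity():
    """Closed form equals N * r^2 with r the point-biserial correlation."""
    k = np.array([20, 10, 5])
    n = np.array([40, 40, 40])
    scores = np.array([0.0, 1.0, 2.0])
    x2, _ = chi_square_trend(k, n, scores)
    # expand to per-gene arrays and correlate score with the 0/1 outcome
    s = np.concatenate([np.repeat(sc, int(nn)) for sc, nn in zip(scores, n)])
    y = np.concatenate(
        [np.r_[np.ones(int(kk)), np.zeros(int(nn - kk))] for kk, nn in zip(k, n)]
    )
    r = np.corrcoef(s, y)[0, 1]
    assert x2 == pytest.approx(len(s) * r**2, abs=1e-10)


@settings(max_examples=100, deadline=None)
@given(
    k=st.lists(st.integers(min_value=0, max_value=30), min_size=3, max_size=6),
    a=st.floats(min_value=0.1, max_value=10),
    b=st.floats(min_value=-5, max_value=5),
)
def test_trend_invariant_under_affine_scores(k, a, b):
    n = [40] * len(k)
    scores = np.arange(len(k), dtype=float)
    x2_1, p1 = chi_square_trend(k, n, scores)
    x2_2, p2 = chi_square_trend(k, n, a * scores + b)
    assert x2_1 == pytest.approx(x2_2, abs=1e-9)
    assert p1 == pytest.approx(p2, abs=1e-9)


def test_two_bin_trend_equals_plain_chi_square():
    k = np.array([30, 12])
    n = np.array([50, 60])
    x2, _ = chi_square_trend(k, n)
    table = np.array([[30, 20], [12, 48]])
    expect = chi2_contingency(table, correction=False)[0]
    assert x2 == pytest.approx(expect, abs=1e-10)


def test_trend_requires_two_populated_bins():
    with pytest.raises(ValueError, match="2 non-empty"):
        chi_square_trend([5], [10])
    with pytest.raises(ValueError, match="2 non-empty"):
        chi_square_trend([5, 0], [10, 0])


def test_one_sided_directions():
    k, n = [30, 20, 5], [40, 40, 40]
    _, p_dec = chi_square_trend(k, n, sided="decreasing")
    _, p_inc = chi_square_trend(k, n, sided="increasing")
    assert p_dec < 0.01
    assert p_inc > 0.99


# ---------------------------------------------------------------------------
# hypergeometric upper tail
# ---------------------------------------------------------------------------


def test_hypergeom_exact_small_case():
    # all 5 draws in the 5-member category among 10: 1 / C(10,5)
    assert 10 ** hypergeom_upper_tail(10, 5, 5, 5) == pytest.approx(1 / 252)


def test_hypergeom_full_support_is_one():
    assert hypergeom_upper_tail(8, 5, 4, 1) == 0.0  # k at the lower bound


def test_hypergeom_support_violations():
    with pytest.raises(ValueError):
        hypergeom_upper_tail(10, 5, 5, 6)
    with pytest.raises(ValueError):
        hypergeom_upper_tail(10, 11, 5, 2)
    with pytest.raises(ValueError):
        hypergeom_upper_tail(10, 5, 5, -1)


def test_hypergeom_matches_integer_arithmetic_spot_checks():
    rng = np.random.default_rng(5)
    for _ in range(200):
        N = int(rng.integers(2, 200))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        lo, hi = max(0, n + K - N), min(n, K)
        k = int(rng.integers(lo, hi + 1))
        exact = Fraction(
            sum(comb(K, j) * comb(N - K, n - j) for j in range(k, hi + 1)), comb(N, n)
        )
        got = hypergeom_upper_tail(N, K, n, k)
        expect = log10(exact.numerator) - log10(exact.denominator)
        assert got == pytest.approx(expect, rel=1e-9, abs=1e-9)


def test_enrichment_result_wrapper():
    res = test_enrichment(100, 50, 30, 25)
    assert res.p_upper == pytest.approx(10 ** res.log10_p_upper)
    assert res.log10_p_upper < -3


# ---------------------------------------------------------------------------
# repressor-multiplicity split
# ---------------------------------------------------------------------------


def test_multiplicity_split_sizes_by_recount():
    genes = [f"G{i}" for i in range(6)]
    mirna_counts = pd.Series([2, 7, 12, 3, 8, 20], index=genes)
    rep_counts = pd.Series([1, 1, 1, 3, 2, 4], index=genes)
    split = repressor_multiplicity_split(genes, mirna_counts, rep_counts, pc_genes=set())
    assert split["1"].total_genes == 3
    assert split["2-5"].total_genes == 3
    assert "6" not in split  # empty stratum omitted


def test_multiplicity_split_all_single_warns(caplog):
    genes = ["A", "B"]
    mirna_counts = pd.Series([2, 3], index=genes)
    rep_counts = pd.Series([1, 1], index=genes)
    with caplog.at_level("WARNING"):
        split = repressor_multiplicity_split(genes, mirna_counts, rep_counts, set())
    assert list(split) == ["1"]
    assert any("empty" in r.message for r in caplog.records)


def test_multiplicity_split_requires_repressed_genes():
    genes = ["A"]
    with pytest.raises(ValueError, match="repressor count"):
        repressor_multiplicity_split(
            genes, pd.Series([1], index=genes), pd.Series([0], index=genes), set()
        )


def test_percent_pc_bounds_and_totals(pipeline_result):
    for summary in pipeline_result.strata.values():
        pop = summary.populated()
        assert ((pop["percent_pc"] >= 0) & (pop["percent_pc"] <= 100)).all()


def test_multi_repressor_genes_override_more(pipeline_result):
    """Planted additive derepression: multi-repressor strata show a
    percent-PC at least as high as single-repressor strata in every
    miRNA-count bin populated in both."""
    strata = pipeline_result.strata
    single = strata["multiplicity_1"].bins.set_index("label")
    multi = strata["multiplicity_2-5"].bins.set_index("label")
    shared = [
        lbl
        for lbl in single.index
        if lbl in multi.index
        and single.at[lbl, "n_genes"] > 0
        and multi.at[lbl, "n_genes"] > 0
    ]
    assert shared
    for lbl in shared:
        assert multi.at[lbl, "percent_pc"] >= single.at[lbl, "percent_pc"]
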