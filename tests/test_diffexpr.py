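"""Fold-change conventions, present filtering, and the permutation test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomnet.diffexpr import (
    DETable,
    SelectionReport,
    collapse_probesets,
    differential_expression,
    present_filter,
    select_mirnas,
    signed_fold_change,
)
from tomnet.io_formats import GeneList

from tests.helpers import make_matrix


# ---------------------------------------------------------------------------
# signed fold change
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "d, expected",
    [
        (0.0, 1.0),  # no change maps to +1
        (np.log2(25.81), 25.81),  # up 25.81-fold
        (-3.0, -8.0),  # down 8-fold, negative sign
    ],
)
def test_signed_fold_change_values(d, expected):
    assert signed_fold_change(0.0, d) == pytest.approx(expected)


@settings(max_examples=200, deadline=None)
@given(d=st.floats(min_value=-20, max_value=20, allow_nan=False))
def test_signed_fold_change_identities(d):
    """|fc| = 2^|d|, and fc(d)*fc(-d) = -fc(d)^2 for d != 0."""
    fc = signed_fold_change(0.0, d)
    assert abs(fc) == pytest.approx(2.0 ** abs(d))
    if d != 0:
        assert signed_fold_change(0.0, d) * signed_fold_change(0.0, -d) == pytest.approx(
            -(fc**2)
        )


# ---------------------------------------------------------------------------
# present filter
# ---------------------------------------------------------------------------


def test_present_filter_either_group_rule():
    # present in 7/10 normal, 2/10 cancer: passes the strict >60% rule
    pres = np.zeros((2, 20), dtype=bool)
    pres[0, :7] = True
    pres[0, 10:12] = True
    mat = make_matrix(np.full((2, 20), 8.0), 10, 10, present=pres)
    kept, report = present_filter(mat, 0.6, strict=True)
    assert kept.feature_ids == ["G0000"]  # the all-absent feature is dropped
    assert report.stages == {"input": 2, "present": 1}


def test_present_filter_boundary_strictness():
    pres = np.zeros((1, 10), dtype=bool)
    pres[0, :3] = True  # exactly 60% of the 5 normal samples
    mat = make_matrix(np.full((1, 10), 8.0), 5, 5, present=pres)
    strict, _ = present_filter(mat, 0.6, strict=True)
    loose, _ = present_filter(mat, 0.6, strict=False)
    assert strict.feature_ids == []
    assert loose.feature_ids == ["G0000"]


def test_present_filter_bad_fraction():
    mat = make_matrix(np.full((1, 4), 8.0), 2, 2)
    with pytest.raises(ValueError):
        present_filter(mat, 0.0)


def test_present_filter_matches_flag_recount(bundle):
    """Retention equals a brute-force recount of the present flags."""
    from tomnet.io_formats import read_expression_matrix

    groups = dict(
        line.split("\t")
        for line in bundle.paths["mrna_groups"].read_text().splitlines()
    )
    mat = read_expression_matrix(
        bundle.paths["mrna_expression"],
        groups,
        scale="log2",
        present_path=bundle.paths["mrna_present"],
    )
    kept, _ = present_filter(mat, 0.6, strict=True)
    flags = pd.read_csv(bundle.paths["mrna_present"], sep="\t", index_col=0)
    normal = [s for s, g in groups.items() if g == "normal"]
    cancer = [s for s, g in groups.items() if g == "cancer"]
    expect = flags.index[
        (flags[normal].mean(axis=1) > 0.6) | (flags[cancer].mean(axis=1) > 0.6)
    ]
    assert list(kept.feature_ids) == list(expect)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def _planted_matrix(seed=0, n_feat=60, shift_first=3.0, sd=0.3, n=10):
    rng = np.random.default_rng(seed)
    vals = rng.normal(8.0, sd, size=(n_feat, 2 * n))
    vals[0, n:] += shift_first
    return vals


def test_overwhelming_shift_is_called_up():
    mat = make_matrix(_planted_matrix(), 10, 10)
    de = differential_expression(mat, n_permutations=200, seed=1)
    assert de.direction_of("G0000") == "up"
    assert de.frame.at["G0000", "fc"] > 4


def test_label_swap_negates_fc_and_swaps_calls():
    vals = _planted_matrix(seed=5)
    vals[1, 10:] -= 2.5  # plant one down gene too
    a = make_matrix(vals, 10, 10)
    b = make_matrix(vals, 10, 10, swap_groups=True)
    de_a = differential_expression(a, n_permutations=200, seed=9)
    de_b = differential_expression(b, n_permutations=200, seed=9)
    assert np.allclose(de_a.frame["fc"], -de_b.frame["fc"])
    assert np.allclose(de_a.frame["p"], de_b.frame["p"])
    assert set(de_a.up()) == set(de_b.down())
    assert set(de_a.down()) == set(de_b.up())


def test_zero_variance_feature_gets_floored_not_nan():
    vals = _planted_matrix(seed=2)
    vals[3] = 5.0  # exactly constant
    mat = make_matrix(vals, 10, 10)
    de = differential_expression(mat, n_permutations=150, seed=3)
    assert np.isfinite(de.frame.loc["G0003", ["t", "p", "q"]].astype(float)).all()


def test_small_group_and_linear_scale_errors():
    mat = make_matrix(np.full((2, 3), 8.0), 1, 2)
    with pytest.raises(ValueError, match="2 samples"):
        differential_expression(mat, seed=0)
    lin = make_matrix(np.full((2, 6), 8.0), 3, 3, scale="linear")
    with pytest.raises(ValueError, match="log2"):
        differential_expression(lin, seed=0)


def test_detable_invariants_enforced():
    frame = pd.DataFrame(
        {
            "mean_normal": [8.0],
            "mean_cancer": [9.0],
            "fc": [2.0],
            "p": [0.001],
            "q": [0.5],
            "direction": ["up"],  # inconsistent: q above threshold
        },
        index=["G1"],
    )
    with pytest.raises(ValueError, match="ns"):
        DETable(frame, fdr_threshold=0.055)


def test_collapse_probesets_keeps_min_p():
    frame = pd.DataFrame(
        {
            "mean_normal": [8, 8, 8.0],
            "mean_cancer": [9, 10, 7.0],
            "fc": [2.0, 4.0, -2.0],
            "p": [0.01, 0.001, 0.5],
            "q": [0.02, 0.002, 0.6],
            "direction": ["up", "up", "ns"],
        },
        index=["ps1", "ps2", "ps3"],
    )
    de = DETable(frame, 0.055)
    mapped = collapse_probesets(de, pd.Series({"ps1": "GENE1", "ps2": "GENE1", "ps3": "GENE2"}))
    assert list(mapped.frame.index) == ["GENE1", "GENE2"]
    assert mapped.frame.at["GENE1", "p"] == 0.001


# ---------------------------------------------------------------------------
# miRNA selection
# ---------------------------------------------------------------------------


def _de_from(fc_p: dict[str, tuple[float, float]]) -> DETable:
    idx = list(fc_p)
    fc = np.array([fc_p[m][0] for m in idx])
    p = np.array([fc_p[m][1] for m in idx])
    d = np.where(fc > 0, np.log2(np.abs(fc)), -np.log2(np.abs(fc)))
    frame = pd.DataFrame(
        {
            "mean_normal": 8.0,
            "mean_cancer": 8.0 + d,
            "fc": fc,
            "p": p,
            "q": p,  # fine for selection tests
            "direction": np.where(p <= 0.055, np.where(fc > 0, "up", "down"), "ns"),
        },
        index=idx,
    )
    return DETable(frame, fdr_threshold=0.055)


def test_select_mirnas_thresholds_are_strict():
    de = _de_from(
        {
            "hsa-miR-a": (6.0, 0.01),  # fc exactly at the bound: excluded
            "hsa-miR-b": (118.6, 0.000004),  # strong: included
            "hsa-miR-c": (8.0, 0.03),  # p exactly at the bound: excluded
            "hsa-miR-d": (-20.0, 0.001),  # downregulated: excluded
            "mmu-miR-e": (50.0, 0.001),  # not human: excluded
            "hsa-miR-f": (50.0, 0.001),  # not conserved: excluded
        }
    )
    conserved = GeneList(
        ["hsa-miR-a", "hsa-miR-b", "hsa-miR-c", "hsa-miR-d", "mmu-miR-e"]
    )
    selected, report = select_mirnas(de, conserved)
    assert list(selected) == ["hsa-miR-b"]
    assert report.stages["human"] == 5
    assert report.stages["conserved"] == 4
    assert report.stages["selected"] == 1


def test_selection_report_rejects_increasing_counts():
    report = SelectionReport()
    report.record("input", 10)
    with pytest.raises(ValueError):
        report.record("filtered", 11)


def test_selected_mirnas_equal_planted_set(bundle, pipeline_result):
    """Default pipeline recovers exactly the 31 planted upregulated miRNAs."""
    assert set(pipeline_result.selected_mirnas) == set(bundle.selected_mirnas)
    assert len(bundle.selected_mirnas) == 31
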