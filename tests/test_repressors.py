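"""Repressor selection, binding-site pairs, and correlation inference."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomnet.diffexpr import DETable
from tomnet.io_formats import GeneList, RegulonTable, read_gmt
from tomnet.repressors import (
    infer_correlation_regulon,
    pearson_directional_p,
    select_repressors,
    transfac_pairs,
)

from tests.helpers import make_matrix


def _de(directions: dict[str, str]) -> DETable:
    idx = list(directions)
    q = np.array([0.01 if d != "ns" else 0.5 for d in directions.values()])
    fc = np.array(
        [3.0 if d == "up" else (-3.0 if d == "down" else 1.1) for d in directions.values()]
    )
    frame = pd.DataFrame(
        {
            "mean_normal": 8.0,
            "mean_cancer": 8.0 + np.where(fc > 0, np.log2(np.abs(fc)), -np.log2(np.abs(fc))),
            "fc": fc,
            "p": q,
            "q": q,
            "direction": list(directions.values()),
        },
        index=idx,
    )
    return DETable(frame, 0.055)


# ---------------------------------------------------------------------------
# repressor selection
# ---------------------------------------------------------------------------


def test_select_repressors_three_stage_filter():
    go = GeneList(["ZNF24", "UPGENE", "NOTARGET", "ABSENT"])
    de = _de({"ZNF24": "down", "UPGENE": "up", "NOTARGET": "down"})
    sel = select_repressors(go, de, mirna_targets={"ZNF24", "UPGENE"})
    assert sel.candidate_count == 4
    assert sel.downregulated_count == 2  # ZNF24, NOTARGET
    assert sel.mirna_targeted_count == 1
    assert list(sel.genes) == ["ZNF24"]


def test_select_repressors_matches_planted_list(bundle, pipeline_result):
    sel = pipeline_result.repressor_selection
    assert set(sel.genes) == set(bundle.repressors)
    assert sel.candidate_count == len(bundle.go_candidates)
    assert sel.candidate_count >= sel.downregulated_count >= sel.mirna_targeted_count


# ---------------------------------------------------------------------------
# binding-site pairs
# ---------------------------------------------------------------------------


def test_transfac_pair_retention_rules():
    regulons = RegulonTable({"ZNF24": {"VEGFA", "NODEG", "NOTARGET"}})
    de = _de({"ZNF24": "down", "VEGFA": "up", "NOTARGET": "down"})
    result = transfac_pairs(
        regulons, GeneList(["ZNF24"]), de, mirna_targets={"VEGFA", "ZNF24"}
    )
    assert result.edges.pairs() == {("ZNF24", "VEGFA")}
    assert result.mutual_targets == {"VEGFA"}
    assert result.active_repressors == {"ZNF24"}
    # NOTARGET is a DEG in the regulon but not miRNA-targeted: repressor-only
    assert result.repressor_only == {"NOTARGET"}


def test_transfac_pairs_equal_triple_intersection(bundle, pipeline_result):
    """Edge set equals the brute-force intersection regulon x DEG x target."""
    res = pipeline_result
    regulons = read_gmt(bundle.paths["regulons"])
    degs = set(res.de_mrna.degs())
    targets = res.predictions.genes_of(set(res.selected_mirnas)) & set(
        res.de_mrna.features
    )
    expect = set()
    for rep in res.repressor_selection.genes:
        if rep in regulons:
            for g in regulons[rep]:
                if g != rep and g in degs and g in targets:
                    expect.add((rep, g))
    assert res.transfac.edges.pairs() == expect
    assert res.transfac.mutual_targets == {g for _, g in expect}


def test_transfac_no_repressor_in_regulons_warns_empty():
    regulons = RegulonTable({"OTHERTF": {"VEGFA"}})
    de = _de({"VEGFA": "up"})
    result = transfac_pairs(regulons, GeneList(["ZNF24"]), de, {"VEGFA"})
    assert len(result.edges) == 0


# ---------------------------------------------------------------------------
# directional correlation significance
# ---------------------------------------------------------------------------


def test_directional_p_null_is_half():
    assert pearson_directional_p(0.0, 25) == pytest.approx(0.5)


def test_directional_p_edge_cases():
    assert pearson_directional_p(-1.0, 10) == 0.0
    assert pearson_directional_p(1.0, 10) == 1.0
    with pytest.raises(ValueError, match="n"):
        pearson_directional_p(-0.5, 2)


@settings(max_examples=100, deadline=None)
@given(
    r=st.floats(min_value=-0.99, max_value=-0.01),
    dr=st.floats(min_value=0.005, max_value=0.3),
    n=st.integers(min_value=4, max_value=50),
)
def test_directional_p_monotone_in_r_and_n(r, dr, n):
    """p decreases as the anti-correlation strengthens or n grows."""
    stronger = max(-0.999, r - dr)
    assert pearson_directional_p(stronger, n) < pearson_directional_p(r, n)
    assert pearson_directional_p(r, n + 5) < pearson_directional_p(r, n)


def test_directional_p_matches_sampling_null_simulation():
    """Independent oracle: under the bivariate-normal null, the frequency of
    sample correlations at or below r matches the t-transform tail."""
    rng = np.random.default_rng(1234)
    n, r0, draws = 10, -0.9, 400_000
    x = rng.normal(size=(draws, n))
    y = rng.normal(size=(draws, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    p_mc = (r <= r0).mean()
    p_t = pearson_directional_p(r0, n)
    mc_sd = np.sqrt(p_t * (1 - p_t) / draws)
    assert abs(p_mc - p_t) < 4 * mc_sd


# ---------------------------------------------------------------------------
# correlation-regulon inference
# ---------------------------------------------------------------------------


def _matrix_with_planted_r(r_target: float, n_normal: int = 10):
    """Two genes whose sample correlation across normal samples is exactly
    r_target, plus cancer columns of irrelevant noise."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=n_normal)
    zx = (x - x.mean()) / np.linalg.norm(x - x.mean())
    perp = rng.normal(size=n_normal)
    perp -= perp.mean()
    perp -= (perp @ zx) * zx
    zp = perp / np.linalg.norm(perp)
    y = r_target * zx + np.sqrt(1 - r_target**2) * zp
    vals = np.vstack([zx, y])
    cancer = rng.normal(size=(2, 4))
    full = np.hstack([vals, cancer]) + 8.0
    return make_matrix(full, n_normal, 4, features=["REP", "TARGET"])


def test_correlation_edge_retained_below_threshold():
    mat = _matrix_with_planted_r(-0.85)
    result = infer_correlation_regulon(mat, GeneList(["REP"]), {"TARGET"})
    assert ("REP", "TARGET") in result.edge_pairs()
    assert result.edges["r"].iloc[0] == pytest.approx(-0.85, abs=1e-9)


def test_correlation_threshold_is_strict_at_boundary():
    """A pair whose correlation exactly equals the threshold is excluded."""
    mat = _matrix_with_planted_r(-0.85)
    loose = infer_correlation_regulon(mat, GeneList(["REP"]), {"TARGET"}, r_threshold=-0.5)
    realized = float(loose.edges["r"].iloc[0])
    at_boundary = infer_correlation_regulon(
        mat, GeneList(["REP"]), {"TARGET"}, r_threshold=realized
    )
    assert at_boundary.edge_pairs() == set()
    just_above = infer_correlation_regulon(
        mat, GeneList(["REP"]), {"TARGET"}, r_threshold=np.nextafter(realized, 0)
    )
    assert just_above.edge_pairs() == {("REP", "TARGET")}


def test_correlation_invariant_to_linear_rescaling():
    mat = _matrix_with_planted_r(-0.9)
    scaled = mat.values.copy()
    scaled.loc["TARGET"] = scaled.loc["TARGET"] * 3.7 + 11.0
    mat2 = make_matrix(
        scaled.to_numpy(), 10, 4, features=["REP", "TARGET"]
    )
    a = infer_correlation_regulon(mat, GeneList(["REP"]), {"TARGET"})
    b = infer_correlation_regulon(mat2, GeneList(["REP"]), {"TARGET"})
    assert a.edge_pairs() == b.edge_pairs()
    assert a.edges["r"].iloc[0] == pytest.approx(b.edges["r"].iloc[0])


def test_zero_variance_pair_skipped():
    vals = np.vstack([np.full(14, 8.0), np.r_[np.arange(10) * 0.1, np.zeros(4)] + 8])
    mat = make_matrix(vals, 10, 4, features=["REP", "TARGET"])
    result = infer_correlation_regulon(mat, GeneList(["REP"]), {"TARGET"})
    assert result.skipped_zero_variance == 1
    assert len(result.edges) == 0


def test_edge_p_bounded_by_threshold_p(pipeline_result):
    """Every retained edge is more significant than the threshold pair, by
    monotonicity of the directional p in |r|."""
    edges = pipeline_result.correlation.edges
    assert len(edges) > 0
    bound = pearson_directional_p(-0.8, int(edges["n"].iloc[0]))
    assert (edges["p_directional"] < bound).all()
    assert (edges["r"] < -0.8).all()


def test_non_target_class_complements_edges(pipeline_result):
    res = pipeline_result
    covered = res.correlation.regulons.all_targets()
    assert covered.isdisjoint(res.correlation.non_targets)
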