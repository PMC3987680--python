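"""Repressor selection and repressor → target edge construction.

Candidate transcriptional repressors (from GO negative-regulation-of-
transcription terms, consumed as a flat gene list) are narrowed to those
that are significantly downregulated in cancer *and* predicted targets of
at least one selected upregulated miRNA — the genes whose loss of function
can derepress their regulons.

Two edge layers are built:

* **binding-site (TRANSFAC) edges** — regulon membership from a GMT file,
  filtered to repressor/target pairs that are both DEGs and miRNA targets;
* **co-expression edges** — pairs whose Pearson correlation across the
  *normal* samples is strongly negative (``r < -0.8`` by default),
  operationally classifying the anti-correlated gene as a repressor target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DETable
from .io_formats import (
    NORMAL,
    REL_REPRESSES,
    EdgeSet,
    ExpressionMatrix,
    GeneList,
    RegulonTable,
)

logger = logging.getLogger(__name__)


@dataclass
class RepressorSelection:
    """Three-stage repressor filter report plus the final gene list."""

    candidate_count: int
    downregulated_count: int
    mirna_targeted_count: int
    genes: GeneList

    def __post_init__(self) -> None:
        if not (
            self.candidate_count >= self.downregulated_count >= self.mirna_targeted_count
        ):
            raise ValueError("repressor filter counts must be monotone non-increasing")
        if len(self.genes) != self.mirna_targeted_count:
            raise ValueError("final gene list inconsistent with final count")


def select_repressors(
    go_list: GeneList,
    de: DETable,
    mirna_targets: set[str],
) -> RepressorSelection:
    """GO candidates ∩ downregulated DEGs ∩ predicted miRNA targets."""
    candidates = go_list.as_set()
    down = candidates & set(de.down())
    final = down & set(mirna_targets)
    if not final:
        logger.warning("no repressor candidates survive all three filters")
    ordered = [g for g in go_list if g in final]
    return RepressorSelection(
        candidate_count=len(candidates),
        downregulated_count=len(down),
        mirna_targeted_count=len(final),
        genes=GeneList(ordered),
    )


@dataclass
class TransfacPairs:
    """Binding-site edges surviving the DEG and miRNA-target filters.

    ``repressor_only_edges`` carries the companion layer of regulon genes
    that are DEGs but *not* predicted miRNA targets — the "targets of the
    repressors but of none of the selected miRNAs" comparison group used
    in the degree-stratified analysis.
    """

    edges: EdgeSet
    mutual_targets: set[str]
    active_repressors: set[str]
    repressor_only_edges: EdgeSet
    repressor_only: set[str]
    self_loops_dropped: int = 0


def transfac_pairs(
    regulons: RegulonTable,
    repressors: GeneList,
    de: DETable,
    mirna_targets: set[str],
) -> TransfacPairs:
    """Repressor → partner edges from binding-site regulons.

    Retains an edge R → G when R is a selected repressor with a regulon,
    G is in R's regulon, G is a DEG, and G is a predicted target of at
    least one selected miRNA.  Returns the surviving edge set, the mutual
    target genes (regulated by a retained repressor *and* miRNA-targeted),
    the repressor subset with at least one retained edge, and — separately —
    the regulon DEGs of those active repressors that no selected miRNA
    targets (the repressor-only comparison group).
    """
    degs = set(de.degs())
    rep_with_regulon = [r for r in repressors if r in regulons]
    if not rep_with_regulon:
        logger.warning("no selected repressor appears among the regulon keys")
    edges = EdgeSet()
    self_loops = 0
    for rep in rep_with_regulon:
        for gene in regulons[rep]:
            if gene == rep:
                self_loops += 1
                continue
            if gene in degs and gene in mirna_targets:
                edges.add(rep, REL_REPRESSES, gene)
    mutual = {t for _, _, t in edges.edges}
    active = {s for s, _, _ in edges.edges}
    ro_edges = EdgeSet()
    for rep in sorted(active):
        for gene in regulons[rep]:
            if gene != rep and gene in degs and gene not in mirna_targets:
                ro_edges.add(rep, REL_REPRESSES, gene)
    return TransfacPairs(
        edges=edges,
        mutual_targets=mutual,
        active_repressors=active,
        repressor_only_edges=ro_edges,
        repressor_only={t for _, _, t in ro_edges.edges},
        self_loops_dropped=self_loops,
    )


def pearson_directional_p(r, n):
    """One-sided p-value for *negative* Pearson correlation.

    Under the null of zero correlation, ``t = r * sqrt(n-2) / sqrt(1-r**2)``
    follows a t distribution with ``n-2`` degrees of freedom; the
    directional p is its lower-tail probability (repression predicts
    anti-correlation, so only the negative tail is of interest).  For
    ``r = -0.8, n = 10`` this gives p ≈ 0.0027.  Accepts scalars or arrays;
    ``|r| = 1`` returns an exact 0 (or 1 for ``r = +1``).
    """
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n)
    if np.any(n_arr < 3):
        raise ValueError("n must be >= 3")
    if np.any(np.abs(r_arr) > 1):
        raise ValueError("|r| must be <= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_arr * np.sqrt(n_arr - 2) / np.sqrt(1.0 - r_arr**2)
    p = stats.t.cdf(t, df=np.asarray(n_arr) - 2)
    p = np.where(r_arr == -1.0, 0.0, np.where(r_arr == 1.0, 1.0, p))
    if p.ndim == 0:
        return float(p)
    return p


@dataclass
class CorrelationRegulon:
    """Co-expression-inferred regulon with the per-pair statistics."""

    regulons: RegulonTable
    non_targets: set[str]
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)
    skipped_zero_variance: int = 0

    def edge_pairs(self) -> set[tuple[str, str]]:
        if self.edges.empty:
            return set()
        return set(zip(self.edges["repressor"], self.edges["target"]))


def infer_correlation_regulon(
    mat: ExpressionMatrix,
    repressors: GeneList,
    candidates: set[str],
    r_threshold: float = -0.8,
) -> CorrelationRegulon:
    """Infer repressor → target edges from anti-correlation in normal samples.

    For every (repressor, candidate) pair measured on the matrix, the
    Pearson correlation is computed across the normal-group samples only;
    the pair becomes an edge iff ``r < r_threshold`` (strictly).  Candidates
    with no qualifying repressor form the non-target class.  Zero-variance
    genes are skipped with a logged count.  Candidate genes that are also
    repressors are never paired with themselves.
    """
    if mat.scale != "log2":
        raise ValueError("correlations are computed on log2 values")
    normal_cols = mat.samples_in(NORMAL)
    n = len(normal_cols)
    if n < 3:
        raise ValueError("need at least 3 normal samples for correlation")

    rep_ids = [r for r in repressors if r in mat.values.index]
    cand_ids = sorted(c for c in candidates if c in mat.values.index)
    X = mat.values.loc[rep_ids, normal_cols].to_numpy(dtype=float)
    Y = mat.values.loc[cand_ids, normal_cols].to_numpy(dtype=float)

    def standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = a - a.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        ok = norms > 0
        centered[ok] = centered[ok] / norms[ok, None]
        return centered, ok

    Xs, x_ok = standardize(X)
    Ys, y_ok = standardize(Y)
    skipped = int((~x_ok).sum() + (~y_ok).sum())
    if skipped:
        logger.info("skipped %d zero-variance gene(s) in correlation inference", skipped)

    R = np.clip(Xs @ Ys.T, -1.0, 1.0)  # repressors × candidates
    regulons: dict[str, set[str]] = {}
    rows = []
    for i, rep in enumerate(rep_ids):
        if not x_ok[i]:
            continue
        for j in np.nonzero((R[i] < r_threshold) & y_ok)[0]:
            target = cand_ids[j]
            if target == rep:
                continue
            r = float(R[i, j])
            regulons.setdefault(rep, set()).add(target)
            rows.append((rep, target, r, n, pearson_directional_p(r, n)))
    edges = pd.DataFrame(rows, columns=["repressor", "target", "r", "n", "p_directional"])
    covered = set(edges["target"]) if not edges.empty else set()
    non_targets = {c for c in cand_ids if c not in covered}
    table = RegulonTable(
        regulons=regulons,
        provenance={k: "correlation" for k in regulons},
    )
    return CorrelationRegulon(
        regulons=table,
        non_targets=non_targets,
        edges=edges,
        skipped_zero_variance=skipped,
    )
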