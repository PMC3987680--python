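"""Degree-stratified trend analysis and enrichment statistics.

Target genes are binned by the number of upregulated miRNAs predicted to
target them; within each bin the fraction of positively correlated (PC)
genes is tallied, and a Cochran–Armitage chi-square test for trend (1 df)
asks whether that fraction falls as miRNA pressure rises — the signature
of miRNA repression progressively outweighing repressor-mediated
derepression.  Gene-set overlaps are scored with an upper-tail
hypergeometric probability computed in log space, stable far below the
smallest positive float.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)

#: Default miRNA-count bin edges: [1-5], [6-10], [11-15], [16-max].
DEFAULT_MIRNA_BINS = (1, 6, 11, 16)
#: Default repressor-multiplicity strata: [1], [2-5], [6-max].
DEFAULT_REPRESSOR_BINS = (1, 2, 6)


@dataclass
class StratifiedSummary:
    """Ordered per-bin PC tallies plus the trend statistic.

    ``bins`` columns: ``label``, ``score``, ``n_genes``, ``n_pc``,
    ``percent_pc``; ``x2_trend``/``p_trend`` are filled by
    :func:`chi_square_trend`.
    """

    bins: pd.DataFrame
    x2_trend: float | None = None
    p_trend: float | None = None

    def __post_init__(self) -> None:
        if (self.bins["n_pc"] > self.bins["n_genes"]).any():
            raise ValueError("n_pc cannot exceed n_genes")
        if not self.bins["score"].is_monotonic_increasing:
            raise ValueError("bins must be ordered by score")

    @property
    def total_genes(self) -> int:
        return int(self.bins["n_genes"].sum())

    def populated(self) -> pd.DataFrame:
        return self.bins[self.bins["n_genes"] > 0]

    def to_tsv(self, path) -> None:
        out = self.bins.copy()
        out.attrs = {}
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _bin_labels(edges: tuple[int, ...], max_count: int) -> list[tuple[str, int, int]]:
    """(label, lo, hi) per bin from left edges; last bin runs to max_count."""
    out = []
    for i, lo in enumerate(edges):
        hi = (edges[i + 1] - 1) if i + 1 < len(edges) else max_count
        label = str(lo) if lo == hi else f"{lo}-{hi}"
        out.append((label, lo, hi))
    return out


def bin_by_mirna_count(
    genes: list[str],
    counts: pd.Series,
    pc_genes: set[str],
    bin_edges: tuple[int, ...] = DEFAULT_MIRNA_BINS,
    repressor_only_group: set[str] | None = None,
    max_count: int | None = None,
    scheme: str = "count_edges",
    n_equal_bins: int = 4,
) -> StratifiedSummary:
    """Partition genes into miRNA-count bins and tally PC per bin.

    Genes with count 0 that carry a repressor edge form the leading
    "repressor-only" group (score below every count bin); count-0 genes
    outside that group get their own "0" bin.  ``scheme="count_edges"``
    uses ``bin_edges`` as left edges on the count scale;
    ``scheme="equal_size"`` instead splits the count-positive genes into
    ``n_equal_bins`` quantile groups of near-equal gene numbers.
    Every gene is assigned exactly once.
    """
    if list(bin_edges) != sorted(set(bin_edges)):
        raise ValueError("bin_edges must be strictly increasing")
    counts = counts.reindex(genes).fillna(0).astype(int)
    if (counts < 0).any():
        raise ValueError("negative miRNA counts")
    if max_count is not None and (counts > max_count).any():
        bad = counts.index[counts > max_count][0]
        raise ValueError(
            f"gene {bad!r} has count {counts[bad]} exceeding the selected "
            f"miRNA set size {max_count}"
        )
    repressor_only_group = repressor_only_group or set()

    rows = []
    score = 0
    ro = [g for g in genes if g in repressor_only_group and counts[g] == 0]
    if repressor_only_group:
        rows.append(("repressor-only", score, ro))
        score += 1
    zero = [g for g in genes if counts[g] == 0 and g not in repressor_only_group]
    if zero:
        rows.append(("0", score, zero))
        score += 1

    positive = [g for g in genes if counts[g] > 0]
    top = int(counts.max()) if len(counts) else 0
    label_top = max_count if max_count is not None else max(top, bin_edges[-1])
    if scheme == "count_edges":
        for label, lo, hi in _bin_labels(tuple(bin_edges), max(label_top, top)):
            members = [g for g in positive if lo <= counts[g] <= hi]
            rows.append((label, score, members))
            score += 1
    elif scheme == "equal_size":
        if positive:
            qs = pd.qcut(counts[positive].rank(method="first"), n_equal_bins, labels=False)
            for b in range(n_equal_bins):
                members = [g for g, q in zip(positive, qs) if q == b]
                lo = min(counts[g] for g in members)
                hi = max(counts[g] for g in members)
                label = str(lo) if lo == hi else f"{lo}-{hi}"
                rows.append((label, score, members))
                score += 1
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")

    assigned = sum(len(m) for _, _, m in rows)
    if assigned != len(genes):
        raise AssertionError("binning did not partition the gene list")

    frame = pd.DataFrame(
        [
            {
                "label": label,
                "score": s,
                "n_genes": len(members),
                "n_pc": sum(g in pc_genes for g in members),
            }
            for label, s, members in rows
        ]
    )
    frame["percent_pc"] = np.where(
        frame["n_genes"] > 0, 100.0 * frame["n_pc"] / frame["n_genes"].clip(lower=1), np.nan
    )
    return StratifiedSummary(bins=frame)


def chi_square_trend(
    n_pc,
    n_genes,
    scores=None,
    sided: str = "two",
) -> tuple[float, float]:
    """Cochran–Armitage chi-square test for trend in proportions (1 df).

    ``n_pc[i] / n_genes[i]`` are the per-bin proportions and ``scores`` the
    ordered bin scores (default: bin index).  The statistic equals
    ``N * r**2`` where ``r`` is the point-biserial correlation between bin
    score and the binary outcome.  ``sided="two"`` returns the chi-square
    upper tail; ``sided="decreasing"``/``"increasing"`` return the
    one-sided normal tail in the stated trend direction.
    """
    k = np.asarray(n_pc, dtype=float)
    n = np.asarray(n_genes, dtype=float)
    if (k > n).any() or (k < 0).any() or (n < 0).any():
        raise ValueError("need 0 <= n_pc <= n_genes per bin")
    nz = n > 0
    if nz.sum() < 2:
        raise ValueError("need at least 2 non-empty bins")
    scores = np.arange(len(n), dtype=float) if scores is None else np.asarray(scores, float)
    if len(scores) != len(n):
        raise ValueError("scores must match the number of bins")
    if not (np.diff(scores) > 0).all():
        raise ValueError("scores must be strictly increasing")
    k, n, s = k[nz], n[nz], scores[nz]

    N = n.sum()
    K = k.sum()
    if K == 0 or K == N:
        return 0.0, 1.0
    pbar = K / N
    sbar = (s * n).sum() / N
    num = (s * k).sum() - sbar * K
    den = pbar * (1 - pbar) * ((s - sbar) ** 2 * n).sum()
    if den == 0:
        return 0.0, 1.0
    z = num / np.sqrt(den)
    x2 = float(z * z)
    if sided == "two":
        p = float(stats.chi2.sf(x2, df=1))
    elif sided == "decreasing":
        p = float(stats.norm.cdf(z))
    elif sided == "increasing":
        p = float(stats.norm.sf(z))
    else:
        raise ValueError(f"unknown sided {sided!r}")
    return x2, p


def trend_of(summary: StratifiedSummary, sided: str = "two") -> StratifiedSummary:
    """Attach the trend test to a stratified summary (populated bins only)."""
    pop = summary.populated()
    x2, p = chi_square_trend(pop["n_pc"], pop["n_genes"], pop["score"], sided=sided)
    summary.x2_trend = x2
    summary.p_trend = p
    return summary


@dataclass
class EnrichmentResult:
    """Hypergeometric overlap: population N, categories K and n, overlap k."""

    N: int
    K: int
    n: int
    k: int
    log10_p_upper: float

    @property
    def p_upper(self) -> float:
        return float(10.0**self.log10_p_upper)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """log10 of P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed by log-sum-exp over the log-pmf, so the result is accurate even
    when the probability is far below the smallest positive double
    (e.g. log10 p ≈ -222 for the repressor-target overlap).  ``k`` at the
    lower support bound returns exactly 0.0 (p = 1).
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if not (K <= N and n <= N):
        raise ValueError("need K <= N and n <= N")
    lo = max(0, n + K - N)
    hi = min(n, K)
    if not (lo <= k <= hi):
        raise ValueError(f"k={k} outside support [{lo}, {hi}]")
    if k == lo:
        return 0.0
    ks = np.arange(k, hi + 1, dtype=float)
    log_pmf = (
        gammaln(K + 1)
        - gammaln(ks + 1)
        - gammaln(K - ks + 1)
        + gammaln(N - K + 1)
        - gammaln(n - ks + 1)
        - gammaln(N - K - n + ks + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(logsumexp(log_pmf) / LN10)


def test_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Convenience wrapper returning an :class:`EnrichmentResult`."""
    return EnrichmentResult(N=N, K=K, n=n, k=k, log10_p_upper=hypergeom_upper_tail(N, K, n, k))


# pytest must not collect the wrapper above as a test function
test_enrichment.__test__ = False  # type: ignore[attr-defined]


def repressor_multiplicity_split(
    genes: list[str],
    mirna_counts: pd.Series,
    repressor_counts: pd.Series,
    pc_genes: set[str],
    split_edges: tuple[int, ...] = DEFAULT_REPRESSOR_BINS,
    mirna_bin_edges: tuple[int, ...] = DEFAULT_MIRNA_BINS,
    sided: str = "two",
) -> dict[str, StratifiedSummary]:
    """Stratify the miRNA-count trend by repressor multiplicity.

    Genes (all with >= 1 repressor) are split into strata by how many
    downregulated repressors regulate them (default [1], [2-5], [6-max]);
    each populated stratum gets its own miRNA-count summary and trend test.
    An empty stratum is omitted with a warning.
    """
    rc = repressor_counts.reindex(genes)
    if rc.isna().any() or (rc < 1).any():
        raise ValueError("every gene in scope needs a repressor count >= 1")
    out: dict[str, StratifiedSummary] = {}
    top = int(rc.max())
    for label, lo, hi in _bin_labels(tuple(split_edges), max(top, split_edges[-1])):
        members = [g for g in genes if lo <= rc[g] <= hi]
        if not members:
            logger.warning("repressor stratum %s is empty; omitted", label)
            continue
        summary = bin_by_mirna_count(
            members, mirna_counts, pc_genes, bin_edges=mirna_bin_edges
        )
        pop = summary.populated()
        if len(pop) >= 2:
            summary = trend_of(summary, sided=sided)
        out[label] = summary
    return out


def plot_percent_pc(summary: StratifiedSummary, path, title: str = "") -> None:
    """Optional bar chart of percent-PC per bin (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pop = summary.populated()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(pop["label"], pop["percent_pc"], color="#4878a8")
    for x, (n, pct) in enumerate(zip(pop["n_genes"], pop["percent_pc"])):
        ax.text(x, pct, str(int(n)), ha="center", va="bottom", fontsize=8)
    ax.set_xlabel("upregulated miRNAs per gene")
    ax.set_ylabel("% PC (upregulated) targets")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
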