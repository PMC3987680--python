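"""Present-call filtering, differential expression, and miRNA selection.

The significance machinery is a permutation two-sample t-test with a
variance floor and Benjamini–Hochberg FDR.  It stands in for SAM
(Significance Analysis of Microarrays): the selection semantics —
permutation-based significance plus a direction call at a stated FDR —
are preserved, while every step is fully specified and seedable.

Fold changes are reported as *signed linear* fold changes: a log2
difference ``d = mean_cancer - mean_normal`` maps to ``2**d`` when the
gene is up in cancer and ``-2**(-d)`` when down, so magnitudes are always
``>= 1`` and the sign carries the direction (the microarray-literature
convention, e.g. "fold change -625 to 121").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CANCER, NORMAL, ExpressionMatrix, GeneList

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NS = "ns"


@dataclass
class SelectionReport:
    """Feature counts at each successive filter stage.

    Counts must be monotone non-increasing through stages, and where both
    are recorded ``up + down == significant``.
    """

    stages: dict[str, int] = field(default_factory=dict)

    def record(self, stage: str, count: int) -> None:
        if self.stages:
            last = list(self.stages.values())[-1]
            if count > last and stage not in ("up", "down"):
                raise ValueError(
                    f"stage {stage!r} count {count} exceeds previous stage ({last})"
                )
        self.stages[stage] = int(count)

    def check_partition(self) -> None:
        s = self.stages
        if {"up", "down", "significant"} <= s.keys():
            if s["up"] + s["down"] != s["significant"]:
                raise ValueError("up + down != significant")


@dataclass
class DETable:
    """Per-feature differential-expression results.

    ``frame`` columns: ``mean_normal``, ``mean_cancer`` (log2), ``fc``
    (signed linear fold change), ``t``, ``p`` (permutation p-value), ``q``
    (BH FDR), ``direction`` in {up, down, ns}.  ``direction == ns`` iff
    ``q > fdr_threshold``.
    """

    frame: pd.DataFrame
    fdr_threshold: float

    def __post_init__(self) -> None:
        required = {"mean_normal", "mean_cancer", "fc", "p", "q", "direction"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"DETable missing columns {sorted(missing)}")
        ns_mask = self.frame["direction"] == NS
        if not (ns_mask == (self.frame["q"] > self.fdr_threshold)).all():
            raise ValueError("direction/ns inconsistent with FDR threshold")
        if (self.frame["fc"].abs() < 1 - 1e-12).any():
            raise ValueError("|fc| must be >= 1 by construction")

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, feature: str) -> bool:
        return feature in self.frame.index

    @property
    def features(self) -> pd.Index:
        return self.frame.index

    def direction_of(self, feature: str) -> str:
        return self.frame.at[feature, "direction"]

    def degs(self) -> pd.Index:
        return self.frame.index[self.frame["direction"] != NS]

    def up(self) -> pd.Index:
        return self.frame.index[self.frame["direction"] == UP]

    def down(self) -> pd.Index:
        return self.frame.index[self.frame["direction"] == DOWN]

    def subset(self, features) -> "DETable":
        idx = [f for f in features if f in self.frame.index]
        return DETable(self.frame.loc[idx], self.fdr_threshold)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", float_format="%.6g", index_label="feature")


def signed_fold_change(mean_normal_log2, mean_cancer_log2):
    """Signed linear fold change from two log2 group means.

    ``d = mean_cancer - mean_normal``; returns ``2**d`` if ``d >= 0`` else
    ``-2**(-d)``.  ``d = 0`` maps to ``+1`` (no change); the magnitude is
    always ``2**|d| >= 1``.  Accepts scalars or arrays.
    """
    d = np.asarray(mean_cancer_log2, dtype=float) - np.asarray(mean_normal_log2, dtype=float)
    fc = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    if fc.ndim == 0:
        return float(fc)
    return fc


def present_filter(
    mat: ExpressionMatrix,
    min_fraction: float = 0.6,
    strict: bool = True,
    mode: str = "either_group",
) -> tuple[ExpressionMatrix, SelectionReport]:
    """Keep features detected in a sufficient fraction of either group.

    With ``strict=True`` a feature is retained when its present fraction is
    *strictly greater* than ``min_fraction`` in at least one group (the
    ">60% present calls" mRNA rule); with ``strict=False`` the comparison is
    ``>=`` (the "at least 65%" miRNA rule).
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if mode != "either_group":
        raise ValueError(f"unsupported mode {mode!r}")
    report = SelectionReport()
    report.record("input", len(mat.feature_ids))
    frac_n = mat.present_fraction(NORMAL)
    frac_c = mat.present_fraction(CANCER)
    if strict:
        keep = (frac_n > min_fraction) | (frac_c > min_fraction)
    else:
        keep = (frac_n >= min_fraction) | (frac_c >= min_fraction)
    out = mat.subset(mat.values.index[keep])
    report.record("present", len(out.feature_ids))
    return out, report


def differential_expression(
    mat: ExpressionMatrix,
    n_permutations: int = 500,
    fdr_threshold: float = 0.055,
    seed: int | None = None,
    null: str = "pooled",
    variance_floor_quantile: float = 0.05,
) -> DETable:
    """Permutation t-test differential expression between the two groups.

    A moderated two-sample t-statistic (pooled-variance, with the per-feature
    standard error floored at the ``variance_floor_quantile`` quantile across
    features — a SAM-like fudge constant) is compared against a group-label
    permutation null.  ``null="pooled"`` pools permuted statistics across all
    features; ``null="per_feature"`` compares each feature only against its
    own permutation distribution.  Both use the add-one estimator
    ``p = (1 + #{|t*| >= |t|}) / (1 + B)`` so p-values are valid
    (super-uniform) under the null.  ``null="parametric"`` skips permutation
    and takes two-sided Student-t tail probabilities instead — the right
    choice for very small designs (e.g. 3 vs 3 miRNA arrays, where only 20
    distinct relabelings exist and no permutation p can fall below 0.05).
    FDR is Benjamini–Hochberg.

    Deterministic given ``seed``.
    """
    if mat.scale != "log2":
        raise ValueError("differential_expression requires a log2-scale matrix")
    if null not in ("pooled", "per_feature", "parametric"):
        raise ValueError(f"unknown null {null!r}")
    if null != "parametric" and n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    n1 = len(mat.samples_in(NORMAL))
    n2 = len(mat.samples_in(CANCER))
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    # native column order: keeps the permutation stream, and hence every
    # p-value, exactly invariant under a normal/cancer label exchange
    values = mat.values.to_numpy(dtype=float)
    labels = (mat.groups.to_numpy() == CANCER).astype(int)

    def tstat(vals: np.ndarray, lab: np.ndarray, s_floor: float | None = None):
        a = vals[:, lab == 0]
        b = vals[:, lab == 1]
        ka, kb = a.shape[1], b.shape[1]
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        sp = np.sqrt(((ka - 1) * va + (kb - 1) * vb) / (ka + kb - 2))
        se = sp * np.sqrt(1.0 / ka + 1.0 / kb)
        if s_floor is not None:
            se = np.maximum(se, s_floor)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mb - ma) / se
        return t, ma, mb, se

    # variance floor from the observed labelling, reused for permutations
    _, _, _, se_obs = tstat(values, labels)
    zero_var = int((se_obs == 0).sum())
    if zero_var:
        logger.info("%d zero-variance feature(s); variance floor applied", zero_var)
    positive = se_obs[se_obs > 0]
    s_floor = float(np.quantile(positive, variance_floor_quantile)) if len(positive) else 1e-8
    s_floor = max(s_floor, 1e-12)

    t_obs, mean_n, mean_c, _ = tstat(values, labels, s_floor)

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(t_obs)
    if null == "parametric":
        p = 2.0 * stats.t.sf(abs_obs, df=n1 + n2 - 2)
    elif null == "pooled":
        null_stats = np.empty((n_permutations, len(t_obs)))
        for b in range(n_permutations):
            perm = rng.permutation(labels)
            null_stats[b], *_ = tstat(values, perm, s_floor)
        flat = np.sort(np.abs(null_stats).ravel())
        # count of null |t*| >= |t| via searchsorted on the sorted pool
        greater = flat.size - np.searchsorted(flat, abs_obs, side="left")
        p = (1.0 + greater) / (1.0 + flat.size)
    else:
        exceed = np.zeros(len(t_obs))
        for b in range(n_permutations):
            perm = rng.permutation(labels)
            t_b, *_ = tstat(values, perm, s_floor)
            exceed += np.abs(t_b) >= abs_obs
        p = (1.0 + exceed) / (1.0 + n_permutations)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    fc = signed_fold_change(mean_n, mean_c)
    direction = np.where(q > fdr_threshold, NS, np.where(fc > 0, UP, DOWN))
    # a zero log2 difference cannot be a DEG; guard the degenerate fc == 1 case
    frame = pd.DataFrame(
        {
            "mean_normal": mean_n,
            "mean_cancer": mean_c,
            "fc": fc,
            "t": t_obs,
            "p": p,
            "q": q,
            "direction": direction,
        },
        index=mat.values.index,
    )
    return DETable(frame, fdr_threshold)


def collapse_probesets(
    de: DETable,
    probe_to_gene: pd.Series,
    rule: str = "min_p",
) -> DETable:
    """Collapse probe-set rows to one row per gene symbol.

    ``rule="min_p"`` keeps the probe set with the smallest p per gene;
    ``rule="max_fc"`` keeps the largest ``|fc|``.  Probe sets without a
    mapping are dropped.
    """
    if rule not in ("min_p", "max_fc"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    frame = de.frame.copy()
    frame["gene"] = frame.index.map(probe_to_gene)
    frame = frame[frame["gene"].notna()]
    if rule == "min_p":
        order = frame.sort_values("p", kind="stable")
    else:
        order = frame.sort_values("fc", key=np.abs, ascending=False, kind="stable")
    best = order.drop_duplicates(subset="gene", keep="first")
    best = best.set_index("gene").sort_index()
    return DETable(best, de.fdr_threshold)


def select_mirnas(
    de: DETable,
    conserved: GeneList,
    fc_min: float = 6.0,
    p_max: float = 0.03,
    require_prefix: str | None = "hsa-",
) -> tuple[GeneList, SelectionReport]:
    """Select upregulated miRNAs: human, conserved, fc > fc_min, p < p_max.

    Both threshold comparisons are strict, matching the printed rule
    "(fc > 6, p-value < .03)": a miRNA at exactly fc = 6 or p = 0.03 is
    excluded.
    """
    report = SelectionReport()
    frame = de.frame
    report.record("input", len(frame))
    if require_prefix is not None:
        human = frame.index.str.lower().str.startswith(require_prefix.lower())
        frame = frame[human]
    report.record("human", len(frame))
    frame = frame[frame.index.isin(conserved.as_set() | set(conserved.symbols))]
    report.record("conserved", len(frame))
    passing = frame[(frame["fc"] > fc_min) & (frame["p"] < p_max)]
    report.record("selected", len(passing))
    if passing.empty:
        logger.warning("no miRNAs pass fc > %s and p < %s", fc_min, p_max)
    return GeneList.from_iterable(passing.index, normalize=False), report
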