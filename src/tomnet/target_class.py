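"""Classify predicted miRNA targets as IC, PC, or NC.

A gene predicted to be targeted by at least one selected upregulated miRNA
is *inversely correlated* (IC) with its regulators if it is significantly
down in cancer, *positively correlated* (PC) if significantly up, and
*no change detected* (NC) if it is not a DEG at the FDR threshold.  NC is
deliberately defined by significance, not by fold-change magnitude: an NC
gene may be a partially masked target or simply unregulated, and the two
cannot be distinguished from expression alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DOWN, NS, UP, DETable
from .io_formats import GeneList, TargetPredictionTable

logger = logging.getLogger(__name__)

IC = "IC"
PC = "PC"
NC = "NC"

_DIRECTION_TO_CLASS = {DOWN: IC, UP: PC, NS: NC}


@dataclass
class TargetClassification:
    """Per-gene miRNA-target classification.

    ``frame`` is indexed by gene symbol with columns ``n_mirnas`` (number of
    distinct selected miRNAs predicted to target the gene, >= 1) and
    ``target_class`` in {IC, PC, NC}.  ``n_unmeasured`` counts predicted
    targets excluded because they were absent from the filtered expression
    matrix.
    """

    frame: pd.DataFrame
    n_unmeasured: int = 0

    def __post_init__(self) -> None:
        if not {"n_mirnas", "target_class"} <= set(self.frame.columns):
            raise ValueError("classification needs n_mirnas and target_class columns")
        bad = set(self.frame["target_class"]) - {IC, PC, NC}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if (self.frame["n_mirnas"] < 1).any():
            raise ValueError("every classified gene must have >= 1 targeting miRNA")

    def __len__(self) -> int:
        return len(self.frame)

    def counts(self) -> dict[str, int]:
        c = self.frame["target_class"].value_counts()
        return {cls: int(c.get(cls, 0)) for cls in (IC, PC, NC)}

    def genes_in(self, cls: str) -> set[str]:
        return set(self.frame.index[self.frame["target_class"] == cls])

    def class_of(self, gene: str) -> str:
        return self.frame.at[gene, "target_class"]

    def mirna_count_of(self, gene: str) -> int:
        return int(self.frame.at[gene, "n_mirnas"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene")


def classify_targets(
    predictions: TargetPredictionTable,
    de: DETable,
    selected_mirnas: GeneList,
) -> TargetClassification:
    """Classify every measured predicted target of the selected miRNAs.

    Predictions referencing miRNAs outside the selected set are ignored.
    Genes never measured on the (present-filtered) array are excluded from
    the denominator but counted in ``n_unmeasured``.
    """
    selected = set(selected_mirnas)
    sub = predictions.restrict(selected)
    counts = sub.mirna_counts(selected)
    measured = counts.index.intersection(de.features)
    n_unmeasured = len(counts) - len(measured)
    if n_unmeasured:
        logger.info("%d predicted target gene(s) not on the filtered array", n_unmeasured)
    directions = de.frame.loc[measured, "direction"]
    frame = pd.DataFrame(
        {
            "n_mirnas": counts.loc[measured].astype(int),
            "target_class": directions.map(_DIRECTION_TO_CLASS),
        },
        index=measured,
    ).sort_index()
    return TargetClassification(frame, n_unmeasured=n_unmeasured)


def round_half_up_percent(count: int, total: int) -> int:
    """Integer percentage with conventional round-half-up."""
    return int(np.floor(100.0 * count / total + 0.5))


def summarize_classification(tc: TargetClassification | dict[str, int]) -> dict:
    """Counts and integer percentages per class, plus the classified total.

    Accepts either a :class:`TargetClassification` or a plain
    ``{"IC": n, "PC": n, "NC": n}`` dict (e.g. printed table rows).
    Percentages are computed on the classified total with round-half-up,
    so they may not sum to exactly 100.
    """
    counts = tc.counts() if isinstance(tc, TargetClassification) else dict(tc)
    total = sum(counts.get(c, 0) for c in (IC, PC, NC))
    if total == 0:
        raise ValueError("empty classification")
    out: dict = {"total": total}
    for cls in (IC, PC, NC):
        n = int(counts.get(cls, 0))
        out[cls] = n
        out[f"{cls}_pct"] = round_half_up_percent(n, total)
    return out


def repressive_potential(
    predictions: TargetPredictionTable,
    de: DETable,
    selected_mirnas: GeneList,
) -> tuple[pd.DataFrame, float, float]:
    """Per-miRNA repression check among differentially expressed targets.

    For each selected miRNA: the fraction of its predicted DEG targets that
    are downregulated (its apparent repressive potential).  The background
    is the downregulated fraction among DEGs predicted to be targeted by
    *none* of the selected miRNAs.  Returns
    ``(per_mirna_frame, mean_fraction, background_fraction)``; a miRNA with
    zero DEG targets gets a missing (NaN) fraction and is excluded from the
    mean.
    """
    selected = list(selected_mirnas)
    degs = set(de.degs())
    down = set(de.down())
    sub = predictions.restrict(selected)
    rows = []
    for mirna in selected:
        targets = sub.genes_of([mirna]) & degs
        if not targets:
            logger.warning("miRNA %s has no DEG targets; fraction undefined", mirna)
            rows.append((mirna, 0, np.nan))
            continue
        n_down = len(targets & down)
        rows.append((mirna, len(targets), n_down / len(targets)))
    frame = pd.DataFrame(rows, columns=["mirna", "n_deg_targets", "frac_down"]).set_index("mirna")

    targeted = sub.genes_of(selected)
    background_degs = degs - targeted
    background = (
        len(background_degs & down) / len(background_degs) if background_degs else np.nan
    )
    mean_fraction = float(frame["frac_down"].mean())
    return frame, mean_fraction, float(background)
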