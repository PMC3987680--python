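"""Assemble the transcriptional-override feed-forward network.

The motif of interest is a three-node feed-forward loop: an upregulated
miRNA targets both a transcriptional repressor and one of the repressor's
regulon genes.  Downregulation of the repressor derepresses the mutual
target, opposing (masking or overriding) the miRNA's direct repression of
that same target.  This module builds the network from the three edge
layers, indexes one :class:`FFLRecord` per mutual target, and answers
per-gene motif queries.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io_formats import REL_MIRNA, REL_REPRESSES, EdgeSet
from .target_class import IC, NC, PC, TargetClassification

logger = logging.getLogger(__name__)


@dataclass
class FFLRecord:
    """One mutual-target motif instance.

    ``shared_mirnas`` are the miRNAs that target both this gene and at
    least one of its retained repressors — the miRNAs closing the
    feed-forward triangle.
    """

    target: str
    targeting_mirnas: frozenset[str]
    repressors: frozenset[str]
    shared_mirnas: frozenset[str]
    target_class: str

    def __post_init__(self) -> None:
        if not self.shared_mirnas <= self.targeting_mirnas:
            raise ValueError("shared miRNAs must target the gene itself")
        if self.target_class not in (IC, PC, NC):
            raise ValueError(f"bad class {self.target_class!r}")

    def narrative(self) -> str:
        lines = [
            f"{self.target} [{self.target_class}] is a predicted target of "
            f"{len(self.targeting_mirnas)} upregulated miRNA(s) and of "
            f"{len(self.repressors)} downregulated repressor(s): "
            + ", ".join(sorted(self.repressors))
            + "."
        ]
        if self.shared_mirnas:
            lines.append(
                f"{len(self.shared_mirnas)} miRNA(s) close the feed-forward loop "
                f"(target both {self.target} and a repressor): "
                + ", ".join(sorted(self.shared_mirnas))
                + "."
            )
        if self.target_class == PC:
            lines.append(
                "Its increased expression despite miRNA targeting is consistent "
                "with repressor-mediated derepression overriding miRNA repression."
            )
        elif self.target_class == NC:
            lines.append(
                "Its unchanged expression is consistent with derepression masking "
                "miRNA repression (or with weak regulation)."
            )
        return "\n".join(lines)


@dataclass
class TomNetwork:
    """Typed miRNA/repressor/target network with a per-target motif index."""

    graph: nx.DiGraph
    mirnas: set[str]
    repressors: set[str]
    mutual_targets: set[str]
    repressor_only: set[str]
    mirna_only: set[str]
    records: dict[str, FFLRecord] = field(default_factory=dict)

    def partition(self, universe: set[str]) -> dict[str, set[str]]:
        """Exact partition of a candidate gene universe by edge coverage."""
        neither = universe - self.mutual_targets - self.repressor_only - self.mirna_only
        return {
            "mutual": self.mutual_targets & universe,
            "repressor_only": self.repressor_only & universe,
            "mirna_only": self.mirna_only & universe,
            "neither": neither,
        }

    def edge_set(self) -> EdgeSet:
        edges = EdgeSet()
        for u, v, data in self.graph.edges(data=True):
            edges.add(u, data["relation"], v)
        return edges

    def subgraph_edges(self, gene: str) -> EdgeSet:
        """All edges touching `gene`, its repressors, and their miRNAs."""
        rec = self.records.get(gene)
        edges = EdgeSet()
        for u, v, data in self.graph.in_edges(gene, data=True):
            edges.add(u, data["relation"], v)
        if rec:
            for rep in rec.repressors:
                for u, v, data in self.graph.in_edges(rep, data=True):
                    edges.add(u, data["relation"], v)
        return edges


def build_tom_network(
    mirna_edges: EdgeSet,
    repressor_edges: EdgeSet,
    classification: TargetClassification,
    repressor_only_edges: EdgeSet | None = None,
) -> TomNetwork:
    """Build the feed-forward network from the two regulatory layers.

    ``mirna_edges`` must already be restricted to the selected upregulated
    miRNAs, and ``repressor_edges`` to the selected (downregulated,
    miRNA-targeted) repressors from a single provenance layer — binding-site
    or co-expression edges are analyzed separately, never merged silently.

    Mutual targets have at least one edge of each type; regulon genes with
    no miRNA edge form the repressor-only group (supplied explicitly via
    ``repressor_only_edges`` when the upstream filter already removed them).
    Self-regulation (a repressor listed in its own regulon) is excluded
    upstream.
    """
    mirna_pairs = mirna_edges.pairs(REL_MIRNA)
    rep_pairs = repressor_edges.pairs(REL_REPRESSES)
    if repressor_only_edges is not None:
        rep_pairs |= repressor_only_edges.pairs(REL_REPRESSES)
    mirnas = {m for m, _ in mirna_pairs}
    repressors = {r for r, _ in rep_pairs}

    mirna_targets_of: dict[str, set[str]] = {}
    for m, g in mirna_pairs:
        mirna_targets_of.setdefault(g, set()).add(m)
    rep_of: dict[str, set[str]] = {}
    for r, g in rep_pairs:
        rep_of.setdefault(g, set()).add(r)

    mirna_covered = set(mirna_targets_of)
    rep_covered = set(rep_of)
    if not (mirna_covered & rep_covered) and mirna_covered and rep_covered:
        raise ValueError(
            "miRNA-target and repressor-target gene universes are disjoint; "
            "check gene-symbol normalization"
        )

    mutual = mirna_covered & rep_covered
    repressor_only = rep_covered - mirna_covered
    mirna_only = mirna_covered - rep_covered

    graph = nx.DiGraph()
    for m, g in mirna_pairs:
        graph.add_edge(m, g, relation=REL_MIRNA)
    for r, g in rep_pairs:
        graph.add_edge(r, g, relation=REL_REPRESSES)

    records: dict[str, FFLRecord] = {}
    for gene in sorted(mutual):
        targeting = frozenset(mirna_targets_of[gene])
        reps = frozenset(rep_of[gene])
        rep_mirnas: set[str] = set()
        for rep in reps:
            rep_mirnas |= mirna_targets_of.get(rep, set())
        shared = frozenset(targeting & rep_mirnas)
        cls = (
            classification.class_of(gene)
            if gene in classification.frame.index
            else NC
        )
        records[gene] = FFLRecord(
            target=gene,
            targeting_mirnas=targeting,
            repressors=reps,
            shared_mirnas=shared,
            target_class=cls,
        )
    return TomNetwork(
        graph=graph,
        mirnas=mirnas,
        repressors=repressors,
        mutual_targets=mutual,
        repressor_only=repressor_only,
        mirna_only=mirna_only,
        records=records,
    )


def query_gene(network: TomNetwork, symbol: str) -> tuple[FFLRecord | None, str]:
    """Full motif context for one gene, with a human-readable narrative."""
    if symbol in network.records:
        rec = network.records[symbol]
        return rec, rec.narrative()
    known = set(network.graph.nodes)
    if symbol in known:
        in_mirna = symbol in network.mirna_only
        in_rep = symbol in network.repressor_only
        if in_mirna:
            msg = (
                f"{symbol} is targeted by upregulated miRNA(s) but has no retained "
                "repressor edge; it is not a mutual target."
            )
        elif in_rep:
            msg = (
                f"{symbol} is in a retained repressor regulon but is not a predicted "
                "target of any selected miRNA (repressor-only group)."
            )
        elif symbol in network.mirnas or symbol in network.repressors:
            msg = f"{symbol} is a regulator node, not a target gene."
        else:
            msg = f"{symbol} is in the network but carries no classified motif."
        return None, msg
    near = difflib.get_close_matches(symbol, list(known), n=5)
    raise KeyError(f"unknown symbol {symbol!r}; nearest matches: {near}")


def records_frame(network: TomNetwork) -> pd.DataFrame:
    """FFLRecord index as a flat table (one row per mutual target)."""
    rows = []
    for gene in sorted(network.records):
        rec = network.records[gene]
        rows.append(
            {
                "gene": gene,
                "target_class": rec.target_class,
                "n_mirnas": len(rec.targeting_mirnas),
                "n_repressors": len(rec.repressors),
                "n_shared_mirnas": len(rec.shared_mirnas),
                "repressors": ",".join(sorted(rec.repressors)),
                "shared_mirnas": ",".join(sorted(rec.shared_mirnas)),
            }
        )
    return pd.DataFrame(rows)
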