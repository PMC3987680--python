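"""Readers and writers for the external formats the pipeline touches.

Every downstream stage consumes only the in-memory containers defined here:

* :class:`ExpressionMatrix` — features × samples with group labels and
  present/absent detection flags,
* :class:`TargetPredictionTable` — miRNA → gene predictions with a score,
* :class:`RegulonTable` — repressor → target-set mappings (TRANSFAC-style
  GMT sets or co-expression-inferred regulons),
* :class:`GeneList` — an ordered, de-duplicated list of gene symbols,
* :class:`EdgeSet` — typed regulator → target edges for network export.

File formats are deliberately plain: tab-separated tables, GMT gene sets,
one-symbol-per-line gene lists, and SIF for network export.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORMAL = "normal"
CANCER = "cancer"
GROUPS = (NORMAL, CANCER)

#: SIF relation labels for the two regulatory edge types.
REL_MIRNA = "mirna_targets"
REL_REPRESSES = "represses"


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol (no alias resolution)."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A features × samples expression matrix with metadata.

    Parameters
    ----------
    values
        DataFrame of expression values, index = feature ids, columns =
        sample ids.
    scale
        ``"log2"`` or ``"linear"``; fold-change computations require log2.
    groups
        Series mapping sample id → ``"normal"`` or ``"cancer"``.
    present
        Boolean DataFrame of per-sample detection calls, same shape as
        ``values``.  If ``None``, everything is treated as present.
    """

    values: pd.DataFrame
    scale: str
    groups: pd.Series
    present: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        bad = sorted(set(self.groups) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group labels: {bad}; expected {GROUPS}")
        for g in GROUPS:
            if not (self.groups == g).any():
                raise ValueError(f"group {g!r} has no samples")
        if self.present is not None:
            if self.present.shape != self.values.shape:
                raise ValueError("present flags must match the value matrix shape")
            self.present = self.present.astype(bool)
            self.present.index = self.values.index
            self.present.columns = self.values.columns

    # -- convenience views --------------------------------------------------

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list:
        return list(self.groups.index[self.groups == group])

    def subset(self, features: Sequence) -> "ExpressionMatrix":
        """Restrict to a feature subset, preserving order of `features`."""
        idx = [f for f in features if f in self.values.index]
        return ExpressionMatrix(
            values=self.values.loc[idx],
            scale=self.scale,
            groups=self.groups,
            present=None if self.present is None else self.present.loc[idx],
        )

    def present_fraction(self, group: str) -> pd.Series:
        """Per-feature fraction of present calls within one group."""
        cols = self.samples_in(group)
        if self.present is None:
            return pd.Series(1.0, index=self.values.index)
        return self.present[cols].mean(axis=1)

    def to_log2(self, floor: float = 1.0) -> "ExpressionMatrix":
        """Return a log2-scale copy (values floored at `floor` first)."""
        if self.scale == "log2":
            return self
        vals = np.log2(self.values.clip(lower=floor))
        return ExpressionMatrix(vals, "log2", self.groups, self.present)


def read_expression_matrix(
    path: str | Path,
    group_map: Mapping[str, str],
    scale: str,
    present_path: str | Path | None = None,
    present_floor: float | None = None,
    normalize_features: bool = False,
    alias_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited expression table (features in rows).

    The first column holds feature ids and the header row sample ids; every
    sample id must appear in ``group_map``.  Features whose values are all
    missing are dropped (with a logged count).  Detection flags come from an
    optional companion table of 0/1 values (``present_path``), or are derived
    as ``value > present_floor`` if a floor is given, else all-present.
    """
    path = Path(path)
    header = path.read_text().splitlines()[0].rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"{path}: duplicated sample id(s): {dupes}")
    unknown = [s for s in samples if s not in group_map]
    if unknown:
        raise ValueError(f"{path}: sample(s) not covered by group_map: {unknown}")

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value at feature {bad[0]!r}, sample {col!r}"
            )
        values[col] = converted

    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        logger.info("%s: dropped %d all-missing feature(s)", path, int(all_missing.sum()))
        values = values.loc[~all_missing]
    if normalize_features:
        aliases = {normalize_symbol(k): normalize_symbol(v) for k, v in (alias_map or {}).items()}
        norm = [normalize_symbol(f) for f in values.index]
        values.index = [aliases.get(f, f) for f in norm]
        if values.index.duplicated().any():
            # keep first occurrence; duplicated symbols after normalization
            n = int(values.index.duplicated().sum())
            logger.warning("%s: %d duplicate feature symbol(s) after normalization", path, n)
            values = values.loc[~values.index.duplicated()]

    present: pd.DataFrame | None = None
    if present_path is not None:
        pres = pd.read_csv(present_path, sep="\t", index_col=0)
        pres = pres.reindex(index=values.index, columns=values.columns).fillna(0)
        present = pres.astype(float) > 0.5
    elif present_floor is not None:
        present = values > present_floor

    groups = pd.Series({s: group_map[s] for s in values.columns})
    return ExpressionMatrix(values=values, scale=scale, groups=groups, present=present)


def write_expression_matrix(
    mat: ExpressionMatrix,
    path: str | Path,
    present_path: str | Path | None = None,
    float_format: str = "%.6f",
    index_label: str = "feature",
) -> None:
    """Write the value matrix (and optionally the 0/1 present flags) as TSV."""
    mat.values.to_csv(path, sep="\t", float_format=float_format, index_label=index_label)
    if present_path is not None:
        if mat.present is None:
            raise ValueError("matrix has no present flags to write")
        mat.present.astype(int).to_csv(
            path_or_buf=present_path, sep="\t", index_label=index_label
        )


# ---------------------------------------------------------------------------
# GeneList
# ---------------------------------------------------------------------------


@dataclass
class GeneList:
    """Ordered, unique gene symbols with optional per-symbol annotation."""

    symbols: list[str]
    annotations: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_iterable(cls, symbols: Iterable[str], normalize: bool = True) -> "GeneList":
        seen: dict[str, None] = {}
        for s in symbols:
            s = normalize_symbol(s) if normalize else s.strip()
            if s and s not in seen:
                seen[s] = None
        return cls(list(seen))

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def as_set(self) -> set[str]:
        return set(self.symbols)


def read_gene_list(path: str | Path, normalize: bool = True) -> GeneList:
    """Read one symbol per line; an optional TAB-separated second field is
    kept as an annotation (e.g. GO term of origin, conserved flag)."""
    symbols: list[str] = []
    annotations: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        sym = normalize_symbol(parts[0]) if normalize else parts[0]
        symbols.append(sym)
        if len(parts) > 1:
            annotations[sym] = parts[1]
    gl = GeneList.from_iterable(symbols, normalize=False)
    gl.annotations = {s: annotations[s] for s in gl.symbols if s in annotations}
    return gl


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in genes.symbols:
            if s in genes.annotations:
                fh.write(f"{s}\t{genes.annotations[s]}\n")
            else:
                fh.write(f"{s}\n")


# ---------------------------------------------------------------------------
# RegulonTable / GMT
# ---------------------------------------------------------------------------

#: Default TRANSFAC-style set-name parser: the token between "V$" and the
#: first underscore, e.g. "V$YY1_02" -> "YY1".
_TRANSFAC_NAME = re.compile(r"^V\$([A-Za-z0-9.-]+?)_")


def transfac_name_parser(name: str) -> str | None:
    m = _TRANSFAC_NAME.match(name.strip())
    return normalize_symbol(m.group(1)) if m else None


@dataclass
class RegulonTable:
    """Mapping repressor symbol → set of target gene symbols.

    ``provenance`` records, per regulon, whether the mapping came from a
    binding-site gene-set file (``"transfac"``) or from co-expression
    inference (``"correlation"``).  ``unparsed`` counts GMT set names the
    name parser could not map to a symbol (kept under their raw names).
    """

    regulons: dict[str, set[str]]
    provenance: dict[str, str] = field(default_factory=dict)
    unparsed: int = 0
    self_loops_removed: int = 0

    def __post_init__(self) -> None:
        for key, members in self.regulons.items():
            if key in members:
                raise ValueError(f"self-loop in regulon {key!r}; strip before constructing")

    def keys(self):
        return self.regulons.keys()

    def __getitem__(self, key: str) -> set[str]:
        return self.regulons[key]

    def __contains__(self, key: str) -> bool:
        return key in self.regulons

    def __len__(self) -> int:
        return len(self.regulons)

    def items(self):
        return self.regulons.items()

    def all_targets(self, keys: Iterable[str] | None = None) -> set[str]:
        keys = self.regulons.keys() if keys is None else keys
        out: set[str] = set()
        for k in keys:
            if k in self.regulons:
                out |= self.regulons[k]
        return out


def read_gmt(
    path: str | Path,
    name_parser: Callable[[str], str | None] = transfac_name_parser,
    provenance: str = "transfac",
) -> RegulonTable:
    """Parse a GMT gene-set file into a :class:`RegulonTable`.

    Standard GMT: ``name TAB description TAB member TAB member ...``.  Set
    names the parser maps to a symbol are keyed by that symbol; unparseable
    names are retained under the raw name (counted in ``unparsed``).  A set
    containing its own parsed symbol has that member removed (self-loop).
    Lines with fewer than three fields are skipped with a warning.
    """
    regulons: dict[str, set[str]] = {}
    unparsed = 0
    self_loops = 0
    skipped = 0
    lines = Path(path).read_text().splitlines()
    for line in lines:
        if not line.strip():
            continue
        fields = [f.strip() for f in line.rstrip("\n").split("\t")]
        if len(fields) < 3:
            skipped += 1
            continue
        raw_name, _desc, *members = fields
        key = name_parser(raw_name)
        if key is None:
            key = raw_name
            unparsed += 1
        members_set = {normalize_symbol(m) for m in members if m.strip()}
        if key in members_set:
            members_set.discard(key)
            self_loops += 1
            logger.info("GMT set %s: removed self-loop member", raw_name)
        regulons.setdefault(key, set()).update(members_set)
    if skipped:
        logger.warning("%s: skipped %d malformed GMT line(s)", path, skipped)
    if not regulons:
        raise ValueError(f"{path}: no gene sets parsed")
    return RegulonTable(
        regulons=regulons,
        provenance={k: provenance for k in regulons},
        unparsed=unparsed,
        self_loops_removed=self_loops,
    )


def write_gmt(table: RegulonTable, path: str | Path, name_format: str = "V${sym}_01") -> None:
    """Write regulons as GMT with TRANSFAC-style set names (sorted, stable)."""
    with open(path, "w") as fh:
        for key in sorted(table.regulons):
            members = "\t".join(sorted(table.regulons[key]))
            fh.write(f"{name_format.format(sym=key)}\t{key} targets\t{members}\n")


# ---------------------------------------------------------------------------
# TargetPredictionTable
# ---------------------------------------------------------------------------


@dataclass
class TargetPredictionTable:
    """Filtered miRNA → gene target predictions.

    ``table`` has columns ``mirna``, ``gene``, ``score`` with unique
    (mirna, gene) pairs; ``score_cutoff`` records the strict upper bound
    applied (rows kept satisfy ``score < score_cutoff``).
    """

    table: pd.DataFrame
    score_cutoff: float | None = None

    def __post_init__(self) -> None:
        required = {"mirna", "gene", "score"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"prediction table needs columns {sorted(required)}")
        if self.table.duplicated(subset=["mirna", "gene"]).any():
            raise ValueError("duplicate (mirna, gene) pairs after filtering")
        if not np.isfinite(self.table["score"]).all():
            raise ValueError("non-finite prediction scores")

    def __len__(self) -> int:
        return len(self.table)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["mirna"], self.table["gene"]))

    def genes_of(self, mirnas: Iterable[str]) -> set[str]:
        """Genes predicted to be targeted by at least one of `mirnas`."""
        sel = self.table["mirna"].isin(set(mirnas))
        return set(self.table.loc[sel, "gene"])

    def mirna_counts(self, mirnas: Iterable[str]) -> pd.Series:
        """Per-gene number of distinct miRNAs (from `mirnas`) targeting it."""
        sel = self.table[self.table["mirna"].isin(set(mirnas))]
        return sel.groupby("gene")["mirna"].nunique()

    def restrict(self, mirnas: Iterable[str]) -> "TargetPredictionTable":
        sub = self.table[self.table["mirna"].isin(set(mirnas))].reset_index(drop=True)
        return TargetPredictionTable(sub, self.score_cutoff)


def read_target_predictions(
    path: str | Path,
    score_cutoff: float = -0.2,
    mirna_col: str = "mirna",
    gene_col: str = "gene_symbol",
    score_col: str = "mirsvr_score",
    alias_map: Mapping[str, str] | None = None,
) -> TargetPredictionTable:
    """Read a tab-delimited prediction table and filter by score.

    Only rows with ``score < score_cutoff`` (strictly) are retained — more
    negative scores predict stronger repression.  Duplicate (miRNA, gene)
    rows are collapsed keeping the minimum (strongest) score.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in (mirna_col, gene_col, score_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.rename(columns={mirna_col: "mirna", gene_col: "gene", score_col: "score"})
    df = df[["mirna", "gene", "score"]].copy()
    df["gene"] = df["gene"].map(normalize_symbol)
    if alias_map:
        aliases = {normalize_symbol(k): normalize_symbol(v) for k, v in alias_map.items()}
        df["gene"] = df["gene"].map(lambda g: aliases.get(g, g))
    df["mirna"] = df["mirna"].astype(str).str.strip()
    df = df[df["score"] < score_cutoff]
    if df.empty:
        logger.warning("%s: no predictions pass score < %s", path, score_cutoff)
    df = df.groupby(["mirna", "gene"], as_index=False)["score"].min()
    return TargetPredictionTable(df.reset_index(drop=True), score_cutoff)


def write_target_predictions(
    table: pd.DataFrame,
    path: str | Path,
    float_format: str = "%.4f",
) -> None:
    """Write an (unfiltered) prediction table with canonical column names."""
    out = table.rename(columns={"mirna": "mirna", "gene": "gene_symbol", "score": "mirsvr_score"})
    out.to_csv(path, sep="\t", index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# EdgeSet / SIF
# ---------------------------------------------------------------------------


@dataclass
class EdgeSet:
    """Typed regulator → target edges.

    Each edge is ``(source, relation, target)`` with relation one of
    ``mirna_targets`` or ``represses``.
    """

    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        allowed = {REL_MIRNA, REL_REPRESSES}
        bad = {rel for _, rel, _ in self.edges if rel not in allowed}
        if bad:
            raise ValueError(f"unknown edge relation(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(sorted(self.edges))

    def add(self, source: str, relation: str, target: str) -> None:
        if relation not in (REL_MIRNA, REL_REPRESSES):
            raise ValueError(f"unknown relation {relation!r}")
        self.edges.add((source, relation, target))

    def sources(self, relation: str | None = None) -> set[str]:
        return {s for s, r, _ in self.edges if relation is None or r == relation}

    def targets_of(self, source: str) -> set[str]:
        return {t for s, _, t in self.edges if s == source}

    def pairs(self, relation: str | None = None) -> set[tuple[str, str]]:
        return {(s, t) for s, r, t in self.edges if relation is None or r == relation}


def write_network_sif(edges: EdgeSet, path: str | Path) -> None:
    """Write edges as SIF (``source TAB relation TAB target``), sorted."""
    with open(path, "w") as fh:
        for source, relation, target in sorted(edges.edges):
            fh.write(f"{source}\t{relation}\t{target}\n")


def read_network_sif(path: str | Path) -> EdgeSet:
    edges: set[tuple[str, str, str]] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed SIF line {line!r}")
        edges.add((parts[0], parts[1], parts[2]))
    return EdgeSet(edges)
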