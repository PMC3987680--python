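"""End-to-end orchestration from a single flat config file.

Stages run in dependency order — differential expression → target
classification → repressor selection → network assembly → stratified
statistics — and every artifact is written only after all stages have
succeeded, so a failed run leaves no partial outputs.  Reruns with an
identical config (including the seed) reproduce identical tables; stage
timings go to a separate sidecar file so the analytical outputs themselves
are byte-stable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, io_formats, repressors, stratification, synthetic, target_class
from .io_formats import (
    REL_MIRNA,
    EdgeSet,
    GeneList,
    read_expression_matrix,
    read_gene_list,
    read_gmt,
    read_network_sif,
    read_target_predictions,
    write_network_sif,
)
from .tom_network import TomNetwork, build_tom_network, records_frame

logger = logging.getLogger(__name__)

#: Defaults for every tunable; unknown config keys are rejected outright.
DEFAULTS: dict = {
    # input paths (required for `run`)
    "mrna_expression": None,
    "mrna_present": None,
    "mrna_groups": None,
    "mirna_expression": None,
    "mirna_present": None,
    "mirna_groups": None,
    "predictions": None,
    "regulons": None,
    "go_candidates": None,
    "conserved_mirnas": None,
    "output_dir": None,
    # prediction table column names
    "prediction_mirna_col": "mirna",
    "prediction_gene_col": "gene_symbol",
    "prediction_score_col": "mirsvr_score",
    # thresholds (printed defaults; strictness as printed)
    "fdr_threshold": 0.055,
    "mirna_fc_min": 6.0,
    "mirna_p_max": 0.03,
    "present_fraction_mrna": 0.60,  # strict >
    "present_fraction_mirna": 0.65,  # non-strict >=
    "score_cutoff": -0.2,  # strict <
    "r_threshold": -0.8,  # strict <
    "n_permutations": 500,
    "permutation_null": "pooled",
    # the 3+3 miRNA design admits only 20 distinct relabelings, so the
    # miRNA stage defaults to Student-t tail probabilities
    "mirna_test": "parametric",
    "seed": None,  # required
    "mirna_bin_edges": [1, 6, 11, 16],
    "repressor_bin_edges": [1, 2, 6],
    "trend_sided": "two",
    # generator section (used by `simulate`)
    "generator": None,
}

_REQUIRED_RUN_KEYS = (
    "mrna_expression",
    "mrna_groups",
    "mirna_expression",
    "mirna_groups",
    "predictions",
    "regulons",
    "go_candidates",
    "conserved_mirnas",
    "output_dir",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated flat configuration."""

    values: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(raw)
        if overrides:
            clash = {k for k, v in overrides.items() if v is not None and raw.get(k) is not None}
            if clash:
                raise ValueError(
                    f"flag(s) {sorted(clash)} conflict with config-file values; "
                    "set each key in exactly one place"
                )
            merged.update({k: v for k, v in overrides.items() if v is not None})
        return cls(merged)

    def __getitem__(self, key: str):
        return self.values[key]

    def require(self, *keys: str) -> None:
        missing = [k for k in keys if self.values.get(k) is None]
        if missing:
            raise ValueError(f"config is missing required key(s): {missing}")


@dataclass
class RunReport:
    """Per-stage counts, statistical summaries, and artifact paths."""

    sections: dict = field(default_factory=dict)

    def check_identities(self) -> None:
        de = self.sections.get("differential_expression", {})
        if de and de["up"] + de["down"] != de["significant"]:
            raise ValueError("report inconsistency: up + down != significant")
        tc = self.sections.get("classification", {})
        if tc and tc["IC"] + tc["PC"] + tc["NC"] != tc["total"]:
            raise ValueError("report inconsistency: class counts do not sum to total")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.sections, indent=2, sort_keys=True) + "\n")


def _read_groups(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        sample, group = line.split("\t")
        out[sample] = group
    return out


def make_synthetic(config_path: str | Path, out_dir: str | Path | None = None):
    """Generate a ground-truthed workspace from the config's generator section.

    Also writes ``pipeline_config.yaml`` inside the workspace, pointing the
    analysis stages at the generated files, so the workspace is immediately
    runnable.
    """
    cfg = RunConfig.load(config_path)
    gen = dict(cfg["generator"] or {})
    if "seed" not in gen:
        if cfg.values.get("seed") is None:
            raise ValueError("generator seed missing (set generator.seed or seed)")
        gen["seed"] = cfg.values["seed"]
    if "mirna_fc_range" in gen:
        gen["mirna_fc_range"] = tuple(gen["mirna_fc_range"])
    gcfg = synthetic.GeneratorConfig(**gen)
    target = Path(out_dir or cfg.values.get("output_dir") or ".")
    bundle = synthetic.generate_bundle(gcfg, target)

    run_cfg = {
        "mrna_expression": str(bundle.paths["mrna_expression"]),
        "mrna_present": str(bundle.paths["mrna_present"]),
        "mrna_groups": str(bundle.paths["mrna_groups"]),
        "mirna_expression": str(bundle.paths["mirna_expression"]),
        "mirna_present": str(bundle.paths["mirna_present"]),
        "mirna_groups": str(bundle.paths["mirna_groups"]),
        "predictions": str(bundle.paths["predictions"]),
        "regulons": str(bundle.paths["regulons"]),
        "go_candidates": str(bundle.paths["go_candidates"]),
        "conserved_mirnas": str(bundle.paths["conserved"]),
        "output_dir": str(target / "results"),
        "seed": int(gcfg.seed),
    }
    with open(target / "pipeline_config.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return bundle


@dataclass
class PipelineResult:
    """In-memory results of a full run (also serialized to output_dir)."""

    report: RunReport
    de_mrna: diffexpr.DETable
    de_mirna: diffexpr.DETable
    selected_mirnas: GeneList
    predictions: io_formats.TargetPredictionTable
    classification: target_class.TargetClassification
    repressor_selection: repressors.RepressorSelection
    transfac: repressors.TransfacPairs
    correlation: repressors.CorrelationRegulon
    network: TomNetwork
    strata: dict[str, stratification.StratifiedSummary]
    enrichment: dict[str, stratification.EnrichmentResult]


def run_pipeline(config: str | Path | RunConfig) -> PipelineResult:
    """Execute all stages and write artifacts + report to output_dir."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.load(config)
    cfg.require(*_REQUIRED_RUN_KEYS, "seed")
    for key in _REQUIRED_RUN_KEYS:
        if key == "output_dir":
            continue
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"input {key!r} not found at {cfg[key]}")
    for key in ("mrna_present", "mirna_present"):
        if cfg.values.get(key) is not None and not Path(cfg[key]).exists():
            raise FileNotFoundError(f"input {key!r} not found at {cfg[key]}")

    seed = int(cfg["seed"])
    report = RunReport()
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Timer()

    with stage("diffexpr_mrna"):
        mrna = read_expression_matrix(
            cfg["mrna_expression"],
            _read_groups(cfg["mrna_groups"]),
            scale="log2",
            present_path=cfg.values.get("mrna_present"),
            normalize_features=True,
        )
        mrna_f, mrna_report = diffexpr.present_filter(
            mrna, cfg["present_fraction_mrna"], strict=True
        )
        de_mrna = diffexpr.differential_expression(
            mrna_f,
            n_permutations=int(cfg["n_permutations"]),
            fdr_threshold=float(cfg["fdr_threshold"]),
            seed=seed,
            null=cfg["permutation_null"],
        )
        report.sections["differential_expression"] = {
            **mrna_report.stages,
            "significant": int(len(de_mrna.degs())),
            "up": int(len(de_mrna.up())),
            "down": int(len(de_mrna.down())),
        }

    with stage("diffexpr_mirna"):
        mirna = read_expression_matrix(
            cfg["mirna_expression"],
            _read_groups(cfg["mirna_groups"]),
            scale="log2",
            present_path=cfg.values.get("mirna_present"),
        )
        mirna_f, mirna_report = diffexpr.present_filter(
            mirna, cfg["present_fraction_mirna"], strict=False
        )
        de_mirna = diffexpr.differential_expression(
            mirna_f,
            n_permutations=int(cfg["n_permutations"]),
            fdr_threshold=float(cfg["fdr_threshold"]),
            seed=seed + 1,
            null=cfg["mirna_test"],
        )
        conserved = read_gene_list(cfg["conserved_mirnas"], normalize=False)
        selected, sel_report = diffexpr.select_mirnas(
            de_mirna,
            conserved,
            fc_min=float(cfg["mirna_fc_min"]),
            p_max=float(cfg["mirna_p_max"]),
        )
        report.sections["mirna_selection"] = {
            **mirna_report.stages,
            **{k: v for k, v in sel_report.stages.items() if k != "input"},
        }

    with stage("target_classification"):
        predictions = read_target_predictions(
            cfg["predictions"],
            score_cutoff=float(cfg["score_cutoff"]),
            mirna_col=cfg["prediction_mirna_col"],
            gene_col=cfg["prediction_gene_col"],
            score_col=cfg["prediction_score_col"],
        )
        classification = target_class.classify_targets(predictions, de_mrna, selected)
        report.sections["classification"] = target_class.summarize_classification(
            classification
        )
        rp_frame, rp_mean, rp_background = target_class.repressive_potential(
            predictions, de_mrna, selected
        )
        report.sections["repressive_potential"] = {
            "mean_frac_down": round(rp_mean, 4),
            "background_frac_down": round(rp_background, 4),
            "n_mirnas": int(len(rp_frame)),
        }

    with stage("repressors"):
        go_list = read_gene_list(cfg["go_candidates"])
        mirna_targets = predictions.genes_of(set(selected)) & set(de_mrna.features)
        selection = repressors.select_repressors(go_list, de_mrna, mirna_targets)
        regulon_table = read_gmt(cfg["regulons"])
        transfac = repressors.transfac_pairs(
            regulon_table, selection.genes, de_mrna, mirna_targets
        )
        candidates = set(de_mrna.degs()) & mirna_targets
        correlation = repressors.infer_correlation_regulon(
            mrna_f, selection.genes, candidates, r_threshold=float(cfg["r_threshold"])
        )
        report.sections["repressors"] = {
            "go_candidates": selection.candidate_count,
            "downregulated": selection.downregulated_count,
            "mirna_targeted": selection.mirna_targeted_count,
            "transfac_active": len(transfac.active_repressors),
            "transfac_edges": len(transfac.edges),
            "mutual_targets": len(transfac.mutual_targets),
            "correlation_edges": int(len(correlation.edges)),
            "correlation_targets": int(len(correlation.regulons.all_targets())),
            "correlation_non_targets": len(correlation.non_targets),
        }

    with stage("tom_network"):
        mirna_edges = EdgeSet()
        sub = predictions.restrict(set(selected))
        measured = set(de_mrna.features)
        for _, row in sub.table.iterrows():
            if row["gene"] in measured:
                mirna_edges.add(row["mirna"], REL_MIRNA, row["gene"])
        network = build_tom_network(
            mirna_edges,
            transfac.edges,
            classification,
            repressor_only_edges=transfac.repressor_only_edges,
        )
        corr_edges = EdgeSet()
        for rep, members in correlation.regulons.items():
            for g in members:
                corr_edges.add(rep, io_formats.REL_REPRESSES, g)
        network_corr = build_tom_network(mirna_edges, corr_edges, classification)
        report.sections["network"] = {
            "mutual_targets_transfac": len(network.mutual_targets),
            "repressor_only_transfac": len(network.repressor_only),
            "mutual_targets_correlation": len(network_corr.mutual_targets),
        }

    with stage("stratification"):
        # "PC" for binning is simply "upregulated": identical to the class
        # label on classified genes, and defined for repressor-only genes too
        pc_genes = set(de_mrna.up())
        counts = classification.frame["n_mirnas"]
        bin_edges = tuple(int(x) for x in cfg["mirna_bin_edges"])
        rep_edges_cfg = tuple(int(x) for x in cfg["repressor_bin_edges"])
        sided = cfg["trend_sided"]
        strata: dict[str, stratification.StratifiedSummary] = {}

        motif_genes = sorted(network.mutual_targets | network.repressor_only)
        strata["mutual_transfac"] = stratification.trend_of(
            stratification.bin_by_mirna_count(
                motif_genes,
                counts,
                pc_genes,
                bin_edges=bin_edges,
                repressor_only_group=network.repressor_only,
                max_count=len(selected) if len(selected) else None,
            ),
            sided=sided,
        )

        # global analysis: every DEG, untargeted genes in their own zero bin
        degs = sorted(de_mrna.degs())
        strata["global_degs"] = stratification.trend_of(
            stratification.bin_by_mirna_count(
                degs, counts, pc_genes, bin_edges=bin_edges
            ),
            sided=sided,
        )

        rep_counts = pd.Series(
            {g: len(network.records[g].repressors) for g in network.mutual_targets}
        )
        multiplicity = stratification.repressor_multiplicity_split(
            sorted(network.mutual_targets),
            counts,
            rep_counts,
            pc_genes,
            split_edges=rep_edges_cfg,
            mirna_bin_edges=bin_edges,
            sided=sided,
        )
        for label, summary in multiplicity.items():
            strata[f"multiplicity_{label}"] = summary

        corr_rep_counts = pd.Series(
            {g: len(network_corr.records[g].repressors) for g in network_corr.mutual_targets}
        )
        if len(network_corr.mutual_targets):
            corr_mult = stratification.repressor_multiplicity_split(
                sorted(network_corr.mutual_targets),
                counts,
                corr_rep_counts,
                pc_genes,
                split_edges=rep_edges_cfg,
                mirna_bin_edges=bin_edges,
                sided=sided,
            )
            for label, summary in corr_mult.items():
                strata[f"correlation_multiplicity_{label}"] = summary

        report.sections["trends"] = {
            name: {
                "x2": None if s.x2_trend is None else round(s.x2_trend, 4),
                "p": None if s.p_trend is None else float(f"{s.p_trend:.6g}"),
                "n_genes": s.total_genes,
            }
            for name, s in strata.items()
        }

    with stage("enrichment"):
        degs_set = set(de_mrna.degs())
        down = set(de_mrna.down())
        up = set(de_mrna.up())
        targets_in_degs = predictions.genes_of(set(selected)) & degs_set
        e_mirna = stratification.test_enrichment(
            N=len(degs_set),
            K=len(down),
            n=len(targets_in_degs),
            k=len(targets_in_degs & down),
        )
        covered = correlation.regulons.all_targets()
        universe = covered | correlation.non_targets
        e_rep = stratification.test_enrichment(
            N=len(universe),
            K=len(universe & up),
            n=len(covered),
            k=len(covered & up),
        )
        enrichment = {"mirna_targets_down": e_mirna, "repressor_targets_up": e_rep}
        report.sections["enrichment"] = {
            name: {
                "N": e.N,
                "K": e.K,
                "n": e.n,
                "k": e.k,
                "log10_p_upper": round(e.log10_p_upper, 4),
            }
            for name, e in enrichment.items()
        }

    report.check_identities()

    # ----- all stages succeeded: write artifacts ---------------------------
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    de_mrna.to_tsv(out / "de_mrna.tsv")
    de_mirna.to_tsv(out / "de_mirna.tsv")
    classification.to_tsv(out / "classification.tsv")
    rp_frame.to_csv(out / "repressive_potential.tsv", sep="\t", float_format="%.4f")
    io_formats.write_gene_list(selection.genes, out / "repressors.txt")
    write_network_sif(mirna_edges, out / "mirna_edges.sif")
    write_network_sif(transfac.edges, out / "transfac_edges.sif")
    write_network_sif(transfac.repressor_only_edges, out / "repressor_only_edges.sif")
    write_network_sif(corr_edges, out / "correlation_edges.sif")
    correlation.edges.to_csv(
        out / "correlation_pairs.tsv", sep="\t", index=False, float_format="%.6g"
    )
    records_frame(network).to_csv(out / "ffl_records.tsv", sep="\t", index=False)
    for name, s in strata.items():
        s.to_tsv(out / f"strata_{name}.tsv")
    report.to_json(out / "report.json")
    Path(out / "timings.json").write_text(json.dumps(timings, indent=2) + "\n")

    return PipelineResult(
        report=report,
        de_mrna=de_mrna,
        de_mirna=de_mirna,
        selected_mirnas=selected,
        predictions=predictions,
        classification=classification,
        repressor_selection=selection,
        transfac=transfac,
        correlation=correlation,
        network=network,
        strata=strata,
        enrichment=enrichment,
    )


def load_network(run_dir: str | Path) -> TomNetwork:
    """Rebuild the binding-site-layer network from run artifacts."""
    run_dir = Path(run_dir)
    mirna_edges = read_network_sif(run_dir / "mirna_edges.sif")
    rep_edges = read_network_sif(run_dir / "transfac_edges.sif")
    ro_path = run_dir / "repressor_only_edges.sif"
    ro_edges = read_network_sif(ro_path) if ro_path.exists() else None
    cls_frame = pd.read_csv(run_dir / "classification.tsv", sep="\t", index_col="gene")
    classification = target_class.TargetClassification(cls_frame)
    return build_tom_network(
        mirna_edges, rep_edges, classification, repressor_only_edges=ro_edges
    )
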