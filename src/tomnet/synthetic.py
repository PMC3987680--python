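"""Ground-truthed synthetic input bundles with planted override structure.

The generator emulates the statistical structure the override analysis
assumes, scaled to desk size:

* a two-condition miRNA matrix (3 + 3 samples) with 31 planted upregulated
  miRNAs whose linear fold changes span roughly 7–120 (safely above the
  strict fc > 6 selection rule, so the planted set is recoverable), plus
  null, non-conserved, non-human, and low-expression decoy miRNAs;
* a two-condition mRNA matrix (10 + 10 samples) whose gene-level expected
  log2 shift is additive in the two opposing forces:
  ``delta_g = sum(gamma per repressor edge) - beta_mir * (#targeting
  upregulated miRNAs) + eps`` — repression strength grows with miRNA count
  while derepression grows with repressor count, so inversely-correlated,
  masked, and overridden targets all arise as the two strengths trade off;
* repressors that are themselves miRNA targets with net negative shift;
* a latent-activity model in which each regulon gene shares its coupled
  repressor's per-sample activity with opposite loading, so true
  repressor–target pairs are strongly anti-correlated across the normal
  samples while decoy pairs are uncorrelated;
* a mirSVR-style prediction table (true edges strictly below the -0.2
  cutoff; decoys at and above it; duplicated rows to exercise collapsing),
  a TRANSFAC-style GMT regulon file (with a planted self-loop and an
  unparseable set name), a GO-style repressor candidate list with decoys,
  and a conserved-miRNA list.

Every file re-parses to exactly the truth tables carried in the returned
:class:`TruthBundle`, and identical config + seed reproduces the bundle
byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CANCER, NORMAL

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Knobs of the generative model (all log2-scale where applicable).

    Defaults mirror the study design: 10 + 10 mRNA samples, 3 + 3 miRNA
    samples, 31 upregulated miRNAs with fold changes up to ~118.6, and an
    expected DEG split near 38% up / 62% down.
    """

    seed: int
    n_genes: int = 3000
    n_normal: int = 10
    n_cancer: int = 10
    n_normal_mirna: int = 3
    n_cancer_mirna: int = 3
    n_mirnas_up: int = 31
    n_mirnas_null: int = 25
    mirna_fc_range: tuple[float, float] = (7.0, 118.6)
    mirna_mean_targets: float = 6.0  # exponential scale for (count - 1)
    beta_mir: float = 0.35  # log2 repression per targeting upregulated miRNA
    gamma_weak_mean: float = 3.0  # derepression per repressor edge (weak bulk)
    gamma_weak_sd: float = 1.2
    gamma_strong_mean: float = 6.0  # heavy-tailed component: override survivors
    gamma_strong_tail: float = 1.0  # exponential tail scale of the strong part
    strong_frac: float = 0.2  # fraction of regulon genes with strong override
    n_repressors: int = 10
    frac_regulon_genes: float = 0.20
    frac_plain_targets: float = 0.13
    frac_background_up: float = 0.01
    frac_background_down: float = 0.05
    frac_low_expressed: float = 0.06
    noise_sd: float = 0.2
    latent_activity_sd: float = 1.5
    mirna_noise_sd: float = 0.15
    delta_noise_sd: float = 0.15  # eps on the planted shift
    score_cutoff: float = -0.2
    significance_margin: float = 2.0  # margin for expected-class labelling

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_genes", "n_normal", "n_cancer", "n_normal_mirna",
                     "n_cancer_mirna", "n_mirnas_up", "n_repressors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("beta_mir", "gamma_weak_mean", "gamma_strong_mean",
                     "noise_sd", "latent_activity_sd", "delta_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_regulon = int(round(self.frac_regulon_genes * self.n_genes))
        if self.n_repressors > n_regulon or self.n_repressors >= self.n_genes:
            raise ValueError("infeasible config: more repressors than regulon genes")


@dataclass
class TruthBundle:
    """Everything the generator planted, plus the files it wrote."""

    config: GeneratorConfig
    gene_truth: pd.DataFrame  # gene, block, delta, m_selected, n_repressors, expected_class
    mirna_truth: pd.DataFrame  # mirna, planted_log2fc, selected, conserved
    prediction_edges: pd.DataFrame  # all (mirna, gene, score) rows below cutoff
    regulons: dict[str, set[str]]  # true repressor -> regulon members
    coupling: list[tuple[str, str]]  # (repressor, gene) latent-coupled pairs
    go_candidates: list[str]
    conserved_mirnas: list[str]
    selected_mirnas: list[str]
    repressors: list[str]
    paths: dict[str, Path] = field(default_factory=dict)

    def expected_counts(self) -> dict[str, int]:
        cls = self.gene_truth["expected_class"].value_counts()
        return {k: int(cls.get(k, 0)) for k in ("IC", "PC", "NC")}


def expected_class(delta, significance_margin: float = 1.0):
    """Truth label from a planted shift: PC above the margin, IC below
    its negation, NC inside the band.  Accepts scalars or arrays."""
    if significance_margin < 0:
        raise ValueError("margin must be >= 0")
    d = np.asarray(delta, dtype=float)
    out = np.where(d > significance_margin, "PC", np.where(d < -significance_margin, "IC", "NC"))
    if out.ndim == 0:
        return str(out)
    return out


def _mirna_count(rng: np.random.Generator, scale: float, cap: int) -> int:
    return 1 + min(int(rng.exponential(scale)), cap - 1)


def generate_bundle(cfg: GeneratorConfig, out_dir: str | Path) -> TruthBundle:
    """Write a complete, ready-to-run input bundle and return its truth."""
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)

    # ----- block sizes ----------------------------------------------------
    n = cfg.n_genes
    n_rep = cfg.n_repressors
    n_regulon = int(round(cfg.frac_regulon_genes * n))
    n_plain = int(round(cfg.frac_plain_targets * n))
    n_bg_up = max(2, int(round(cfg.frac_background_up * n)))
    n_bg_down = max(2, int(round(cfg.frac_background_down * n)))
    n_decoy = max(8, int(round(0.01 * n)))
    n_low = int(round(cfg.frac_low_expressed * n))
    used = n_rep + n_decoy + n_regulon + n_plain + n_bg_up + n_bg_down + n_low
    if used >= n:
        raise ValueError("infeasible config: blocks exceed n_genes")
    n_null = n - used

    repressors = [f"REP{i + 1:02d}" for i in range(n_rep)]
    decoys = [f"GODEC{i + 1:02d}" for i in range(n_decoy)]
    regulon_genes = [f"RT{i + 1:04d}" for i in range(n_regulon)]
    plain_targets = [f"TG{i + 1:04d}" for i in range(n_plain)]
    background_up = [f"BG{i + 1:03d}" for i in range(n_bg_up)]
    background_down = [f"BD{i + 1:03d}" for i in range(n_bg_down)]
    null_genes = [f"NU{i + 1:04d}" for i in range(n_null)]
    low_genes = [f"LO{i + 1:03d}" for i in range(n_low)]
    all_genes = (
        repressors + decoys + regulon_genes + plain_targets
        + background_up + background_down + null_genes + low_genes
    )

    # ----- miRNA identities ----------------------------------------------
    selected_mirnas = [f"hsa-miR-T{i + 1:02d}" for i in range(cfg.n_mirnas_up)]
    null_mirnas = [f"hsa-miR-N{i + 1:02d}" for i in range(cfg.n_mirnas_null)]
    noncons_mirnas = ["hsa-miR-U01", "hsa-miR-U02"]  # up but not conserved
    nonhuman_mirnas = ["mmu-miR-X01", "mmu-miR-X02"]  # up but not human
    low_mirnas = [f"hsa-miR-L{i + 1:02d}" for i in range(5)]  # absent calls
    all_mirnas = selected_mirnas + null_mirnas + noncons_mirnas + nonhuman_mirnas + low_mirnas
    conserved = selected_mirnas + null_mirnas + nonhuman_mirnas

    # ----- miRNA -> gene targeting (the selected 31 only drive delta) -----
    cap = cfg.n_mirnas_up
    m_count: dict[str, int] = {g: 0 for g in all_genes}
    gene_mirnas: dict[str, list[str]] = {g: [] for g in all_genes}
    for g in repressors:
        m_count[g] = int(rng.integers(8, 17))
    targeted_regulon = rng.choice(n_regulon, size=int(round(0.8 * n_regulon)), replace=False)
    for j in sorted(targeted_regulon):
        m_count[regulon_genes[j]] = _mirna_count(rng, cfg.mirna_mean_targets, cap)
    for g in plain_targets:
        m_count[g] = _mirna_count(rng, cfg.mirna_mean_targets, cap)
    for g in all_genes:
        if m_count[g]:
            picks = rng.choice(cfg.n_mirnas_up, size=m_count[g], replace=False)
            gene_mirnas[g] = [selected_mirnas[i] for i in sorted(picks)]

    # ----- regulon membership and multiplicity ----------------------------
    n_single = int(round(0.75 * n_regulon))
    n_double = int(round(0.175 * n_regulon))
    rep_assign: dict[str, list[str]] = {}
    for i, g in enumerate(regulon_genes):
        k = 1 if i < n_single else (2 if i < n_single + n_double else 3)
        k = min(k, n_rep)
        picks = rng.choice(n_rep, size=k, replace=False)
        rep_assign[g] = [repressors[j] for j in sorted(picks)]
    regulons: dict[str, set[str]] = {r: set() for r in repressors}
    for g, reps in rep_assign.items():
        for r in reps:
            regulons[r].add(g)
    # latent coupling: each regulon gene shares one repressor's activity
    coupling = [(reps[int(rng.integers(len(reps)))], g) for g, reps in rep_assign.items()]
    coupled_rep = {g: r for r, g in coupling}

    # ----- planted log2 shifts --------------------------------------------
    eps = rng.normal(0.0, cfg.delta_noise_sd, size=len(all_genes))
    strong = rng.random(len(all_genes)) < cfg.strong_frac
    delta: dict[str, float] = {}
    for i, g in enumerate(all_genes):
        d = -cfg.beta_mir * m_count[g] + eps[i]
        if g in rep_assign:
            for _r in rep_assign[g]:
                if strong[i]:
                    d += cfg.gamma_strong_mean + float(rng.exponential(cfg.gamma_strong_tail))
                else:
                    d += max(0.0, rng.normal(cfg.gamma_weak_mean, cfg.gamma_weak_sd))
        delta[g] = d
    for g in decoys[:5]:
        delta[g] = 2.2 + float(rng.normal(0, 0.3))  # up: fails the "down" filter
    for g in decoys[5:8]:
        delta[g] = -2.2 + float(rng.normal(0, 0.3))  # down but not miRNA-targeted
    for g in background_up:
        delta[g] = float(rng.normal(2.2, 0.6))
    for g in background_down:
        delta[g] = float(rng.normal(-2.2, 0.6))
    for g in low_genes:
        delta[g] = 0.0

    # ----- mRNA expression matrix ------------------------------------------
    n_samp = cfg.n_normal + cfg.n_cancer
    samples = [f"OSE_{i + 1:02d}" for i in range(cfg.n_normal)] + [
        f"CEPI_{i + 1:02d}" for i in range(cfg.n_cancer)
    ]
    is_cancer = np.array([0] * cfg.n_normal + [1] * cfg.n_cancer)

    base = {}
    for g in all_genes:
        base[g] = max(7.0, float(rng.normal(8.5, 0.8)))
    for g in null_genes:
        base[g] = float(rng.normal(6.5, 1.0))
    for g in low_genes:
        base[g] = float(rng.normal(3.5, 0.6))

    latent = {r: rng.normal(0.0, cfg.latent_activity_sd, size=n_samp) for r in repressors}
    values = np.empty((len(all_genes), n_samp))
    for i, g in enumerate(all_genes):
        row = base[g] + delta[g] * is_cancer + rng.normal(0, cfg.noise_sd, size=n_samp)
        if g in repressors:
            row = row + latent[g]
        elif g in coupled_rep:
            row = row - latent[coupled_rep[g]]
        values[i] = row
    mrna = pd.DataFrame(values, index=all_genes, columns=samples)

    def present_probs(means: np.ndarray) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-(means - 5.0) / 0.7))
        return np.where(means >= 7.0, 1.0, p)

    gene_means = np.array([base[g] for g in all_genes])
    pres_p = present_probs(gene_means)
    mrna_present = pd.DataFrame(
        rng.random((len(all_genes), n_samp)) < pres_p[:, None],
        index=all_genes,
        columns=samples,
    )

    # ----- miRNA expression matrix -----------------------------------------
    m_samp = cfg.n_normal_mirna + cfg.n_cancer_mirna
    m_samples = [f"mOSE_{i + 1}" for i in range(cfg.n_normal_mirna)] + [
        f"mCEPI_{i + 1}" for i in range(cfg.n_cancer_mirna)
    ]
    m_cancer = np.array([0] * cfg.n_normal_mirna + [1] * cfg.n_cancer_mirna)
    lo, hi = cfg.mirna_fc_range
    log_fc = {}
    for m in all_mirnas:
        if m in selected_mirnas or m in noncons_mirnas or m in nonhuman_mirnas:
            log_fc[m] = float(np.log2(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        else:
            log_fc[m] = 0.0
    m_base = {m: max(7.0, float(rng.normal(8.5, 0.8))) for m in all_mirnas}
    for m in low_mirnas:
        m_base[m] = float(rng.normal(3.5, 0.6))
    m_values = np.empty((len(all_mirnas), m_samp))
    for i, m in enumerate(all_mirnas):
        m_values[i] = (
            m_base[m] + log_fc[m] * m_cancer + rng.normal(0, cfg.mirna_noise_sd, size=m_samp)
        )
    mirna = pd.DataFrame(m_values, index=all_mirnas, columns=m_samples)
    m_means = np.array([m_base[m] for m in all_mirnas])
    mirna_present = pd.DataFrame(
        rng.random((len(all_mirnas), m_samp)) < present_probs(m_means)[:, None],
        index=all_mirnas,
        columns=m_samples,
    )

    # ----- prediction table -------------------------------------------------
    rows: list[tuple[str, str, float]] = []
    for g in all_genes:
        for m in gene_mirnas[g]:
            rows.append((m, g, float(rng.uniform(-1.0, -0.25))))
    # below-cutoff edges for unselected miRNAs (ignored downstream by design)
    for m in null_mirnas:
        for j in rng.choice(len(null_genes), size=10, replace=False):
            rows.append((m, null_genes[j], float(rng.uniform(-1.0, -0.25))))
    for m in noncons_mirnas + nonhuman_mirnas:
        for j in rng.choice(len(null_genes), size=15, replace=False):
            rows.append((m, null_genes[j], float(rng.uniform(-1.0, -0.25))))
    edges_below = pd.DataFrame(rows, columns=["mirna", "gene", "score"])
    extra: list[tuple[str, str, float]] = []
    # duplicated pairs with a weaker (still below-cutoff) score: collapse work
    for i in rng.choice(len(rows), size=min(20, len(rows)), replace=False):
        m, g, s = rows[i]
        extra.append((m, g, min(-0.201, s + 0.02)))
    # decoys at and above the cutoff: must be filtered out
    for _ in range(int(0.2 * n)):
        m = all_mirnas[int(rng.integers(len(all_mirnas)))]
        g = all_genes[int(rng.integers(len(all_genes)))]
        extra.append((m, g, float(rng.uniform(cfg.score_cutoff, 0.4))))
    for i in rng.choice(len(rows), size=5, replace=False):
        m, g, _s = rows[i]
        extra.append((m, g, cfg.score_cutoff))  # exactly at the strict boundary
    written = pd.concat(
        [edges_below, pd.DataFrame(extra, columns=["mirna", "gene", "score"])],
        ignore_index=True,
    )
    written = written.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    truth_edges = (
        edges_below.groupby(["mirna", "gene"], as_index=False)["score"].min().sort_values(
            ["mirna", "gene"]
        ).reset_index(drop=True)
    )

    # ----- truth tables ------------------------------------------------------
    blocks = (
        [("repressor", g) for g in repressors]
        + [("go_decoy", g) for g in decoys]
        + [("regulon", g) for g in regulon_genes]
        + [("plain_target", g) for g in plain_targets]
        + [("background_up", g) for g in background_up]
        + [("background_down", g) for g in background_down]
        + [("null", g) for g in null_genes]
        + [("low_expressed", g) for g in low_genes]
    )
    block_of = {g: b for b, g in blocks}
    gene_truth = pd.DataFrame(
        {
            "gene": all_genes,
            "block": [block_of[g] for g in all_genes],
            "delta": [delta[g] for g in all_genes],
            "m_selected": [m_count[g] for g in all_genes],
            "n_repressors": [len(rep_assign.get(g, [])) for g in all_genes],
        }
    )
    gene_truth["expected_class"] = expected_class(
        gene_truth["delta"].to_numpy(), cfg.significance_margin
    )
    mirna_truth = pd.DataFrame(
        {
            "mirna": all_mirnas,
            "planted_log2fc": [log_fc[m] for m in all_mirnas],
            "selected": [m in set(selected_mirnas) for m in all_mirnas],
            "conserved": [m in set(conserved) for m in all_mirnas],
        }
    )
    go_candidates = repressors + decoys

    # ----- write files --------------------------------------------------------
    paths = {
        "mrna_expression": out_dir / "mrna_expression.tsv",
        "mrna_present": out_dir / "mrna_present.tsv",
        "mrna_groups": out_dir / "mrna_groups.tsv",
        "mirna_expression": out_dir / "mirna_expression.tsv",
        "mirna_present": out_dir / "mirna_present.tsv",
        "mirna_groups": out_dir / "mirna_groups.tsv",
        "predictions": out_dir / "predictions.tsv",
        "regulons": out_dir / "regulons.gmt",
        "go_candidates": out_dir / "repressor_candidates.txt",
        "conserved": out_dir / "conserved_mirnas.txt",
        "gene_truth": truth_dir / "gene_truth.tsv",
        "mirna_truth": truth_dir / "mirna_truth.tsv",
        "prediction_edges": truth_dir / "prediction_edges.tsv",
        "coupling": truth_dir / "coupling.tsv",
    }
    mrna.to_csv(paths["mrna_expression"], sep="\t", float_format="%.6f", index_label="gene")
    mrna_present.astype(int).to_csv(paths["mrna_present"], sep="\t", index_label="gene")
    with open(paths["mrna_groups"], "w") as fh:
        for s, c in zip(samples, is_cancer):
            fh.write(f"{s}\t{CANCER if c else NORMAL}\n")
    mirna.to_csv(paths["mirna_expression"], sep="\t", float_format="%.6f", index_label="mirna")
    mirna_present.astype(int).to_csv(paths["mirna_present"], sep="\t", index_label="mirna")
    with open(paths["mirna_groups"], "w") as fh:
        for s, c in zip(m_samples, m_cancer):
            fh.write(f"{s}\t{CANCER if c else NORMAL}\n")
    written.rename(columns={"gene": "gene_symbol", "score": "mirsvr_score"}).to_csv(
        paths["predictions"], sep="\t", index=False, float_format="%.4f"
    )
    _write_gmt_with_decoys(paths["regulons"], regulons, null_genes, rng)
    with open(paths["go_candidates"], "w") as fh:
        for g in go_candidates:
            fh.write(f"{g}\tGO:0045892\n")
    with open(paths["conserved"], "w") as fh:
        for m in conserved:
            fh.write(m + "\n")
    gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False, float_format="%.6f")
    mirna_truth.to_csv(paths["mirna_truth"], sep="\t", index=False, float_format="%.6f")
    truth_edges.rename(columns={"gene": "gene_symbol", "score": "mirsvr_score"}).to_csv(
        paths["prediction_edges"], sep="\t", index=False, float_format="%.4f"
    )
    with open(paths["coupling"], "w") as fh:
        fh.write("repressor\tgene\n")
        for r, g in sorted(coupling, key=lambda x: (x[0], x[1])):
            fh.write(f"{r}\t{g}\n")

    return TruthBundle(
        config=cfg,
        gene_truth=gene_truth.set_index("gene", drop=False),
        mirna_truth=mirna_truth.set_index("mirna", drop=False),
        prediction_edges=truth_edges,
        regulons=regulons,
        coupling=coupling,
        go_candidates=go_candidates,
        conserved_mirnas=conserved,
        selected_mirnas=selected_mirnas,
        repressors=repressors,
        paths=paths,
    )


def _write_gmt_with_decoys(
    path: Path,
    regulons: dict[str, set[str]],
    decoy_pool: list[str],
    rng: np.random.Generator,
) -> None:
    """True regulons plus parsing hazards: a self-loop member on the first
    set, two decoy TF sets, and one set with an unparseable name."""
    keys = sorted(regulons)
    with open(path, "w") as fh:
        for i, key in enumerate(keys):
            members = sorted(regulons[key])
            if i == 0:
                members = sorted(members + [key])  # self-loop, stripped on read
            fh.write(f"V${key}_01\t{key} targets\t" + "\t".join(members) + "\n")
        for j in range(2):
            tf = decoy_pool[j]
            members = sorted(
                decoy_pool[k] for k in rng.choice(len(decoy_pool), size=8, replace=False)
            )
            fh.write(f"V${tf}_02\tdecoy set\t" + "\t".join(members) + "\n")
        members = sorted(decoy_pool[k] for k in rng.choice(len(decoy_pool), size=5, replace=False))
        fh.write("UNNAMED_MOTIF_SET\tunparseable name\t" + "\t".join(members) + "\n")


def config_to_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["mirna_fc_range"] = list(d["mirna_fc_range"])
    return d
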