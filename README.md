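# tomnet

Transcriptional-override analysis of miRNA/repressor feed-forward networks
in two-condition expression data.

## The problem

MicroRNAs repress their target mRNAs, so when a miRNA rises between two
conditions (say, normal ovarian surface epithelium vs. cancer epithelium),
its targets are expected to fall — an *inversely correlated* (IC) response.
In genome-wide comparisons, however, only ~20–30% of predicted targets
behave that way; many show *no change* (NC) or even rise (*positively
correlated*, PC).

The transcriptional override model explains part of this paradox with a
feed-forward loop.  Some targets of the upregulated miRNAs are themselves
transcriptional **repressors**.  When a miRNA knocks a repressor down, the
repressor's own target genes are *derepressed* — their transcription rises.
A gene sitting at the sharp end of both arrows

```
miRNA ──┬──────────────────⊣ target gene
        └──⊣ repressor ──⊣──────┘
```

feels two opposing forces: direct miRNA repression and indirect
derepression.  Depending on their relative strengths, the gene's observed
response is IC (repression wins), NC (forces cancel — masking), or PC
(derepression wins — override).

`tomnet` implements the full analysis as a library: differential
expression of genes and miRNAs, IC/PC/NC target classification,
repressor selection (GO candidates ∩ downregulated ∩ miRNA-targeted),
feed-forward network assembly from binding-site (TRANSFAC-style GMT) or
co-expression regulons, degree-stratified trend tests, and gene-set
enrichment.  A ground-truthed synthetic-data generator makes every stage
verifiable without external data.

## Core statistics

* **Signed fold change** — for log2 group means, `d = mean_cancer −
  mean_normal` maps to `2^d` (up) or `−2^(−d)` (down), so `|fc| ≥ 1`.
* **Differential expression** — two-sample t statistic with a variance
  floor, compared against a group-label permutation null (pooled across
  features) or Student-t tails for very small designs; Benjamini–Hochberg
  FDR (default threshold 0.055).
* **Directional correlation significance** — one-sided p for negative
  Pearson correlation via `t = r·√(n−2)/√(1−r²)`, `t ~ t(n−2)`; for
  `r = −0.8, n = 10` this gives p ≈ 0.0027, the criterion behind the
  `r < −0.8` co-expression regulon rule.
* **Cochran–Armitage trend test** — 1-df chi-square for a monotone trend
  in per-bin PC proportions, algebraically `N·r²` with `r` the
  point-biserial correlation of bin score with the binary outcome.
* **Hypergeometric enrichment** — upper-tail overlap probability
  `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`, evaluated in log space so
  values far below the smallest positive double remain exact.

## Worked example

`examples/02_synthetic_workspace_and_pipeline.py` generates a synthetic
workspace (seed 42) with 31 planted upregulated miRNAs and 10 planted
repressors, runs the full pipeline, and prints:

```
planted: 31 upregulated miRNAs, 10 repressors
DEGs: 1434 of 2663 present genes (637 up / 797 down)
selected miRNAs recovered: True
repressors recovered: True
classification: {'total': 880, 'IC': 443, 'IC_pct': 50, 'PC': 320, 'PC_pct': 36, 'NC': 117, 'NC_pct': 13}
percent-PC by miRNA-count bin (mutual targets):
   repressor-only: 100.0%  (n = 107)
              1-5: 100.0%  (n = 243)
             6-10:  86.8%  (n = 68)
            11-15:  58.3%  (n = 24)
            16-31:  10.8%  (n = 37)
trend: X2 = 238.0, p = 1.08e-53
```

Reading the output: the pipeline recovers exactly the planted miRNA and
repressor sets from the written files; among genes regulated by both a
downregulated repressor and upregulated miRNAs, the fraction that still
manages to *rise* (percent-PC) falls monotonically as the number of
targeting miRNAs grows — the override signature — and the trend test is
decisive.  The other examples show the enrichment/trend statistics on
printed inputs, a single-gene feed-forward query (the ZNF24→VEGFA-style
motif), and co-expression regulon recovery (precision 0.984, recall 1.000
at `r < −0.8`).

The same pipeline is scriptable from a shell:

```bash
tomnet simulate -c generate.yaml        # write a ground-truthed workspace
tomnet run -c workspace/pipeline_config.yaml
tomnet query-gene -r workspace/results RT0123
tomnet export-network -r workspace/results -o network.sif
```

## Layout

```
src/tomnet/
  io_formats.py      # TSV/GMT/SIF/gene-list readers and writers
  diffexpr.py        # present filter, permutation DE, miRNA selection
  target_class.py    # IC/PC/NC classification, repressive potential
  repressors.py      # repressor selection, TRANSFAC pairs, correlation regulons
  tom_network.py     # feed-forward loop assembly and per-gene queries
  stratification.py  # binning, trend test, hypergeometric enrichment
  synthetic.py       # ground-truthed synthetic bundle generator
  pipeline.py        # config-driven orchestration
  cli.py             # thin click CLI (simulate / run / query-gene / export-network)
examples/            # narrative scripts, one per capability
docs/methods.md      # model, assumptions, parameter choices, limitations
```
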