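"""Generate a ground-truthed synthetic workspace and run the full pipeline.

The generator plants 31 upregulated miRNAs, 10 downregulated repressors
with regulons, and gene-level shifts that trade miRNA repression against
repressor-mediated derepression; the pipeline then recovers the planted
structure from the written files alone.
"""

import tempfile
from pathlib import Path

import yaml

from tomnet.pipeline import make_synthetic, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg_path = Path(tmp) / "generate.yaml"
    cfg_path.write_text(
        yaml.safe_dump({"generator": {"seed": 42}, "output_dir": f"{tmp}/workspace"})
    )
    bundle = make_synthetic(cfg_path)
    print(f"planted: {len(bundle.selected_mirnas)} upregulated miRNAs, "
          f"{len(bundle.repressors)} repressors")

    result = run_pipeline(f"{tmp}/workspace/pipeline_config.yaml")
    de = result.report.sections["differential_expression"]
    print(f"DEGs: {de['significant']} of {de['present']} present genes "
          f"({de['up']} up / {de['down']} down)")
    print(f"selected miRNAs recovered: "
          f"{sorted(result.selected_mirnas.symbols) == sorted(bundle.selected_mirnas)}")
    print(f"repressors recovered: "
          f"{sorted(result.repressor_selection.genes.symbols) == sorted(bundle.repressors)}")
    print(f"classification: {result.report.sections['classification']}")

    summary = result.strata["mutual_transfac"]
    print("percent-PC by miRNA-count bin (mutual targets):")
    for _, row in summary.populated().iterrows():
        print(f"  {row['label']:>15}: {row['percent_pc']:5.1f}%  (n = {row['n_genes']})")
    print(f"trend: X2 = {summary.x2_trend:.1f}, p = {summary.p_trend:.2e}")
    print("  -> the planted override gradient is recovered: fewer PC genes "
          "as miRNA pressure rises")
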