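"""Shared fixtures: one default synthetic bundle + one full pipeline run.

Both are session-scoped — the bundle is the generator's default study
conditions (seed 42) and most truth-recovery tests interrogate the same
run rather than regenerating it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import yaml
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from tomnet.pipeline import RunConfig, run_pipeline
from tomnet.synthetic import GeneratorConfig, TruthBundle, generate_bundle

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> TruthBundle:
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(GeneratorConfig(seed=DEFAULT_SEED), out)


@pytest.fixture(scope="session")
def run_config(bundle) -> RunConfig:
    paths = bundle.paths
    values = {
        "mrna_expression": str(paths["mrna_expression"]),
        "mrna_present": str(paths["mrna_present"]),
        "mrna_groups": str(paths["mrna_groups"]),
        "mirna_expression": str(paths["mirna_expression"]),
        "mirna_present": str(paths["mirna_present"]),
        "mirna_groups": str(paths["mirna_groups"]),
        "predictions": str(paths["predictions"]),
        "regulons": str(paths["regulons"]),
        "go_candidates": str(paths["go_candidates"]),
        "conserved_mirnas": str(paths["conserved"]),
        "output_dir": str(paths["mrna_expression"].parent / "results"),
        "seed": DEFAULT_SEED,
    }
    cfg_path = paths["mrna_expression"].parent / "test_run_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(values, fh)
    return RunConfig.load(cfg_path)


@pytest.fixture(scope="session")
def pipeline_result(run_config):
    return run_pipeline(run_config)
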