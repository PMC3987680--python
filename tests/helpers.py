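"""Small in-memory builders shared across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from tomnet.io_formats import ExpressionMatrix


def make_matrix(
    values: np.ndarray,
    n_normal: int,
    n_cancer: int,
    features: list[str] | None = None,
    present: np.ndarray | None = None,
    scale: str = "log2",
    swap_groups: bool = False,
) -> ExpressionMatrix:
    """Small in-memory expression matrix with OSE_/CEPI_-style samples."""
    n_feat, n_samp = values.shape
    assert n_samp == n_normal + n_cancer
    features = features or [f"G{i:04d}" for i in range(n_feat)]
    samples = [f"S{i:02d}" for i in range(n_samp)]
    groups = ["normal"] * n_normal + ["cancer"] * n_cancer
    if swap_groups:
        groups = ["cancer" if g == "normal" else "normal" for g in groups]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=features, columns=samples),
        scale=scale,
        groups=pd.Series(groups, index=samples),
        present=None if present is None else pd.DataFrame(
            present, index=features, columns=samples
        ),
    )
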