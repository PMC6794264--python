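import numpy as np
import pandas as pd
import pytest

from dieltx.matrix import ExpressionMatrix
from dieltx.timeline import Timeline


@pytest.fixture
def drift_timeline() -> Timeline:
    """16 samples at 4-h spacing starting 10:00, late-September dawn/dusk."""
    return Timeline.drift_default()


def make_matrix(counts: np.ndarray, taxa, functions=None, compartments=None,
                labels=None) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from raw arrays."""
    n, m = counts.shape
    idx = pd.Index([f"orf{i}" for i in range(n)], name="orf_id")
    cols = labels if labels is not None else [f"s{j}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "taxon_group": taxa,
            "function_label": functions if functions is not None else [""] * n,
            "compartment": compartments if compartments is not None else ["nuclear"] * n,
        },
        index=idx,
    )
    return ExpressionMatrix(
        counts=pd.DataFrame(np.asarray(counts, float), index=idx, columns=cols),
        meta=meta,
    )


@pytest.fixture
def tiny_matrix(drift_timeline) -> ExpressionMatrix:
    """3 ORFs x 16 samples, two taxon groups."""
    rng = np.random.default_rng(42)
    counts = rng.integers(1, 100, size=(3, 16)).astype(float)
    return make_matrix(
        counts,
        taxa=["diatom", "diatom", "ciliate"],
        labels=drift_timeline.sample_labels,
    )
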