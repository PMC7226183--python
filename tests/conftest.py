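import numpy as np
import pandas as pd
import pytest

import circaweld as cw


@pytest.fixture(scope="session")
def small_truth():
    return cw.simulate_truth(500, frac_rhythmic=0.3, seed=11)


@pytest.fixture(scope="session")
def small_platforms(small_truth):
    intensity = cw.render_intensity(small_truth, seed=12)
    counts = cw.render_counts(small_truth, seed=13)
    return intensity, counts


@pytest.fixture()
def toy_counts():
    """4 genes x 4 samples count matrix with unequal library sizes."""
    values = pd.DataFrame(
        {
            "s1": [100, 200, 300, 400],
            "s2": [200, 400, 600, 800],
            "s3": [150, 250, 350, 450],
            "s4": [90, 210, 310, 390],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    return cw.ExpressionMatrix(
        values,
        pd.Series([0.0, 3.0, 6.0, 9.0], index=values.columns),
        "rnaseq",
        "counts",
    )


def cosine_series(t, mesor, relamp, phase, period=24.0):
    return mesor * (1.0 + relamp * np.cos(2 * np.pi * (t - phase) / period))
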