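import numpy as np
import pandas as pd
import pytest

from necrosig import ClinicalTable, ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, log2 scale, hand-pickable values."""
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array(
            [
                [5.0, 6.0, 1.0, 2.0],
                [2.0, 2.0, 2.0, 2.0],
                [1.0, 3.0, 5.0, 7.0],
            ]
        ),
    )


def make_clinical(n, necrosis=None, pam50=None, er=None, sex=None,
                  time=None, cause=None, pr=None, her2=None):
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "necrosis": necrosis if necrosis is not None else ["absent"] * n,
            "er": er if er is not None else ["positive"] * n,
            "pr": pr if pr is not None else ["positive"] * n,
            "her2": her2 if her2 is not None else ["negative"] * n,
            "pam50": pam50 if pam50 is not None else ["LumA"] * n,
            "tumor_size_mm": [20.0] * n,
            "grade": ["2"] * n,
            "lymph_node": ["negative"] * n,
            "surv_time_months": time if time is not None else [60.0] * n,
            "death_cause": cause if cause is not None else ["alive"] * n,
            "sex": sex if sex is not None else ["female"] * n,
        }
    )
    return ClinicalTable(df)


@pytest.fixture
def clinical_10():
    return make_clinical(10)


def random_matrix(rng, n_genes=5, n_samples=8, loc=7.0, sd=1.0):
    return ExpressionMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
        rng.normal(loc, sd, size=(n_genes, n_samples)),
    )
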