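import numpy as np
import pandas as pd
import pytest

from varens import (
    PredictorRegistry,
    PredictorSpec,
    ScoreTable,
    bundled_model,
    bundled_registry,
)

PREDICTORS = ["SIFT", "PolyPhen-2", "MLb-LDLr", "MutationTaster", "REVEL", "VARITY"]


@pytest.fixture(scope="session")
def registry() -> PredictorRegistry:
    return bundled_registry()


@pytest.fixture(scope="session")
def model():
    return bundled_model()


def make_normalized_table(scores, labels=None, positions=None, predictors=None):
    """Build a normalized ScoreTable from a matrix of scores (NaN = missing)."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    predictors = predictors or PREDICTORS[: scores.shape[1]]
    df = pd.DataFrame(
        {
            "position": positions if positions is not None else range(1, n + 1),
            "ref": ["A"] * n,
            "alt": ["V"] * n,
        }
    )
    if labels is not None:
        df["label"] = list(labels)
    for j, p in enumerate(predictors):
        df[p] = scores[:, j]
    return ScoreTable(df, predictors, "normalized")


@pytest.fixture
def unit_spec() -> PredictorSpec:
    """A direct predictor on [0, 1] with the 0.5 threshold (identity map)."""
    return PredictorSpec(name="unit", encoding="direct", t_s=0.5)
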