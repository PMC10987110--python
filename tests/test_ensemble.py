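"""Uniform and weighted ensemble combination, display scale, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varens import (
    EnsembleModel,
    classify,
    combine_uniform,
    score_optimized,
    to_display_scale,
)
from varens.ensemble import uniform_raw_scores
from tests.conftest import PREDICTORS, make_normalized_table

WEIGHT_SUM = 0.76 + 1.38 + 0.67 + 0.91 + 0.51 + 1.82  # = 6.05


def vec(values):
    return pd.Series(dict(zip(PREDICTORS, values)), dtype=float)


class TestCombineUniform:
    def test_maximum(self):
        c = combine_uniform(vec([1.0] * 6))
        assert c.raw_value == pytest.approx(6.0)
        assert c.call == "pathogenic"

    def test_threshold_is_inclusive(self):
        c = combine_uniform(vec([0.5] * 6))
        assert c.raw_value == pytest.approx(3.0)
        assert c.call == "pathogenic"

    def test_missing_rescale_keeps_range(self):
        values = [1.0] * 6
        values[3] = np.nan  # MutationTaster missing
        c = combine_uniform(vec(values))
        assert c.raw_value == pytest.approx(5 * 6 / 5)  # = 6.0
        assert c.predictors_used == frozenset(p for p in PREDICTORS if p != "MutationTaster")

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            combine_uniform(vec([np.nan] * 6))

    @given(st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6))
    @settings(deadline=None)
    def test_no_missing_equals_plain_sum(self, values):
        c = combine_uniform(vec(values))
        assert c.raw_value == pytest.approx(sum(values))

    @given(
        values=st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6),
        missing=st.sets(st.integers(0, 5), max_size=5),
    )
    @settings(deadline=None)
    def test_rescale_preserves_range(self, values, missing):
        vals = [np.nan if i in missing else v for i, v in enumerate(values)]
        c = combine_uniform(vec(vals))
        assert -1e-9 <= c.raw_value <= 6.0 + 1e-9


class TestScoreOptimized:
    def test_all_zero_is_the_intercept(self, model):
        c = score_optimized(vec([0.0] * 6), model)
        assert c.raw_value == pytest.approx(-3.43)
        assert c.call == "benign"

    def test_all_one_is_intercept_plus_weight_sum(self, model):
        c = score_optimized(vec([1.0] * 6), model)
        assert c.raw_value == pytest.approx(-3.43 + WEIGHT_SUM)
        assert c.raw_value == pytest.approx(2.62)
        assert c.call == "pathogenic"

    def test_missing_predictor_rescale(self, model):
        values = [1.0] * 6
        values[PREDICTORS.index("MutationTaster")] = np.nan
        c = score_optimized(vec(values), model)
        # (6.05 - 0.91) * 6.05/(6.05 - 0.91) - 3.43 = 2.62
        assert c.raw_value == pytest.approx(2.62)

    def test_unknown_predictor_errors(self, model):
        with pytest.raises(ValueError, match="absent from the model"):
            score_optimized(pd.Series({"nonesuch": 0.5}), model)

    def test_zero_remaining_weight_errors(self):
        m = EnsembleModel(weights={"a": 1.0, "b": 0.0}, intercept=-0.5)
        with pytest.raises(ValueError, match="zero"):
            score_optimized(pd.Series({"a": np.nan, "b": 0.7}), m)

    @given(
        low=st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6),
        bump=st.integers(0, 5),
        eps=st.floats(0.0, 0.3),
    )
    @settings(deadline=None)
    def test_monotone_in_every_score(self, model, low, bump, eps):
        high = list(low)
        high[bump] = min(1.0, high[bump] + eps)
        a = score_optimized(vec(low), model).raw_value
        b = score_optimized(vec(high), model).raw_value
        assert b >= a - 1e-12


class TestDisplayScale:
    @pytest.mark.parametrize(
        "raw, expected",
        [(-3.43, 0.0), (0.0, 3.5), (2.62, 7.0)],
    )
    def test_anchor_points(self, model, raw, expected):
        assert to_display_scale(raw, model) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_raw_errors(self, model):
        with pytest.raises(ValueError):
            to_display_scale(-4.0, model)
        with pytest.raises(ValueError):
            to_display_scale(3.0, model)

    def test_classify_boundaries(self, model):
        assert classify(3.5, model) == "pathogenic"  # threshold inclusive
        assert classify(0.0, model) == "benign"
        assert classify(7.0, model) == "pathogenic"

    def test_classification_invariant_to_display_transform(self, model):
        rng = np.random.default_rng(11)
        raws = rng.uniform(model.raw_min, model.raw_max, size=10_000)
        for r in raws:
            assert (classify(to_display_scale(r, model), model) == "pathogenic") == (
                r >= 0.0
            )


class TestUniformEquivalence:
    @given(
        values=st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6),
        missing=st.sets(st.integers(0, 5), max_size=4),
    )
    @settings(deadline=None)
    def test_unit_weight_model_matches_uniform_call(self, values, missing):
        vals = [np.nan if i in missing else v for i, v in enumerate(values)]
        uniform_model = EnsembleModel.uniform(PREDICTORS)
        a = combine_uniform(vec(vals))
        b = score_optimized(vec(vals), uniform_model)
        assert a.call == b.call


def test_vectorized_table_scores_match_per_row(model):
    rng = np.random.default_rng(3)
    X = rng.random((25, 6))
    X[rng.random((25, 6)) < 0.15] = np.nan
    X[np.isnan(X).all(axis=1), 0] = 0.5
    table = make_normalized_table(X)
    raws = uniform_raw_scores(table)
    for i in range(25):
        assert raws[i] == pytest.approx(combine_uniform(vec(X[i])).raw_value)
    from varens.ensemble import optimized_raw_scores

    opt = optimized_raw_scores(table, model)
    for i in range(25):
        assert opt[i] == pytest.approx(score_optimized(vec(X[i]), model).raw_value)
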