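"""Ensemble combination of normalized predictor scores.

Two combinations are provided.  The uniform (non-optimized) combination is
the plain sum of the available normalized scores, on [0, S] for S
predictors with decision threshold S/2.  The optimized combination is an
intercept plus a non-negative weighted sum,

    raw = e_t + sum_s e_s * p_s,

pathogenic iff raw >= 0.  When predictors are missing, the available part
is rescaled so the score keeps its range: by S/S_available for the uniform
sum, and by W/(W - W_missing) for the weighted sum, where W is the total
weight and W_missing the weight of the absent predictors.

The raw optimized score lives on [e_t, e_t + W]; for presentation it is
mapped onto a fixed display scale (default 0-7, threshold at the
half-scale 3.5) by a two-segment linear map.  Classification is defined on
the raw score and is invariant to the display transform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .table import ScoreTable

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1
_TOL = 1e-9


@dataclass(frozen=True)
class EnsembleModel:
    """Per-predictor weights e_s and intercept e_t of the optimized score."""

    weights: dict[str, float]
    intercept: float
    display_max: float = 7.0

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if w < 0:
                raise ValueError(f"weight for {name} must be non-negative, got {w}")
        if self.display_max <= 0:
            raise ValueError("display_max must be positive")

    @property
    def predictors(self) -> list[str]:
        return list(self.weights)

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights.values()))

    @property
    def raw_min(self) -> float:
        return self.intercept

    @property
    def raw_max(self) -> float:
        return self.intercept + self.total_weight

    @classmethod
    def uniform(cls, predictors: Sequence[str], display_max: float = 7.0) -> "EnsembleModel":
        """Equal weights 1 and intercept -S/2: call-equivalent to the plain sum."""
        return cls(
            weights={p: 1.0 for p in predictors},
            intercept=-len(predictors) / 2.0,
            display_max=display_max,
        )


def write_model(model: EnsembleModel, path: str | Path) -> None:
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "weights": model.weights,
        "intercept": model.intercept,
        "display_max": model.display_max,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model(path: str | Path) -> EnsembleModel:
    data = json.loads(Path(path).read_text())
    version = data.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version!r} not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    for key in ("weights", "intercept"):
        if key not in data:
            raise ValueError(f"model file missing key {key!r}")
    return EnsembleModel(
        weights={k: float(v) for k, v in data["weights"].items()},
        intercept=float(data["intercept"]),
        display_max=float(data.get("display_max", 7.0)),
    )


def bundled_model() -> EnsembleModel:
    """The optimized six-predictor LDLr model shipped with the package."""
    ref = resources.files("varens.data").joinpath("optimized_model.json")
    data = json.loads(ref.read_text())
    return EnsembleModel(
        weights={k: float(v) for k, v in data["weights"].items()},
        intercept=float(data["intercept"]),
        display_max=float(data.get("display_max", 7.0)),
    )


@dataclass(frozen=True)
class CombinedScore:
    raw_value: float
    display_value: Optional[float]
    call: str
    predictors_used: frozenset[str] = field(default_factory=frozenset)


def _as_series(scores) -> pd.Series:
    if isinstance(scores, pd.Series):
        return scores.astype(float)
    if isinstance(scores, Mapping):
        return pd.Series(scores, dtype=float)
    return pd.Series(list(scores), dtype=float)


def combine_uniform(scores, n_predictors: Optional[int] = None) -> CombinedScore:
    """Non-optimized sum of available normalized scores, on [0, S].

    Missing scores (NaN) trigger the S/S_available rescale so the combined
    value keeps the full [0, S] range; the decision threshold S/2 is
    inclusive on the pathogenic side.
    """
    s = _as_series(scores)
    total = n_predictors if n_predictors is not None else len(s)
    avail = s.dropna()
    if avail.empty:
        raise ValueError("all predictor scores are missing")
    factor = total / len(avail)
    if len(avail) < total:
        logger.warning(
            "missing predictors: rescaling uniform sum by %d/%d", total, len(avail)
        )
    raw = float(avail.sum() * factor)
    call = "pathogenic" if raw >= total / 2.0 else "benign"
    if pd.api.types.is_numeric_dtype(avail.index):
        used: frozenset[str] = frozenset()
    else:
        used = frozenset(str(k) for k in avail.index)
    return CombinedScore(raw_value=raw, display_value=None, call=call, predictors_used=used)


def score_optimized(scores, model: EnsembleModel) -> CombinedScore:
    """Weighted optimized score e_t + sum e_s p_s with missing-weight rescale."""
    s = _as_series(scores)
    unknown = [k for k in s.index if k not in model.weights]
    if unknown:
        raise ValueError(f"scores include predictors absent from the model: {unknown}")
    avail = s.dropna()
    if avail.empty:
        raise ValueError("all predictor scores are missing")
    w = pd.Series(model.weights, dtype=float)
    w_avail = float(w[avail.index].sum())
    if w_avail <= _TOL:
        raise ValueError("remaining total weight after missing predictors is zero")
    weighted = float((w[avail.index] * avail).sum())
    if len(avail) < len(model.weights):
        factor = model.total_weight / w_avail
        logger.warning(
            "missing predictors %s: rescaling weighted sum by %.4f",
            sorted(set(model.weights) - set(avail.index)),
            factor,
        )
        weighted *= factor
    raw = model.intercept + weighted
    call = "pathogenic" if raw >= 0.0 else "benign"
    return CombinedScore(
        raw_value=raw,
        display_value=to_display_scale(raw, model),
        call=call,
        predictors_used=frozenset(str(k) for k in avail.index),
    )


def to_display_scale(raw_value: float, model: EnsembleModel) -> float:
    """Map the raw score onto [0, display_max] with the threshold at mid-scale.

    Two linear segments: [raw_min, 0] -> [0, display_max/2] and
    [0, raw_max] -> [display_max/2, display_max].  A presentation transform
    only; classification happens on the raw score.
    """
    lo, hi = model.raw_min, model.raw_max
    v = float(raw_value)
    if v < lo - _TOL or v > hi + _TOL:
        raise ValueError(f"raw score {v} outside model range [{lo}, {hi}]")
    v = min(max(v, lo), hi)
    half = model.display_max / 2.0
    if v >= 0:
        return half + half * v / hi if hi > 0 else half
    return half - half * v / lo if lo < 0 else half


def classify(display_value: float, model: EnsembleModel) -> str:
    """Pathogenic iff the display value reaches the half-scale threshold."""
    if not (0.0 - _TOL <= display_value <= model.display_max + _TOL):
        raise ValueError(
            f"display value {display_value} outside [0, {model.display_max}]"
        )
    return "pathogenic" if display_value >= model.display_max / 2.0 else "benign"


# ---------------------------------------------------------------------------
# vectorized table scoring


def optimized_raw_scores(table: ScoreTable, model: EnsembleModel) -> np.ndarray:
    """Raw optimized scores for every row of a normalized table."""
    if table.stage != "normalized":
        raise ValueError("table must be normalized before scoring")
    predictors = [p for p in table.predictors if p in model.weights]
    unknown = set(table.predictors) - set(model.weights)
    if unknown:
        raise ValueError(f"table predictors not in model: {sorted(unknown)}")
    X = table.df[predictors].to_numpy(dtype=float)
    w = np.array([model.weights[p] for p in predictors])
    return raw_scores_matrix(X, w, model.intercept)


def raw_scores_matrix(X: np.ndarray, weights: np.ndarray, intercept: float) -> np.ndarray:
    """Vectorized e_t + (sum over available of e_s p_s) * W/(W - W_missing)."""
    miss = np.isnan(X)
    if miss.all(axis=1).any():
        raise ValueError("a row has all predictor scores missing")
    W = weights.sum()
    w_missing = miss @ weights
    w_avail = W - w_missing
    if np.any(w_avail <= _TOL):
        raise ValueError("a row retains zero total weight after missing predictors")
    filled = np.where(miss, 0.0, X)
    weighted = filled @ weights
    return intercept + weighted * (W / w_avail)


def score_table(table: ScoreTable, model: EnsembleModel) -> pd.DataFrame:
    """Score every variant of a normalized table under a model.

    Returns a DataFrame with ``position, ref, alt, raw_score,
    display_score, call, predictors_used``.
    """
    raw = optimized_raw_scores(table, model)
    display = np.array([to_display_scale(v, model) for v in raw])
    present = table.scores().notna()
    used = [
        ";".join(p for p in table.predictors if row[p])
        for _, row in present.iterrows()
    ]
    out = table.df[["position", "ref", "alt"]].copy()
    out["raw_score"] = raw
    out["display_score"] = display
    out["call"] = np.where(raw >= 0.0, "pathogenic", "benign")
    out["predictors_used"] = used
    return out


def uniform_raw_scores(table: ScoreTable) -> np.ndarray:
    """Vectorized non-optimized sums with the S/S_available rescale."""
    if table.stage != "normalized":
        raise ValueError("table must be normalized before scoring")
    X = table.scores().to_numpy(dtype=float)
    miss = np.isnan(X)
    if miss.all(axis=1).any():
        raise ValueError("a row has all predictor scores missing")
    S = X.shape[1]
    n_avail = S - miss.sum(axis=1)
    return np.where(miss, 0.0, X).sum(axis=1) * (S / n_avail)
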