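"""Homogenization and normalization of raw predictor scores.

Two steps bring every predictor onto a common [0, 1] pathogenicity scale:

1. *Homogenize*: reorient the raw score into a pathogenicity probability
   p(P=1) in [0, 1], where 1 is most pathogenic.  Direct scores pass
   through; inverted scores (SIFT-style) become 1 - raw; signed-class
   scores (MutationTaster/MLb-style, sign = predicted class, magnitude =
   that class's probability) become |raw|/scale for positive raw and
   1 - |raw|/scale otherwise.
2. *Normalize*: a two-segment linear map that sends the predictor's own
   decision threshold t_s to 0.5, [min_h, t_s] onto [0, 0.5] and
   [t_s, max_h] onto [0.5, 1].  Values exactly at the threshold map to 0.5
   and are called pathogenic (threshold inclusive), so a normalized score
   >= 0.5 is always a predictor-level pathogenic call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .registry import PredictorRegistry, PredictorSpec
from .table import ScoreTable

_CLAMP_TOL = 1e-9


def _check_range(value: float, lo: float, hi: float, what: str) -> float:
    # values marginally outside range are floating-point noise; clamp them
    if lo - _CLAMP_TOL <= value < lo:
        return lo
    if hi < value <= hi + _CLAMP_TOL:
        return hi
    if not (lo <= value <= hi):
        raise ValueError(f"{what}: value {value} outside [{lo}, {hi}]")
    return value


def homogenize(raw: float, spec: PredictorSpec) -> float:
    """Map a raw score to the pathogenicity probability p(P=1) in [0, 1]."""
    lo, hi = spec.raw_range
    raw = _check_range(float(raw), lo, hi, f"predictor {spec.name}")
    if spec.encoding == "direct":
        return raw
    if spec.encoding == "inverted":
        return 1.0 - raw
    # signed_class: positive sign carries p(P=1), negative carries p(P=0)
    mag = abs(raw) / spec.magnitude_scale
    return mag if raw > 0 else 1.0 - mag


def normalize(p: float, spec: PredictorSpec) -> float:
    """Piecewise-linear map sending [min_h, t_s] -> [0, 0.5], [t_s, max_h] -> [0.5, 1]."""
    p = _check_range(
        float(p), spec.min_h, spec.max_h, f"predictor {spec.name} homogenized"
    )
    if p >= spec.t_s:
        return 0.5 + 0.5 * (p - spec.t_s) / (spec.max_h - spec.t_s)
    return 0.5 * (p - spec.min_h) / (spec.t_s - spec.min_h)


def normalize_value(raw: float, spec: PredictorSpec) -> float:
    """Convenience composition ``normalize(homogenize(raw))``."""
    return normalize(homogenize(raw, spec), spec)


def denormalize(value: float, spec: PredictorSpec) -> float:
    """Inverse of :func:`normalize_value`: normalized score back to a raw score.

    The signed-class encoding is inverted by class: normalized >= 0.5
    (pathogenic call) yields a positive raw score, otherwise negative.
    """
    value = _check_range(float(value), 0.0, 1.0, f"predictor {spec.name} normalized")
    if value >= 0.5:
        h = spec.t_s + 2.0 * (value - 0.5) * (spec.max_h - spec.t_s)
    else:
        h = spec.min_h + 2.0 * value * (spec.t_s - spec.min_h)
    if spec.encoding == "direct":
        return h
    if spec.encoding == "inverted":
        return 1.0 - h
    if h >= spec.t_s:
        return h * spec.magnitude_scale
    return -(1.0 - h) * spec.magnitude_scale


def normalize_table(table: ScoreTable, registry: PredictorRegistry) -> ScoreTable:
    """Normalize every predictor column of a raw table; mask is preserved."""
    if table.stage != "raw":
        raise ValueError(f"expected a raw table, got stage {table.stage!r}")
    unregistered = [p for p in table.predictors if p not in registry]
    if unregistered:
        raise ValueError(f"no registered spec for predictors: {unregistered}")
    df = table.df.copy()
    for p in table.predictors:
        spec = registry[p]
        col = df[p].to_numpy(dtype=float)
        out = np.full_like(col, np.nan)
        for i, v in enumerate(col):
            if np.isnan(v):
                continue
            try:
                out[i] = normalize_value(v, spec)
            except ValueError as exc:
                raise ValueError(f"row {i}, predictor {p}: {exc}") from exc
        df[p] = out
    return table.with_stage(df, "normalized")
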