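"""Evaluation machinery: splits, confusion metrics, AUROC, bootstrap,
concordance counts and per-domain performance.

Sensitivity and specificity are reported as percentages; the optimization
objective F0 is their product on the fractional scale, F0 = Sn * Sp with
Sn, Sp in [0, 1].  Internal math keeps full precision; rounding to one
decimal (half-up) happens only at reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .ensemble import EnsembleModel, optimized_raw_scores
from .table import DomainAnnotation, ScoreTable

logger = logging.getLogger(__name__)

POSITIVE = "pathogenic"
NEGATIVE = "benign"


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, used only for reported percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricsReport:
    """Point metrics with optional bootstrap CIs and per-domain breakdown.

    ``sensitivity``/``specificity``/``auroc`` are percentages (0-100); ``f0``
    is the fractional product Sn*Sp in [0, 1].  ``ci95`` maps metric name to
    a (low, high) percentile interval; low <= high always holds, but the
    interval is not guaranteed to bracket the point estimate.
    """

    sensitivity: float
    specificity: float
    f0: float
    counts: Optional[ConfusionCounts] = None
    auroc: Optional[float] = None
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    per_domain: Optional[dict] = None

    def rounded(self) -> dict:
        out = {
            "sensitivity": round_half_up(self.sensitivity),
            "specificity": round_half_up(self.specificity),
            "f0": round(self.f0, 4),
        }
        if self.auroc is not None:
            out["auroc"] = round_half_up(self.auroc)
        if self.ci95:
            out["ci95"] = {
                k: (round_half_up(lo), round_half_up(hi))
                for k, (lo, hi) in self.ci95.items()
            }
        return out


def _to_bool(values, positive: str = POSITIVE) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype == bool:
        return arr
    return arr == positive


def confusion_metrics(calls, labels) -> MetricsReport:
    """Sn/Sp/F0 from parallel call and label sequences.

    Both classes must be represented in the labels; an empty class is an
    error naming it, since the corresponding rate is undefined.
    """
    y_call = _to_bool(calls)
    y_true = _to_bool(labels)
    if len(y_call) != len(y_true):
        raise ValueError("calls and labels differ in length")
    counts = ConfusionCounts(
        tp=int((y_call & y_true).sum()),
        fn=int((~y_call & y_true).sum()),
        tn=int((~y_call & ~y_true).sum()),
        fp=int((y_call & ~y_true).sum()),
    )
    return metrics_from_counts(counts)


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    if counts.positives == 0:
        raise ValueError("no pathogenic examples: sensitivity is undefined")
    if counts.negatives == 0:
        raise ValueError("no benign examples: specificity is undefined")
    sn = 100.0 * counts.tp / counts.positives
    sp = 100.0 * counts.tn / counts.negatives
    return MetricsReport(
        sensitivity=sn,
        specificity=sp,
        f0=(sn / 100.0) * (sp / 100.0),
        counts=counts,
    )


def split_train_validation(
    table: ScoreTable, seed: int
) -> tuple[ScoreTable, ScoreTable]:
    """Random stratified split: 3/4 of pathogenic and 2/3 of benign variants
    go to training (counts rounded half-up), the remainder to validation.
    """
    labels = table.labels
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    valid_idx: list[int] = []
    for label, frac in ((POSITIVE, 0.75), (NEGATIVE, 2.0 / 3.0)):
        idx = np.flatnonzero((labels == label).to_numpy())
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 members")
        n_train = training_count(len(idx), frac)
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
        valid_idx.extend(perm[n_train:].tolist())
    train = ScoreTable(
        table.df.iloc[sorted(train_idx)], table.predictors, table.stage
    )
    valid = ScoreTable(
        table.df.iloc[sorted(valid_idx)], table.predictors, table.stage
    )
    return train, valid


def training_count(n: int, fraction: float) -> int:
    """Half-up rounding of fraction*n, the class-wise training-set size."""
    return int(np.floor(fraction * n + 0.5))


def auroc(scores, labels) -> float:
    """Area under the ROC curve as a percentage.

    Equivalent to the threshold sweep over all distinct score values with
    trapezoidal integration, and hence to the pairwise Mann-Whitney
    statistic P(score_path > score_ben) + 0.5 P(tie).
    """
    y = _to_bool(labels)
    if y.all() or not y.any():
        raise ValueError("AUROC needs both classes present")
    return 100.0 * float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def bootstrap_metrics(
    table: ScoreTable,
    model: EnsembleModel,
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricsReport:
    """Percentile bootstrap of Sn/Sp under a fixed model.

    Resamples the labeled table with replacement at its original size;
    resamples lacking a class are redrawn (counted and logged) so exactly
    ``n_boot`` valid resamples contribute.  CIs are the 2.5th/97.5th
    percentiles.  Deterministic given the seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    labels = _to_bool(table.labels.to_numpy())
    if labels.all() or not labels.any():
        raise ValueError("bootstrap needs both classes in the dataset")
    calls = optimized_raw_scores(table, model) >= 0.0
    n = len(labels)
    rng = np.random.default_rng(seed)
    sns = np.empty(n_boot)
    sps = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.any() and not lab.all():
                break
            redraws += 1
        cal = calls[idx]
        sns[b] = 100.0 * (cal & lab).sum() / lab.sum()
        sps[b] = 100.0 * (~cal & ~lab).sum() / (~lab).sum()
    if redraws:
        logger.info("bootstrap: redrew %d resamples lacking a class", redraws)
    point = confusion_metrics(calls, labels)
    point.ci95 = {
        "sensitivity": (
            float(np.percentile(sns, 2.5)),
            float(np.percentile(sns, 97.5)),
        ),
        "specificity": (
            float(np.percentile(sps, 2.5)),
            float(np.percentile(sps, 97.5)),
        ),
    }
    return point


def concordance_counts(correct: pd.DataFrame) -> dict:
    """Agreement histogram from a variants x predictors correctness matrix.

    Missing cells count as incorrect (logged).  Returns the histogram over
    agreement levels 0..S plus per-predictor correct totals; histogram
    levels sum to the variant count.
    """
    if correct.empty:
        raise ValueError("empty correctness matrix")
    if correct.isna().any().any():
        logger.warning(
            "correctness matrix has %d missing cells; treating as incorrect",
            int(correct.isna().sum().sum()),
        )
        correct = correct.astype("boolean").fillna(False)
    mat = correct.to_numpy(dtype=bool)
    S = mat.shape[1]
    levels = np.bincount(mat.sum(axis=1), minlength=S + 1)
    return {
        "levels": {int(k): int(v) for k, v in enumerate(levels)},
        "per_predictor": {
            str(c): int(mat[:, j].sum()) for j, c in enumerate(correct.columns)
        },
        "n_variants": int(mat.shape[0]),
    }


def per_domain_metrics(
    table: ScoreTable,
    model: EnsembleModel,
    domains: DomainAnnotation,
) -> dict:
    """Sn/Sp and correct-call counts within each annotated domain.

    Positions outside every declared domain fall into an ``unassigned``
    pseudo-domain.  A domain missing one class reports only the defined
    metric (the other is None).
    """
    labels = _to_bool(table.labels.to_numpy())
    calls = optimized_raw_scores(table, model) >= 0.0
    assigned = [
        domains.domain_of(int(p)) or "unassigned" for p in table.df["position"]
    ]
    out: dict[str, dict] = {}
    for name in sorted(set(assigned)):
        sel = np.array([a == name for a in assigned])
        lab, cal = labels[sel], calls[sel]
        entry: dict = {
            "n_pathogenic": int(lab.sum()),
            "n_benign": int((~lab).sum()),
            "correct_pathogenic": int((cal & lab).sum()),
            "correct_benign": int((~cal & ~lab).sum()),
            "sensitivity": None,
            "specificity": None,
        }
        if lab.any():
            entry["sensitivity"] = 100.0 * (cal & lab).sum() / lab.sum()
        if (~lab).any():
            entry["specificity"] = 100.0 * (~cal & ~lab).sum() / (~lab).sum()
        out[name] = entry
    return out
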