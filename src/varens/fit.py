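"""Weight optimization: fit the ensemble to labeled variants.

The objective is F0 = Sn * Sp (both fractional) of the weighted-score
classifier on the training table; the decision variables are the S
non-negative predictor weights and the intercept (the threshold term),
bounded to [0, w_max] and [-S, 0].  F0 is piecewise constant in the
parameters, so a derivative-free evolutionary search is used
(:func:`scipy.optimize.differential_evolution` with gradient polishing
disabled).  The uniform model (all weights 1, intercept -S/2) is seeded
into the initial population, so the fitted model never scores below that
baseline on training.  Ties in F0 break toward higher sensitivity.

The statsmodels-style surface is :class:`EnsemblePathogenicityModel` /
:class:`EnsembleFitResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .ensemble import EnsembleModel, raw_scores_matrix, score_table
from .metrics import (
    MetricsReport,
    auroc,
    bootstrap_metrics,
    confusion_metrics,
    round_half_up,
)
from .table import ScoreTable

logger = logging.getLogger(__name__)

_SN_TIEBREAK = 1e-6  # < smallest possible F0 increment for n <= ~1000


@dataclass(frozen=True)
class OptimizerConfig:
    """Evolutionary-search settings for the weight fit."""

    population_size: int = 60
    generations: int = 300
    weight_max: float = 3.0
    mutation: tuple[float, float] = (0.3, 1.0)
    recombination: float = 0.7
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 5:
            raise ValueError("population_size must be >= 5")
        if self.generations < 1 or self.weight_max <= 0 or self.tol <= 0:
            raise ValueError("generations, weight_max and tol must be positive")


def _objective_factory(X: np.ndarray, y: np.ndarray):
    """Return f(params) -> negative (F0 + tiny * Sn) for the DE minimizer."""
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    miss = np.isnan(X)
    filled = np.where(miss, 0.0, X)

    def objective(params: np.ndarray) -> float:
        w, b = params[:-1], params[-1]
        W = w.sum()
        w_avail = W - miss @ w
        if np.any(w_avail <= 1e-12):
            return 0.0  # degenerate: some row loses all weight
        raw = b + (filled @ w) * (W / w_avail)
        calls = raw >= 0.0
        sn = (calls & y).sum() / n_pos
        sp = (~calls & ~y).sum() / n_neg
        return -(sn * sp + _SN_TIEBREAK * sn)

    return objective


def optimize_weights(
    training: ScoreTable,
    config: OptimizerConfig = OptimizerConfig(),
) -> tuple[EnsembleModel, dict]:
    """Maximize training F0 over weights and intercept.

    Returns the fitted :class:`EnsembleModel` and a diagnostics dict with
    the achieved F0, generation count and convergence flag.  Deterministic
    given ``config.seed``.  If the search does not converge within the
    generation budget the best-so-far model is returned with
    ``converged=False`` and a warning.
    """
    labels = training.labels
    y = (labels == "pathogenic").to_numpy()
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")
    if len(training.predictors) < 2:
        raise ValueError("need at least 2 predictors to optimize")
    X = training.scores().to_numpy(dtype=float)
    S = X.shape[1]
    objective = _objective_factory(X, y)

    bounds = [(0.0, config.weight_max)] * S + [(-float(S), 0.0)]
    rng = np.random.default_rng(config.seed)
    init = np.empty((config.population_size, S + 1))
    init[:, :S] = rng.uniform(0.0, config.weight_max, size=(config.population_size, S))
    init[:, S] = rng.uniform(-S, 0.0, size=config.population_size)
    # seed the uniform baseline (weights 1, intercept -S/2) into the population
    init[0, :S] = 1.0
    init[0, S] = -S / 2.0

    result = differential_evolution(
        objective,
        bounds=bounds,
        init=init,
        maxiter=config.generations,
        mutation=config.mutation,
        recombination=config.recombination,
        tol=config.tol,
        seed=config.seed,
        polish=False,  # objective is piecewise constant; gradients are useless
        updating="immediate",
    )
    params = result.x
    converged = bool(result.success)
    if not converged:
        logger.warning(
            "weight optimization did not converge in %d generations; "
            "returning best-so-far",
            config.generations,
        )
    model = EnsembleModel(
        weights={p: float(w) for p, w in zip(training.predictors, params[:S])},
        intercept=float(params[S]),
    )
    calls = raw_scores_matrix(X, params[:S], params[S]) >= 0.0
    report = confusion_metrics(calls, y)
    diagnostics = {
        "f0": report.f0,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "generations": int(result.nit),
        "converged": converged,
        "n_evaluations": int(result.nfev),
    }
    return model, diagnostics


class EnsemblePathogenicityModel:
    """Ensemble pathogenicity classifier to be fitted to labeled variants.

    Built from a normalized, fully labeled :class:`ScoreTable`; ``fit()``
    runs the evolutionary weight search and returns an
    :class:`EnsembleFitResults`.
    """

    def __init__(self, training: ScoreTable, config: Optional[OptimizerConfig] = None):
        if training.stage != "normalized":
            raise ValueError("model requires a normalized score table")
        if not training.has_labels:
            raise ValueError("model requires labels on every record")
        self.training = training
        self.config = config or OptimizerConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        predictors: Sequence[str],
        config: Optional[OptimizerConfig] = None,
    ) -> "EnsemblePathogenicityModel":
        """Build from a DataFrame with position/ref/alt/label + normalized scores."""
        return cls(ScoreTable(df, list(predictors), "normalized"), config=config)

    def fit(self, seed: Optional[int] = None) -> "EnsembleFitResults":
        config = self.config
        if seed is not None:
            config = OptimizerConfig(
                population_size=config.population_size,
                generations=config.generations,
                weight_max=config.weight_max,
                mutation=config.mutation,
                recombination=config.recombination,
                tol=config.tol,
                seed=seed,
            )
        model, diagnostics = optimize_weights(self.training, config)
        return EnsembleFitResults(self, model, diagnostics)


class EnsembleFitResults:
    """Fitted ensemble: weights, intercept, training metrics, predictions."""

    def __init__(
        self,
        model: EnsemblePathogenicityModel,
        fitted: EnsembleModel,
        diagnostics: dict,
    ):
        self.model = model
        self.ensemble = fitted
        self.diagnostics = diagnostics

    @property
    def params(self) -> pd.Series:
        s = pd.Series(self.ensemble.weights, dtype=float)
        s["intercept"] = self.ensemble.intercept
        return s

    @property
    def f0(self) -> float:
        return self.diagnostics["f0"]

    def predict(self, table: ScoreTable) -> pd.DataFrame:
        """Score a normalized table; returns the per-variant score frame."""
        return score_table(table, self.ensemble)

    def evaluate(
        self, table: ScoreTable, with_auroc: bool = False
    ) -> MetricsReport:
        """Confusion metrics (optionally AUROC) on a labeled normalized table."""
        scored = self.predict(table)
        report = confusion_metrics(
            scored["call"].to_numpy(), table.labels.to_numpy()
        )
        if with_auroc:
            report.auroc = auroc(
                scored["raw_score"].to_numpy(), table.labels.to_numpy()
            )
        return report

    def bootstrap(
        self, table: ScoreTable, n_boot: int = 1000, seed: int = 0
    ) -> MetricsReport:
        return bootstrap_metrics(table, self.ensemble, n_boot=n_boot, seed=seed)

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Ensemble pathogenicity fit",
            "=" * 44,
            f"{'n variants':<24}{len(self.model.training):>20}",
            f"{'n predictors':<24}{len(self.model.training.predictors):>20}",
            f"{'generations':<24}{d['generations']:>20}",
            f"{'converged':<24}{str(d['converged']):>20}",
            f"{'training F0':<24}{d['f0']:>20.4f}",
            f"{'training Sn (%)':<24}{round_half_up(d['sensitivity']):>20.1f}",
            f"{'training Sp (%)':<24}{round_half_up(d['specificity']):>20.1f}",
            "-" * 44,
            f"{'term':<24}{'estimate':>20}",
        ]
        for name, value in self.params.items():
            lines.append(f"{name:<24}{value:>20.4f}")
        lines.append("=" * 44)
        return "\n".join(lines)
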