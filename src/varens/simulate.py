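"""Synthetic labeled score tables with controllable signal.

The generator emulates the geometry of real predictor outputs on the
common normalized scale: each predictor draws a label-conditional score
from a bounded unimodal distribution on [0, 1] whose class means are
separated by ``delta`` (benign mean 0.5 - delta/2, pathogenic mean
0.5 + delta/2).  Two named presets exercise the shapes seen in practice:
``polarized`` (scores piled at the extremes, MutationTaster-like) and
``threshold_hugging`` (scores compressed around the 0.5 threshold,
MLb-like).  Optionally a planted ensemble model is recorded alongside the
data as ground truth for recovery studies, and raw-scale tables can be
produced by inverting each predictor's encoding so the normalization
pipeline can be round-trip tested.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ensemble import EnsembleModel, score_table, write_model
from .normalize import denormalize
from .registry import PredictorRegistry, bundled_registry
from .substitutions import AA1, accessible_substitutions
from .table import ScoreTable, write_score_table

PRESETS = ("gaussian", "polarized", "threshold_hugging")
_AA_LIST = sorted(AA1)


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    ``delta`` is the mean separation between the label-conditional score
    distributions, per predictor (a scalar applies to all).  ``missingness``
    is the per-predictor probability that a cell is masked.
    """

    n_pathogenic: int = 500
    n_benign: int = 50
    predictors: tuple[str, ...] = (
        "SIFT",
        "PolyPhen-2",
        "MLb-LDLr",
        "MutationTaster",
        "REVEL",
        "VARITY",
    )
    delta: float | Mapping[str, float] = 0.6
    noise_sd: float = 0.15
    missingness: float | Mapping[str, float] = 0.0
    preset: str | Mapping[str, str] = "gaussian"
    protein_length: int = 860
    max_subs_per_residue: int = 9
    planted_model: Optional[EnsembleModel] = None
    cds: Optional[str] = None
    seed: int = 0

    def _per_predictor(self, value, what: str) -> dict[str, float]:
        if isinstance(value, Mapping):
            return {p: value.get(p, 0.0) for p in self.predictors}
        return {p: value for p in self.predictors}

    def deltas(self) -> dict[str, float]:
        d = self._per_predictor(self.delta, "delta")
        for p, v in d.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"delta for {p} must be in [0, 1], got {v}")
        return d

    def missing_rates(self) -> dict[str, float]:
        m = self._per_predictor(self.missingness, "missingness")
        for p, v in m.items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"missingness for {p} must be in [0, 1), got {v}")
        return m

    def presets(self) -> dict[str, str]:
        if isinstance(self.preset, Mapping):
            out = {p: self.preset.get(p, "gaussian") for p in self.predictors}
        else:
            out = {p: self.preset for p in self.predictors}
        for p, name in out.items():
            if name not in PRESETS:
                raise ValueError(f"unknown preset {name!r} for {p}")
        return out


def _truncnorm_draw(rng, mean: float, sd: float, size: int) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_scores(
    rng: np.random.Generator,
    preset: str,
    delta: float,
    sd: float,
    pathogenic: bool,
    size: int,
) -> np.ndarray:
    sign = 1.0 if pathogenic else -1.0
    if preset == "gaussian":
        return _truncnorm_draw(rng, 0.5 + sign * delta / 2.0, sd, size)
    if preset == "threshold_hugging":
        return _truncnorm_draw(rng, 0.5 + sign * delta / 4.0, 0.05, size)
    # polarized: mass at the extremes, class shifts the mixture weight
    p_high = 0.5 + sign * delta / 2.0
    high = rng.random(size) < p_high
    out = np.empty(size)
    out[high] = _truncnorm_draw(rng, 0.97, 0.03, int(high.sum()))
    out[~high] = _truncnorm_draw(rng, 0.03, 0.03, int((~high).sum()))
    return out


def _place_substitutions(
    rng: np.random.Generator, spec: SimulationSpec, n: int
) -> pd.DataFrame:
    """Positions/ref/alt with consistent refs and <= max_subs per residue."""
    if spec.cds is not None:
        cds = spec.cds.upper().replace("\n", "")
        codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
        choices = []
        for pos, codon in enumerate(codons, start=1):
            try:
                alts = accessible_substitutions(codon)
            except ValueError:
                continue
            from Bio.Data.CodonTable import unambiguous_dna_by_id

            ref = unambiguous_dna_by_id[1].forward_table[codon]
            choices.extend((pos, ref, alt) for alt in sorted(alts))
        if len(choices) < n:
            raise ValueError(
                f"coding sequence offers only {len(choices)} accessible "
                f"substitutions, need {n}"
            )
        picked = rng.choice(len(choices), size=n, replace=False)
        rows = [choices[i] for i in picked]
        return pd.DataFrame(rows, columns=["position", "ref", "alt"])

    refs: dict[int, str] = {}
    used: dict[int, set[str]] = {}
    rows = []
    attempts = 0
    while len(rows) < n:
        attempts += 1
        if attempts > 100 * n:
            raise ValueError("cannot place substitutions under the residue cap")
        pos = int(rng.integers(1, spec.protein_length + 1))
        ref = refs.setdefault(pos, _AA_LIST[rng.integers(0, 20)])
        taken = used.setdefault(pos, set())
        if len(taken) >= min(spec.max_subs_per_residue, 19):
            continue
        alt = _AA_LIST[rng.integers(0, 20)]
        if alt == ref or alt in taken:
            continue
        taken.add(alt)
        rows.append((pos, ref, alt))
    return pd.DataFrame(rows, columns=["position", "ref", "alt"])


def generate_dataset(spec: SimulationSpec) -> tuple[ScoreTable, dict]:
    """Draw a labeled, normalized score table plus ground-truth metadata."""
    n = spec.n_pathogenic + spec.n_benign
    if spec.n_pathogenic < 1 or spec.n_benign < 1:
        raise ValueError("need at least one variant of each class")
    rng = np.random.default_rng(spec.seed)
    deltas = spec.deltas()
    missing = spec.missing_rates()
    presets = spec.presets()

    df = _place_substitutions(rng, spec, n)
    labels = np.array(
        ["pathogenic"] * spec.n_pathogenic + ["benign"] * spec.n_benign
    )
    rng.shuffle(labels)
    df["label"] = labels
    is_path = labels == "pathogenic"

    n_masked = 0
    for p in spec.predictors:
        col = np.empty(n)
        col[is_path] = _draw_scores(
            rng, presets[p], deltas[p], spec.noise_sd, True, int(is_path.sum())
        )
        col[~is_path] = _draw_scores(
            rng, presets[p], deltas[p], spec.noise_sd, False, int((~is_path).sum())
        )
        if missing[p] > 0:
            mask = rng.random(n) < missing[p]
            col[mask] = np.nan
            n_masked += int(mask.sum())
        df[p] = col
    # never leave a row entirely unscored
    all_missing = df[list(spec.predictors)].isna().all(axis=1)
    if all_missing.any():
        first = spec.predictors[0]
        for i in np.flatnonzero(all_missing.to_numpy()):
            df.loc[i, first] = _draw_scores(
                rng, presets[first], deltas[first], spec.noise_sd,
                bool(is_path[i]), 1,
            )[0]
            n_masked -= 1
    table = ScoreTable(df, list(spec.predictors), "normalized")
    metadata = {
        "seed": spec.seed,
        "n_pathogenic": spec.n_pathogenic,
        "n_benign": spec.n_benign,
        "n_masked_cells": n_masked,
        "planted_model": None
        if spec.planted_model is None
        else {
            "weights": spec.planted_model.weights,
            "intercept": spec.planted_model.intercept,
        },
    }
    return table, metadata


def generate_raw_dataset(
    spec: SimulationSpec, registry: PredictorRegistry
) -> tuple[ScoreTable, dict]:
    """Raw-scale synthetic table: normalized draws pushed back through each
    predictor's encoding, so ``normalize_table`` recovers them to 1e-9."""
    missing = [p for p in spec.predictors if p not in registry]
    if missing:
        raise ValueError(f"registry lacks specs for predictors: {missing}")
    table, metadata = generate_dataset(spec)
    df = table.df.copy()
    for p in spec.predictors:
        spec_p = registry[p]
        df[p] = [
            np.nan if pd.isna(v) else denormalize(float(v), spec_p)
            for v in df[p]
        ]
    return ScoreTable(df, list(spec.predictors), "raw"), metadata


_TOY_SPEC = SimulationSpec(
    n_pathogenic=25,
    n_benign=15,
    delta=0.7,
    missingness={"MutationTaster": 0.15},
    seed=20240123,
)


def write_golden_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the bundled model, registry, domain config and a 40-variant toy
    table with its expected scored output into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("registry.yaml", "optimized_model.json", "ldlr_domains.json"):
        src = resources.files("varens.data").joinpath(name)
        dst = out / name
        dst.write_text(src.read_text())
        paths[name] = dst

    registry = bundled_registry()
    from .ensemble import bundled_model

    model = bundled_model()
    raw_table, _ = generate_raw_dataset(_TOY_SPEC, registry)
    toy_path = out / "toy_variants.tsv"
    write_score_table(raw_table, toy_path)
    paths["toy_variants.tsv"] = toy_path

    from .normalize import normalize_table

    scored = score_table(normalize_table(raw_table, registry), model)
    expected_path = out / "toy_expected.tsv"
    scored.to_csv(expected_path, sep="\t", index=False, float_format="%.6f")
    paths["toy_expected.tsv"] = expected_path
    return paths
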