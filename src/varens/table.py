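"""Variant score tables and protein domain annotations.

A :class:`ScoreTable` wraps a pandas DataFrame with the fixed columns
``position, ref, alt`` (and optionally ``label``) followed by one numeric
column per predictor; missing cells are NaN and are never imputed.  The
``stage`` attribute tracks whether the predictor columns hold raw,
homogenized or normalized values; transitions only move forward
(raw -> homogenized -> normalized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .registry import PredictorRegistry
from .substitutions import AminoAcidSubstitution

STAGES = ("raw", "homogenized", "normalized")
META_COLUMNS = ("position", "ref", "alt", "label")

_LABEL_ALIASES = {
    "benign": "benign",
    "likely benign": "benign",
    "likely_benign": "benign",
    "pathogenic": "pathogenic",
    "likely pathogenic": "pathogenic",
    "likely_pathogenic": "pathogenic",
}


def canonical_label(value: str) -> str:
    """Collapse likely-benign/likely-pathogenic onto the binary labels."""
    key = str(value).strip().lower()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown label {value!r}") from None


@dataclass(frozen=True)
class VariantRecord:
    substitution: AminoAcidSubstitution
    raw_scores: dict[str, float] = field(default_factory=dict)
    label: Optional[str] = None


class ScoreTable:
    """Substitutions x predictors score matrix with missingness and labels."""

    def __init__(self, df: pd.DataFrame, predictors: Sequence[str], stage: str):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        for col in ("position", "ref", "alt"):
            if col not in df.columns:
                raise ValueError(f"score table is missing column {col!r}")
        missing = [p for p in predictors if p not in df.columns]
        if missing:
            raise ValueError(f"predictor columns absent from table: {missing}")
        self.df = df.reset_index(drop=True)
        self.predictors = list(predictors)
        self.stage = stage
        if stage == "normalized":
            vals = self.scores().to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("normalized scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_labels(self) -> bool:
        return "label" in self.df.columns and self.df["label"].notna().all()

    @property
    def labels(self) -> pd.Series:
        if not self.has_labels:
            raise ValueError("table has no complete label column")
        return self.df["label"]

    def scores(self) -> pd.DataFrame:
        """Predictor columns only (NaN = missing)."""
        return self.df[self.predictors]

    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask, True where a score is absent."""
        return self.df[self.predictors].isna()

    def records(self) -> Iterator[VariantRecord]:
        for _, row in self.df.iterrows():
            scores = {
                p: float(row[p]) for p in self.predictors if pd.notna(row[p])
            }
            yield VariantRecord(
                substitution=AminoAcidSubstitution(
                    int(row["position"]), str(row["ref"]), str(row["alt"])
                ),
                raw_scores=scores,
                label=row.get("label") if pd.notna(row.get("label")) else None,
            )

    def with_stage(self, df: pd.DataFrame, stage: str) -> "ScoreTable":
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"cannot move stage backwards: {self.stage} -> {stage}")
        return ScoreTable(df, self.predictors, stage)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_score_table(
    path: str | Path,
    registry: PredictorRegistry,
    stage: str = "raw",
) -> ScoreTable:
    """Read a TSV/CSV score table; delimiter chosen from the extension.

    Header must contain ``position, ref, alt``, optionally ``label``, and
    only registered predictor names beyond those.  Empty cells are recorded
    as missing; non-numeric score cells are an error naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    unknown = [
        c for c in df.columns if c not in META_COLUMNS and c not in registry
    ]
    if unknown:
        raise ValueError(f"unregistered predictor columns: {unknown}")
    predictors = [c for c in df.columns if c in registry]
    for col in ("position", "ref", "alt"):
        if col not in df.columns:
            raise ValueError(f"score table {path} is missing column {col!r}")
    out = pd.DataFrame()
    out["position"] = df["position"].astype(int)
    out["ref"] = df["ref"].str.strip()
    out["alt"] = df["alt"].str.strip()
    if "label" in df.columns:
        out["label"] = [
            canonical_label(v) if v.strip() else None for v in df["label"]
        ]
    for p in predictors:
        vals = []
        for i, cell in enumerate(df[p]):
            cell = cell.strip()
            if not cell:
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"non-numeric score {cell!r} for predictor {p} at row {i}"
                ) from None
        out[p] = vals
    return ScoreTable(out, predictors, stage)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a score table; output is always tab-delimited, NaN as empty."""
    table.df.to_csv(path, sep="\t", index=False, na_rep="")


@dataclass(frozen=True)
class Domain:
    name: str
    start: int
    end: int


class DomainAnnotation:
    """Named, non-overlapping, 1-based inclusive residue ranges."""

    def __init__(self, protein_length: int, domains: Sequence[Domain]):
        if protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        ordered = sorted(domains, key=lambda d: d.start)
        prev_end = 0
        for d in ordered:
            if not (1 <= d.start <= d.end <= protein_length):
                raise ValueError(
                    f"domain {d.name}: range [{d.start}, {d.end}] outside "
                    f"[1, {protein_length}]"
                )
            if d.start <= prev_end:
                raise ValueError(f"domain {d.name} overlaps a previous domain")
            prev_end = d.end
        self.protein_length = protein_length
        self.domains = ordered

    def domain_of(self, position: int) -> Optional[str]:
        """Domain name at ``position``, or None if unannotated."""
        for d in self.domains:
            if d.start <= position <= d.end:
                return d.name
        return None

    @classmethod
    def from_dict(cls, data: dict) -> "DomainAnnotation":
        return cls(
            protein_length=int(data["protein_length"]),
            domains=[
                Domain(e["name"], int(e["start"]), int(e["end"]))
                for e in data["domains"]
            ],
        )

    @classmethod
    def load(cls, path: str | Path) -> "DomainAnnotation":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def bundled_ldlr_domains() -> DomainAnnotation:
    """Approximate 9-domain annotation of the 860-residue LDL receptor."""
    from importlib import resources

    ref = resources.files("varens.data").joinpath("ldlr_domains.json")
    return DomainAnnotation.from_dict(json.loads(ref.read_text()))
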