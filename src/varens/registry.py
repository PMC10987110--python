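"""Predictor registry: how each software encodes its raw score.

Three raw-score encodings cover the predictors handled here:

``direct``
    Higher means more pathogenic, raw range [0, 1] (PolyPhen-2, REVEL,
    VARITY).
``inverted``
    Lower means more pathogenic, raw range [0, 1] (SIFT).
``signed_class``
    The sign encodes the predicted class and the magnitude that class's
    probability, on either a unit scale (MLb-LDLr, raw in [-1, 1]) or a
    percent scale (MutationTaster, raw in [-100, 100]).

``t_s`` is the decision threshold on the *homogenized* probability scale:
homogenized values >= t_s are called pathogenic (threshold inclusive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import yaml

ENCODINGS = ("direct", "inverted", "signed_class")


@dataclass(frozen=True)
class PredictorSpec:
    """Raw-score encoding, scale and decision threshold of one predictor."""

    name: str
    encoding: str
    t_s: float = 0.5
    magnitude_scale: float = 1.0
    min_h: float = 0.0
    max_h: float = 1.0

    def __post_init__(self) -> None:
        if self.encoding not in ENCODINGS:
            raise ValueError(
                f"{self.name}: unknown encoding {self.encoding!r} "
                f"(expected one of {ENCODINGS})"
            )
        if self.magnitude_scale <= 0:
            raise ValueError(f"{self.name}: magnitude_scale must be > 0")
        if not (self.min_h < self.t_s < self.max_h):
            raise ValueError(
                f"{self.name}: need min_h < t_s < max_h, got "
                f"{self.min_h} / {self.t_s} / {self.max_h}"
            )

    @property
    def raw_range(self) -> tuple[float, float]:
        if self.encoding == "signed_class":
            return (-self.magnitude_scale, self.magnitude_scale)
        return (0.0, 1.0)


class PredictorRegistry(Mapping[str, PredictorSpec]):
    """Ordered mapping of predictor name -> :class:`PredictorSpec`."""

    def __init__(self, specs: list[PredictorSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictor names in registry")
        self._specs = {s.name: s for s in specs}

    def __getitem__(self, name: str) -> PredictorSpec:
        return self._specs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def to_dict(self) -> dict:
        return {
            s.name: {
                "encoding": s.encoding,
                "t_s": s.t_s,
                "magnitude_scale": s.magnitude_scale,
                "min_h": s.min_h,
                "max_h": s.max_h,
            }
            for s in self._specs.values()
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PredictorRegistry":
        specs = [
            PredictorSpec(
                name=name,
                encoding=entry["encoding"],
                t_s=float(entry.get("t_s", 0.5)),
                magnitude_scale=float(entry.get("magnitude_scale", 1.0)),
                min_h=float(entry.get("min_h", 0.0)),
                max_h=float(entry.get("max_h", 1.0)),
            )
            for name, entry in data.items()
        ]
        return cls(specs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PredictorRegistry":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def bundled_registry() -> PredictorRegistry:
    """The six-predictor registry shipped with the package."""
    ref = resources.files("varens.data").joinpath("registry.yaml")
    return PredictorRegistry.from_dict(yaml.safe_load(ref.read_text()))
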