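"""Per-residue potential pathogenicity and hotspot maps.

A residue's potential pathogenicity summarizes how pathogenic its
accessible substitutions are predicted to be: for each predictor, the
arithmetic mean of the normalized scores of the substitutions observed at
that residue; the per-predictor averages are then combined exactly like a
single substitution's scores (uniform sum or weighted optimized score).
Display-scale values are binned for the hotspot map: white below/at 4.5,
then five red shades over the upper-inclusive intervals (4.5, 4.9],
(4.9, 5.3], (5.3, 5.7], (5.7, 6.1], (6.1, 6.5].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel, score_optimized, to_display_scale
from .table import DomainAnnotation, ScoreTable

logger = logging.getLogger(__name__)

BIN_LOWER = 4.5
BIN_WIDTH = 0.4
N_RED_BINS = 5
_TOL = 1e-9

# white + five red shades, darkest red = most pathogenic
BIN_COLORS = ("#FFFFFF", "#FDD0C0", "#FB9C80", "#F4614D", "#D32232", "#9E0022")


@dataclass(frozen=True)
class ResiduePotential:
    position: int
    per_software: dict[str, float]
    n_sr: dict[str, int]
    combined: float
    display: float
    bin: int


def residue_potential_per_software(
    table: ScoreTable, position: int
) -> tuple[dict[str, float], dict[str, int]]:
    """Per-predictor mean normalized score over a residue's substitutions.

    Predictors with no data at the residue are absent from the result.
    Returns (means, substitution counts used).
    """
    if table.stage != "normalized":
        raise ValueError("residue potentials need a normalized table")
    sel = table.df["position"] == position
    if not sel.any():
        raise ValueError(f"no substitutions at position {position}")
    refs = set(table.df.loc[sel, "ref"])
    if len(refs) > 1:
        raise ValueError(
            f"position {position} has conflicting reference residues: {sorted(refs)}"
        )
    block = table.df.loc[sel, table.predictors]
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for p in table.predictors:
        col = block[p].dropna()
        if col.empty:
            continue
        means[p] = float(col.mean())
        counts[p] = int(col.size)
    if not means:
        raise ValueError(f"position {position} has no scores at all")
    return means, counts


def combine_potentials_uniform(
    per_software: dict[str, float], n_predictors: Optional[int] = None
) -> float:
    """Sum of per-predictor averages on [0, S], rescaled for absent predictors."""
    if not per_software:
        raise ValueError("empty per-predictor average map")
    S = n_predictors if n_predictors is not None else len(per_software)
    factor = S / len(per_software)
    if factor != 1.0:
        logger.warning(
            "absent predictors: rescaling residue potential by %d/%d",
            S,
            len(per_software),
        )
    return float(sum(per_software.values()) * factor)


def combine_potentials_weighted(
    per_software: dict[str, float], model: EnsembleModel
) -> float:
    """Weighted optimized residue potential, on the display scale.

    Identical arithmetic to scoring one substitution whose normalized
    scores equal the per-predictor averages.
    """
    scores = {p: per_software.get(p, np.nan) for p in model.predictors}
    combined = score_optimized(scores, model)
    return float(combined.display_value)


def assign_bins(display_value: float, display_max: float = 7.0) -> int:
    """Hotspot bin for a display-scale value: 0 = white, 1-5 = red shades.

    Red intervals include only their upper limit, so exactly 4.5 is white;
    values above 6.5 (possible up to display_max) clamp to the darkest bin
    with a warning.
    """
    v = float(display_value)
    if v < -_TOL or v > display_max + _TOL:
        raise ValueError(f"display value {v} outside [0, {display_max}]")
    if v <= BIN_LOWER:
        return 0
    top = BIN_LOWER + N_RED_BINS * BIN_WIDTH
    if v > top + _TOL:
        logger.warning("display value %.3f above %.1f; clamping to bin %d", v, top, N_RED_BINS)
        return N_RED_BINS
    return min(N_RED_BINS, math.ceil((v - BIN_LOWER) / BIN_WIDTH - _TOL))


def residue_potential_map(
    table: ScoreTable,
    model: EnsembleModel,
    positions: Optional[Sequence[int]] = None,
) -> list[ResiduePotential]:
    """Weighted residue potentials for every (or the given) residue positions."""
    if positions is None:
        positions = sorted(set(int(p) for p in table.df["position"]))
    out = []
    for pos in positions:
        means, counts = residue_potential_per_software(table, pos)
        scores = {p: means.get(p, np.nan) for p in model.predictors}
        combined = score_optimized(scores, model)
        display = float(combined.display_value)
        out.append(
            ResiduePotential(
                position=pos,
                per_software=means,
                n_sr=counts,
                combined=float(combined.raw_value),
                display=display,
                bin=assign_bins(display, model.display_max),
            )
        )
    return out


def export_map(
    potentials: Sequence[ResiduePotential],
    domains: DomainAnnotation,
    path: str | Path,
    colors_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Write the per-residue hotspot TSV (position, domain, display, bin).

    Residues of the annotated protein with no computed potential are
    emitted with an empty value and bin 0, so the map always covers
    1..protein_length.  Positions beyond the annotation get a warning and
    an empty domain field.  Optionally also writes a flat
    ``position<TAB>hex-color`` file for structure viewers.
    """
    by_pos = {p.position: p for p in potentials}
    for pos in by_pos:
        if pos > domains.protein_length:
            logger.warning(
                "position %d outside annotated protein length %d",
                pos,
                domains.protein_length,
            )
    rows = []
    all_positions = sorted(set(range(1, domains.protein_length + 1)) | set(by_pos))
    for pos in all_positions:
        p = by_pos.get(pos)
        domain = domains.domain_of(pos) if pos <= domains.protein_length else None
        rows.append(
            {
                "position": pos,
                "domain": domain or "",
                "combined_display": "" if p is None else f"{p.display:.4f}",
                "bin": 0 if p is None else p.bin,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    if colors_path is not None:
        with open(colors_path, "w") as fh:
            for row in rows:
                fh.write(f"{row['position']}\t{BIN_COLORS[row['bin']]}\n")
    return df
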