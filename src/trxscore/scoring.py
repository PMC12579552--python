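"""Composite scoring and ranking of candidate two-state models.

A batch of refined candidate models is ranked by a composite score that sums
three min-max-normalized terms — lower is better everywhere:

* R-factor term = R'free + R'work                                  (range 0-2)
* Geometry score = MolProbity' + Ramachandran' + Rotamer' + Cbeta'
  + RMS'bond + RMS'angle + Clash' + RMSD'(B vs A)                  (range 0-8)
* Density score = RSZD' + (1 - RSCC') + (1 - RSZO')                (range 0-3)

where X' = (X - min X) / (max X - min X) over the batch.  The density term
uses a difference-density-weighted RSZD,

    RSZD_n = (1/m) * sum_j [ rho_neg_j * RSZD-_{j,n} + rho_pos_j * RSZD+_{j,n} ],

with per-residue weights rho_pos/rho_neg taken from the isomorphous
difference map, and batch averages of per-residue RSCC and RSZO over the
residues modeled with alternative conformers.

Missing-value policy: a metric column absent for every model is dropped from
the sum with a warning (it cannot discriminate); a metric missing for only
some models pins those models at the worst normalized value 1.0, so
incomplete validation is never rewarded.  A constant column normalizes to
all zeros.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .density import ResidueDensityMetrics, ResidueWeightSet
from .structure import ResidueKey, ValidationError

__all__ = [
    "ModelMetrics",
    "ScoreBreakdown",
    "minmax_normalize",
    "r_factor_term",
    "geometry_score",
    "weighted_rszd",
    "residue_average",
    "density_score",
    "composite_score",
    "rank_models",
    "GEOMETRY_COLUMNS",
]

GEOMETRY_COLUMNS = (
    "molprobity_score",
    "ramachandran_outliers",
    "rotamer_outliers",
    "cbeta_outliers",
    "rms_bond",
    "rms_angle",
    "clashscore",
    "rmsd_AB",
)


@dataclass
class ModelMetrics:
    """All raw validation quantities for one candidate model."""

    model_id: str
    r_work: Optional[float] = None
    r_free: Optional[float] = None
    molprobity_score: Optional[float] = None
    ramachandran_outliers: Optional[float] = None
    rotamer_outliers: Optional[float] = None
    cbeta_outliers: Optional[float] = None
    rms_bond: Optional[float] = None
    rms_angle: Optional[float] = None
    clashscore: Optional[float] = None
    rmsd_AB: Optional[float] = None
    residue_density: Dict[ResidueKey, ResidueDensityMetrics] = field(
        default_factory=dict
    )
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("r_work", "r_free"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValidationError(f"{self.model_id}: {name}={val} outside [0, 1]")

    def set_field(self, name: str, value: float, provenance: str = "native",
                  prefer: Optional[str] = None) -> None:
        current = getattr(self, name)
        if current is not None and self.provenance.get(name) != provenance:
            if prefer is None:
                raise ValidationError(
                    f"{self.model_id}.{name}: conflicting native/ingested values; "
                    "pass prefer='native' or prefer='ingested'"
                )
            if prefer != provenance:
                return
        setattr(self, name, value)
        self.provenance[name] = provenance


@dataclass
class ScoreBreakdown:
    model_id: str
    r_factor_term: float
    geometry_score: float
    density_score: float
    weighted_rszd: float
    rscc_bar: Optional[float]
    rszo_bar: Optional[float]
    composite: float
    rank: int = 0
    flags: List[str] = field(default_factory=list)


def minmax_normalize(values: Sequence[Optional[float]]) -> np.ndarray:
    """Min-max scaling S' = (S - min)/(max - min) over a batch pool.

    Missing entries (None/NaN) stay NaN.  A constant pool maps to all zeros
    (the metric then cannot discriminate).
    """
    arr = np.array(
        [math.nan if v is None else float(v) for v in values], dtype=float
    )
    if arr.size == 0:
        raise ValidationError("minmax_normalize: empty pool")
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        return arr  # all missing
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        out = np.where(np.isfinite(arr), 0.0, math.nan)
        return out
    return (arr - lo) / (hi - lo)


def _normalized_column(
    batch: Sequence[ModelMetrics], name: str
) -> Tuple[Optional[np.ndarray], List[str]]:
    """Normalize one metric column; missing-for-some models get 1.0 (worst).

    Returns (column or None if absent for all, flags).
    """
    raw = [getattr(m, name) for m in batch]
    flags: List[str] = []
    if all(v is None or (isinstance(v, float) and math.isnan(v)) for v in raw):
        warnings.warn(f"metric {name!r} missing for every model; "
                      "dropped from the score", stacklevel=3)
        return None, [f"dropped:{name}"]
    norm = minmax_normalize(raw)
    missing = ~np.isfinite(norm)
    if np.any(missing):
        for m, is_missing in zip(batch, missing):
            if is_missing:
                flags.append(f"missing:{name}:{m.model_id}")
        norm = np.where(missing, 1.0, norm)
    return norm, flags


def r_factor_term(batch: Sequence[ModelMetrics]) -> np.ndarray:
    """R'free + R'work per model (each min-max normalized over the batch)."""
    if sum(m.r_free is not None for m in batch) < 2 or \
       sum(m.r_work is not None for m in batch) < 2:
        raise ValidationError("r_factor_term needs r_work and r_free for >=2 models")
    free, _ = _normalized_column(batch, "r_free")
    work, _ = _normalized_column(batch, "r_work")
    return free + work


def geometry_score(batch: Sequence[ModelMetrics]) -> Tuple[np.ndarray, List[str]]:
    """Sum of the eight normalized geometry terms; absent columns contribute 0."""
    if len(batch) < 2:
        raise ValidationError("geometry_score needs a batch of >=2 models")
    total = np.zeros(len(batch))
    flags: List[str] = []
    for name in GEOMETRY_COLUMNS:
        col, col_flags = _normalized_column(batch, name)
        flags.extend(col_flags)
        if col is not None:
            total = total + col
    return total, flags


def weighted_rszd(
    batch: Sequence[ModelMetrics], weights: ResidueWeightSet
) -> np.ndarray:
    """Difference-density-weighted RSZD per model.

    RSZD_n = (1/m) sum_j [rho_neg_j * RSZD-_{j,n} + rho_pos_j * RSZD+_{j,n}]
    over the m residues of the weight set (zero-weight residues count in m).
    RSZD+ and RSZD- enter as non-negative magnitudes.
    """
    if weights.m == 0:
        raise ValidationError("weighted_rszd: empty weight set")
    out = np.zeros(len(batch))
    for n, model in enumerate(batch):
        acc = 0.0
        for key in weights.keys():
            metrics = model.residue_density.get(key)
            if metrics is None:
                raise ValidationError(
                    f"{model.model_id}: no residue density metrics for {key}"
                )
            acc += (
                weights.rho_neg[key] * abs(metrics.rszd_minus)
                + weights.rho_pos[key] * abs(metrics.rszd_plus)
            )
        out[n] = acc / weights.m
    return out


def residue_average(
    batch: Sequence[ModelMetrics], metric: str
) -> Tuple[np.ndarray, List[str]]:
    """Per-model average of a residue-level metric ('rscc' or 'rszo').

    Averages over the residues carrying alternative conformers; residues with
    a missing value are excluded with the divisor adjusted and flagged.
    """
    if metric not in ("rscc", "rszo"):
        raise ValueError(f"metric must be 'rscc' or 'rszo', got {metric!r}")
    out = np.full(len(batch), math.nan)
    flags: List[str] = []
    for n, model in enumerate(batch):
        vals = []
        for key, rm in model.residue_density.items():
            v = getattr(rm, metric)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                flags.append(f"excluded:{metric}:{model.model_id}:{key}")
                continue
            vals.append(v)
        if not vals:
            raise ValidationError(
                f"{model.model_id}: no residue-level {metric} values"
            )
        out[n] = float(np.mean(vals))
    return out, flags


def density_score(
    batch: Sequence[ModelMetrics], weights: ResidueWeightSet
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, List[str]]:
    """RSZD' + (1 - RSCC') + (1 - RSZO') per model.

    Returns (score, weighted_rszd_raw, rscc_bar, rszo_bar, flags).
    """
    if len(batch) < 2:
        raise ValidationError("density_score needs a batch of >=2 models")
    rszd_n = weighted_rszd(batch, weights)
    rscc_bar, f1 = residue_average(batch, "rscc")
    rszo_bar, f2 = residue_average(batch, "rszo")
    score = (
        minmax_normalize(rszd_n)
        + (1.0 - minmax_normalize(rscc_bar))
        + (1.0 - minmax_normalize(rszo_bar))
    )
    return score, rszd_n, rscc_bar, rszo_bar, f1 + f2


def composite_score(
    batch: Sequence[ModelMetrics], weights: ResidueWeightSet
) -> List[ScoreBreakdown]:
    """Composite = R-factor term + Geometry score + Density score, per model."""
    rf = r_factor_term(batch)
    geo, gflags = geometry_score(batch)
    dens, rszd_raw, rscc_bar, rszo_bar, dflags = density_score(batch, weights)
    out = []
    for n, model in enumerate(batch):
        composite = float(rf[n] + geo[n] + dens[n])
        out.append(ScoreBreakdown(
            model_id=model.model_id,
            r_factor_term=float(rf[n]),
            geometry_score=float(geo[n]),
            density_score=float(dens[n]),
            weighted_rszd=float(rszd_raw[n]),
            rscc_bar=float(rscc_bar[n]),
            rszo_bar=float(rszo_bar[n]),
            composite=composite,
            flags=[f for f in gflags + dflags if f"{model.model_id}" in f
                   or f.startswith("dropped:")],
        ))
    return out


def rank_models(
    breakdowns: Sequence[ScoreBreakdown],
    batch: Optional[Sequence[ModelMetrics]] = None,
) -> List[ScoreBreakdown]:
    """Ascending composite; ties broken by lower r_free, then model_id.

    Returns a new list with 1-based ``rank`` fields filled in.
    """
    if not breakdowns:
        raise ValidationError("rank_models: empty input")
    rfree = {}
    if batch is not None:
        rfree = {m.model_id: m.r_free for m in batch}

    def sort_key(b: ScoreBreakdown):
        rf = rfree.get(b.model_id)
        return (b.composite, rf if rf is not None else math.inf, b.model_id)

    ordered = sorted(breakdowns, key=sort_key)
    for i, b in enumerate(ordered, start=1):
        b.rank = i
    return ordered
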