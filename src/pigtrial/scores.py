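"""Bedside scalar scores: microglial ramification index, SIRI, aEEG handling.

The ramification index (RI) summarises microglial morphology from a grid
count made over one field of view: a 50 µm × 50 µm sampling grid with 3
horizontal and 3 vertical lines is placed on the field, and the number of
Iba1+ process-gridline intersections and the number of complete somata
inside the grid are counted.  RI = intersections² / somata; ramified
(resting) microglia score high, amoeboid (activated) microglia score low.

The systemic inflammation response index (SIRI) is
neutrophils × monocytes / lymphocytes from a full blood count.

aEEG background activity is scored hourly on the 0 (isoelectric) to
4 (continuous normal voltage) scale and aggregated into 6-hour epochs
before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridCount",
    "BloodCounts",
    "VoltageCriteria",
    "ramification_index",
    "region_ri",
    "siri",
    "aggregate_eeg",
    "classify_background",
]

#: fixed vocabulary of assessed brain regions
REGIONS = ("cCTX", "sCTX", "PvWM", "IC", "Hip", "CAUD", "PTMN", "THAL")

#: expected number of fields of view per region (hippocampus appears in one
#: coronal section only, so half the fields)
EXPECTED_FIELDS = {r: 6 for r in REGIONS}
EXPECTED_FIELDS["Hip"] = 3


@dataclass(frozen=True)
class GridCount:
    """Counts from one sampling-grid field of view."""

    intersections: int
    somata: int
    field_id: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        for name in ("intersections", "somata"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class BloodCounts:
    """Full-blood-count cell concentrations in 1e9 cells/L."""

    neutrophils: float
    monocytes: float
    lymphocytes: float
    platelets: float = np.nan
    timepoint_h: float = np.nan

    def __post_init__(self) -> None:
        for name in ("neutrophils", "monocytes", "lymphocytes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class UndefinedScoreError(ValueError):
    """A score is mathematically undefined for this input (e.g. 0 somata)."""


def ramification_index(g: GridCount) -> float:
    """RI = intersections² / somata for one field.

    Fields with no intact somata are undefined and must be excluded upstream
    (raises :class:`UndefinedScoreError`), never silently scored 0: including
    them would bias the regional mean downward.
    """
    if g.somata == 0:
        raise UndefinedScoreError(
            f"ramification index undefined for field {g.field_id!r}: 0 intact somata"
        )
    return float(g.intersections) ** 2 / float(g.somata)


def region_ri(fields: Sequence[GridCount], region: str) -> tuple[float, int]:
    """Mean per-field RI over the valid (somata >= 1) fields of one region.

    Returns ``(mean_ri, n_valid_fields)``.  Warns when the number of valid
    fields differs from the sampling design (3 for hippocampus, 6 elsewhere).
    """
    valid = [f for f in fields if f.somata >= 1]
    if not valid:
        raise UndefinedScoreError(f"region {region!r}: no field with >=1 soma")
    expected = EXPECTED_FIELDS.get(region)
    if expected is not None and len(valid) != expected:
        warnings.warn(
            f"region {region!r}: {len(valid)} valid fields, design expects {expected}",
            stacklevel=2,
        )
    ri = [ramification_index(f) for f in valid]
    return float(np.mean(ri)), len(valid)


def siri(b: BloodCounts) -> float:
    """Systemic inflammation response index: neutrophils × monocytes / lymphocytes."""
    if b.lymphocytes == 0:
        raise UndefinedScoreError("SIRI undefined: lymphocyte count is 0")
    return b.neutrophils * b.monocytes / b.lymphocytes


def aggregate_eeg(hourly: Sequence[float], epoch_h: int = 6) -> pd.DataFrame:
    """Aggregate hourly aEEG background scores into consecutive epochs.

    Parameters
    ----------
    hourly
        Hourly scores in {0..4}; ``NaN``/``None`` marks a missing hour,
        which is excluded from its epoch mean (the count of contributing
        hours is recorded).
    epoch_h
        Epoch length in hours (default 6, the study's aggregation interval).

    Returns
    -------
    DataFrame with columns ``epoch`` (0-based), ``start_h``, ``mean_score``,
    ``n_hours`` (non-missing hours contributing) and ``partial`` (True for a
    trailing incomplete epoch).
    """
    scores = np.asarray([np.nan if s is None else s for s in hourly], dtype=float)
    if scores.size == 0:
        raise ValueError("empty score sequence")
    obs = scores[~np.isnan(scores)]
    if obs.size and (np.any(obs < 0) | np.any(obs > 4)):
        raise ValueError("scores must lie in [0, 4]")
    if scores.size < epoch_h:
        raise ValueError(f"need at least one complete {epoch_h}-h epoch, got {scores.size} h")
    rows = []
    for e in range(int(np.ceil(scores.size / epoch_h))):
        block = scores[e * epoch_h : (e + 1) * epoch_h]
        n = int(np.sum(~np.isnan(block)))
        rows.append(
            {
                "epoch": e,
                "start_h": e * epoch_h,
                "mean_score": float(np.nanmean(block)) if n else np.nan,
                "n_hours": n,
                "partial": block.size < epoch_h,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VoltageCriteria:
    """Voltage cutoffs (µV) for background classification.

    The published criteria are cited by reference in the field, so the
    thresholds are configuration, with conventional defaults: continuous
    normal voltage needs lower margin > 5 and upper > 10; a discontinuous
    trace keeps upper > 10 with depressed lower margin; an isoelectric
    trace stays below 2 µV.
    """

    isoelectric_upper: float = 2.0
    low_voltage_upper: float = 10.0
    normal_lower: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.isoelectric_upper <= self.low_voltage_upper:
            raise ValueError("require 0 < isoelectric_upper <= low_voltage_upper")


def classify_background(
    lower_margin: float,
    upper_margin: float,
    burst_suppression: bool = False,
    criteria: Optional[VoltageCriteria] = None,
) -> int:
    """Score one hour of aEEG background activity on the 0-4 scale.

    4 continuous normal voltage, 3 discontinuous, 2 burst suppression,
    1 continuous low voltage, 0 isoelectric.
    """
    c = criteria or VoltageCriteria()
    if lower_margin < 0 or upper_margin < 0:
        raise ValueError("voltage margins must be >= 0")
    if lower_margin > upper_margin:
        raise ValueError(
            f"inconsistent margins: lower {lower_margin} > upper {upper_margin}"
        )
    if upper_margin < c.isoelectric_upper:
        return 0
    if burst_suppression:
        return 2
    if upper_margin > c.low_voltage_upper:
        return 4 if lower_margin > c.normal_lower else 3
    return 1
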