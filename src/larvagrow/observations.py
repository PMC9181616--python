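"""Observation records: individual larval lengths, per-time summaries and
rate-versus-temperature measurements."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import FOOD_LABELS
from .exceptions import ValidationError

__all__ = [
    "LengthObservation",
    "SummaryObservation",
    "RateObservation",
    "observations_to_frame",
    "summaries_to_frame",
    "rates_to_frame",
]


@dataclass(frozen=True)
class LengthObservation:
    """One larva's total length at one age under one treatment.

    time: days post-fertilization; length: μm; temperature: °C;
    food: 'fed' | 'non_fed' | 'pre_birth'; stage: setiger count (optional);
    id: replicate label (optional).
    """

    time: float
    length: float
    temperature: float
    food: str
    stage: Optional[int] = None
    id: Optional[str] = None

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"time must be >= 0, got {self.time!r}")
        if not np.isfinite(self.length) or self.length <= 0:
            raise ValidationError(f"length must be > 0, got {self.length!r}")
        if not np.isfinite(self.temperature):
            raise ValidationError(f"temperature must be finite, got {self.temperature!r}")
        if self.food not in FOOD_LABELS:
            raise ValidationError(
                f"food must be one of {FOOD_LABELS}, got {self.food!r}"
            )


@dataclass(frozen=True)
class SummaryObservation:
    """Per-time-point mean/SD/n of larval length (the printed-table form)."""

    time: float
    mean: float
    sd: Optional[float]
    n: int
    temperature: float
    food: str

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"time must be >= 0, got {self.time!r}")
        if not np.isfinite(self.mean) or self.mean <= 0:
            raise ValidationError(f"mean must be > 0, got {self.mean!r}")
        if int(self.n) != self.n or self.n < 1:
            raise ValidationError(f"n must be an integer >= 1, got {self.n!r}")
        object.__setattr__(self, "n", int(self.n))
        if self.n >= 2:
            if self.sd is None or not np.isfinite(self.sd) or self.sd < 0:
                raise ValidationError(
                    f"sd must be present and >= 0 when n >= 2 (t={self.time}, n={self.n})"
                )
        elif self.sd is not None and (not np.isfinite(self.sd) or self.sd < 0):
            raise ValidationError(f"sd must be >= 0 if given, got {self.sd!r}")
        if self.food not in FOOD_LABELS:
            raise ValidationError(
                f"food must be one of {FOOD_LABELS}, got {self.food!r}"
            )


@dataclass(frozen=True)
class RateObservation:
    """A metabolic or performance rate measured at one temperature.

    temperature: K; value: rate in native (or standardized) units;
    dataset: label grouping values that share a common scale;
    standardized: True once the dataset has been divided by its maximum.
    """

    temperature: float
    value: float
    dataset: str = "rates"
    standardized: bool = False

    def __post_init__(self):
        if not np.isfinite(self.temperature) or self.temperature <= 250.0:
            raise ValidationError(
                f"temperature must be > 250 K (Kelvin expected), got {self.temperature!r}"
            )
        if not np.isfinite(self.value):
            raise ValidationError(f"value must be finite, got {self.value!r}")
        if self.standardized and not 0.0 <= self.value <= 1.0:
            raise ValidationError(
                f"standardized values must lie in [0, 1], got {self.value!r}"
            )


def observations_to_frame(obs: Sequence[LengthObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_dpf": [o.time for o in obs],
            "length_um": [o.length for o in obs],
            "temperature_c": [o.temperature for o in obs],
            "food": [o.food for o in obs],
            "stage_setigers": [o.stage for o in obs],
            "id": [o.id for o in obs],
        }
    )


def summaries_to_frame(summaries: Sequence[SummaryObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_dpf": [s.time for s in summaries],
            "mean_um": [s.mean for s in summaries],
            "sd_um": [s.sd for s in summaries],
            "n": [s.n for s in summaries],
            "temperature_c": [s.temperature for s in summaries],
            "food": [s.food for s in summaries],
        }
    )


def rates_to_frame(rates: Sequence[RateObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "temperature_k": [r.temperature for r in rates],
            "value": [r.value for r in rates],
            "dataset": [r.dataset for r in rates],
            "standardized": [r.standardized for r in rates],
        }
    )
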