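"""Synthetic cohorts and rate curves with the structure the analysis assumes.

The cohort generator draws individual larval lengths around the biphasic
growth curve on the sampling schedule of the packaged tables (same days,
group sizes and per-day SDs), so every pipeline stage can be exercised and
calibrated without the unpublished individual-level measurements.  The
rate-curve generator draws standardized-rate observations around the DEB
upper-boundary temperature-correction curve, emulating the
fertilization-success style datasets used to re-estimate the larval
thermal parameters.

Noise model: Gaussian around the model curve, floored at ``min_length``
(lengths) or 0 (rates).  With the table-scale coefficients of variation
the floor changes cohort means by well under 0.1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import PRE_BIRTH, RATE_CURVE_TEMPERATURES_C
from .datasets import fixture_summaries, table3_params
from .exceptions import ValidationError
from .growth import BiphasicParams, biphasic_length
from .observations import LengthObservation, RateObservation, SummaryObservation
from .thermal import ThermalParams, celsius_to_kelvin, standardize_by_max, tc_upper

__all__ = [
    "ScheduleEntry",
    "CohortConfig",
    "RateCurveConfig",
    "default_cohort_config",
    "simulate_cohort",
    "simulate_rate_curves",
]


@dataclass(frozen=True)
class ScheduleEntry:
    """One sampling occasion: day, food label, group size and noise SD (μm)."""

    day: float
    food: str
    n: int
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"schedule n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"schedule sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one simulated rearing cohort.

    ``noise_sd``/``noise_cv`` override the per-day schedule SDs with a
    global value (absolute μm or a coefficient of variation).
    """

    params: BiphasicParams
    schedule: tuple[ScheduleEntry, ...]
    temperature: float = 15.0
    seed: Optional[int] = None
    min_length: float = 50.0
    noise_sd: Optional[float] = None
    noise_cv: Optional[float] = None

    def __post_init__(self):
        if not self.schedule:
            raise ValidationError("schedule must be non-empty")
        if self.min_length <= 0:
            raise ValidationError("min_length must be > 0")
        if self.noise_sd is not None and self.noise_cv is not None:
            raise ValidationError("set at most one of noise_sd / noise_cv")


def default_cohort_config(
    temperature: float = 15.0,
    seed: Optional[int] = None,
    food: Optional[str] = None,
    include_common: bool = True,
    **overrides,
) -> CohortConfig:
    """Study-structured cohort config for one rearing temperature.

    The schedule mirrors the packaged tables (sampling days, group sizes
    and per-day SDs); the generating parameters are the published fits for
    that temperature.  ``food`` restricts the post-birth schedule to one
    condition; pre-birth occasions are always kept.
    """
    params = table3_params(temperature)
    entries = []
    for s in fixture_summaries(temperature, include_common=include_common):
        if food is not None and s.food not in (PRE_BIRTH, food):
            continue
        entries.append(
            ScheduleEntry(day=s.time, food=s.food, n=s.n, sd=s.sd or 0.0)
        )
    return CohortConfig(
        params=params, schedule=tuple(entries), temperature=float(temperature),
        seed=seed, **overrides,
    )


def _entry_sd(cfg: CohortConfig, entry: ScheduleEntry, mean: float) -> float:
    if cfg.noise_sd is not None:
        return cfg.noise_sd
    if cfg.noise_cv is not None:
        return cfg.noise_cv * mean
    return entry.sd


def simulate_cohort(
    cfg: CohortConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[LengthObservation], list[SummaryObservation]]:
    """Draw a cohort of individual lengths plus their exact summaries.

    For each scheduled occasion, n lengths are drawn from a Normal
    centred on the biphasic curve with the occasion's SD, floored at
    ``cfg.min_length``.  The returned summaries are computed from the
    drawn individuals, so mean/SD/n always agree with them exactly.
    Reproducible: a fixed ``cfg.seed`` yields identical output.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = cfg.params
    individuals: list[LengthObservation] = []
    summaries: list[SummaryObservation] = []
    for entry in cfg.schedule:
        if not 0.0 <= entry.day <= 50.0:
            warnings.warn(
                f"schedule day {entry.day} outside the 0-50 dpf study window "
                "(extrapolating the growth curve)",
                stacklevel=2,
            )
        food = None if entry.day <= p.t_b else entry.food
        mean = biphasic_length(entry.day, p, food=food)
        sd = _entry_sd(cfg, entry, mean)
        draws = np.maximum(rng.normal(mean, sd, size=entry.n), cfg.min_length)
        for value in draws:
            individuals.append(
                LengthObservation(
                    time=entry.day, length=float(value),
                    temperature=cfg.temperature, food=entry.food,
                )
            )
        emp_sd = float(np.std(draws, ddof=1)) if entry.n >= 2 else None
        summaries.append(
            SummaryObservation(
                time=entry.day, mean=float(np.mean(draws)), sd=emp_sd,
                n=entry.n, temperature=cfg.temperature, food=entry.food,
            )
        )
    return individuals, summaries


@dataclass(frozen=True)
class RateCurveConfig:
    """Configuration of a simulated rate-versus-temperature dataset."""

    thermal: ThermalParams
    temperatures_c: tuple[float, ...] = RATE_CURVE_TEMPERATURES_C
    noise_sd: float = 0.05
    seed: Optional[int] = None
    dataset: str = "rates"
    standardize: bool = False

    def __post_init__(self):
        if not self.temperatures_c:
            raise ValidationError("temperature list must be non-empty")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def simulate_rate_curves(cfg: RateCurveConfig) -> list[RateObservation]:
    """Draw one rate dataset around the upper-boundary TC curve.

    Evaluates the curve at the configured temperatures (°C, converted
    internally to K), adds Gaussian noise, clips below at 0 and tags the
    dataset label.  ``standardize=True`` additionally divides by the
    realized maximum (see :func:`larvagrow.thermal.standardize_by_max`).
    """
    rng = np.random.default_rng(cfg.seed)
    temps_k = np.asarray(celsius_to_kelvin(list(cfg.temperatures_c)), dtype=float)
    values = np.asarray(tc_upper(temps_k, cfg.thermal), dtype=float)
    values = np.clip(values + rng.normal(0.0, cfg.noise_sd, size=values.size), 0.0, None)
    rates = [
        RateObservation(temperature=float(T), value=float(v), dataset=cfg.dataset)
        for T, v in zip(temps_k, values)
    ]
    return standardize_by_max(rates) if cfg.standardize else rates
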