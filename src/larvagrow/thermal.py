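"""DEB Arrhenius temperature correction (TC) of metabolic rates.

The baseline correction scales a rate measured at the reference temperature
``T_ref`` to temperature ``T`` (both Kelvin)::

    TC(T) = exp(T_A / T_ref - T_A / T)

Outside the thermal tolerance range the correction is damped by boundary
terms (Kooijman 2010).  With both boundaries::

    TC(T) = exp(T_A/T_ref - T_A/T)
            * [1 + exp(T_AL/T_ref - T_AL/T_L) + exp(T_AH/T_H - T_AH/T_ref)]
            / [1 + exp(T_AL/T   - T_AL/T_L) + exp(T_AH/T_H - T_AH/T  )]

and with the upper boundary only (the form fitted here, since no rate data
exist below 5°C) the ``T_AL`` terms drop out.  All forms equal 1 at
``T = T_ref`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import T_AH_K, T_REF_K
from .exceptions import ValidationError
from .observations import RateObservation

__all__ = [
    "ThermalParams",
    "celsius_to_kelvin",
    "tc_arrhenius",
    "tc_upper",
    "tc_full",
    "standardize_by_max",
    "fit_thermal",
]


@dataclass(frozen=True)
class ThermalParams:
    """Arrhenius TC parameter set (all temperatures in Kelvin).

    ``t_a`` is the Arrhenius temperature; ``t_ah``/``t_h`` govern the decay
    beyond the upper tolerance boundary and ``t_al``/``t_l`` beyond the
    lower one (optional, unused when no cold-side data exist).
    """

    t_a: float
    t_ref: float = T_REF_K
    t_ah: Optional[float] = None
    t_h: Optional[float] = None
    t_al: Optional[float] = None
    t_l: Optional[float] = None

    def __post_init__(self):
        for name in ("t_a", "t_ref", "t_ah", "t_h", "t_al", "t_l"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v <= 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
        if self.t_ah is not None and self.t_ah <= self.t_a:
            raise ValidationError(
                f"t_ah ({self.t_ah}) must exceed t_a ({self.t_a})"
            )
        if self.t_l is not None and self.t_h is not None:
            if not self.t_l < self.t_ref < self.t_h:
                raise ValidationError(
                    f"need t_l < t_ref < t_h, got {self.t_l}, {self.t_ref}, {self.t_h}"
                )


def celsius_to_kelvin(t):
    """Convert °C to K (adds 273.15 exactly)."""
    arr = np.asarray(t, dtype=float) + 273.15
    return arr if np.ndim(t) else float(arr)


def _check_kelvin(T) -> np.ndarray:
    arr = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValidationError("temperature must be finite and > 0 K")
    return arr


def tc_arrhenius(T, p: ThermalParams):
    """Baseline Arrhenius correction factor at temperature ``T`` (K).

    Equals 1 at ``T = T_ref`` and is strictly increasing in ``T``.
    """
    arr = _check_kelvin(T)
    out = np.exp(p.t_a / p.t_ref - p.t_a / arr)
    return out if np.ndim(T) else float(out)


def tc_upper(T, p: ThermalParams):
    """Correction with the upper-boundary damping term.

    Requires ``t_ah`` and ``t_h``.  Equals 1 at ``T_ref``; declines beyond
    the upper tolerance boundary ``t_h``.
    """
    if p.t_ah is None or p.t_h is None:
        raise ValidationError("tc_upper requires t_ah and t_h")
    arr = _check_kelvin(T)
    base = np.exp(p.t_a / p.t_ref - p.t_a / arr)
    num = 1.0 + np.exp(p.t_ah / p.t_h - p.t_ah / p.t_ref)
    den = 1.0 + np.exp(p.t_ah / p.t_h - p.t_ah / arr)
    out = base * num / den
    return out if np.ndim(T) else float(out)


def tc_full(T, p: ThermalParams):
    """Correction with both tolerance-boundary terms.

    When the lower boundary is unset (``t_al``/``t_l`` None) the lower
    terms vanish and the result equals :func:`tc_upper`.
    """
    if p.t_ah is None or p.t_h is None:
        raise ValidationError("tc_full requires t_ah and t_h")
    if (p.t_al is None) != (p.t_l is None):
        raise ValidationError("t_al and t_l must be set together")
    arr = _check_kelvin(T)
    base = np.exp(p.t_a / p.t_ref - p.t_a / arr)
    hi_const = np.exp(p.t_ah / p.t_h - p.t_ah / p.t_ref)
    if p.t_al is None:
        lo_num = lo_den = 0.0
    else:
        lo_num = np.exp(p.t_al / p.t_ref - p.t_al / p.t_l)
        lo_den = np.exp(p.t_al / arr - p.t_al / p.t_l)
    num = 1.0 + lo_num + hi_const
    den = 1.0 + lo_den + np.exp(p.t_ah / p.t_h - p.t_ah / arr)
    out = base * num / den
    return out if np.ndim(T) else float(out)


def standardize_by_max(rates: Sequence[RateObservation]) -> list[RateObservation]:
    """Divide each dataset's values by that dataset's maximum.

    Each ``dataset`` label is standardized independently; the maximum maps
    to exactly 1.  Datasets whose maximum is not positive are rejected.
    """
    rates = list(rates)
    out: list[Optional[RateObservation]] = [None] * len(rates)
    labels = {r.dataset for r in rates}
    for label in labels:
        idx = [i for i, r in enumerate(rates) if r.dataset == label]
        peak = max(rates[i].value for i in idx)
        if peak <= 0:
            raise ValidationError(
                f"dataset {label!r} has no positive value; cannot standardize"
            )
        for i in idx:
            r = rates[i]
            out[i] = RateObservation(
                temperature=r.temperature,
                value=r.value / peak,
                dataset=r.dataset,
                standardized=True,
            )
    return [r for r in out if r is not None]


def fit_thermal(
    rates: Sequence[RateObservation],
    t_ah: float = T_AH_K,
    t_ref: float = T_REF_K,
    free_t_ah: bool = False,
    starts=None,
    weights=None,
):
    """Least-squares fit of the upper-boundary TC curve to standardized rates.

    ``t_a`` and ``t_h`` are free (plus ``t_ah`` when ``free_t_ah``); the fit
    is multi-start with the lowest-RSS converged solution winning.  Thin
    wrapper over :class:`larvagrow.estimators.ThermalResponseRegressor`.

    Returns a :class:`larvagrow.fitting.FitResult`.
    """
    from .estimators import ThermalResponseRegressor

    rates = list(rates)
    if not all(r.standardized for r in rates):
        raise ValidationError(
            "rates must be standardized first (see standardize_by_max)"
        )
    X = np.array([[r.temperature] for r in rates])
    y = np.array([r.value for r in rates])
    est = ThermalResponseRegressor(
        t_ah=t_ah, t_ref=t_ref, free_t_ah=free_t_ah, start_grid=starts
    )
    est.fit(X, y, sample_weight=weights)
    return est.result_
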