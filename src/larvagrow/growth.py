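"""Biphasic larval growth model.

Body length follows a von Bertalanffy curve from fertilization until the
first exogenous feeding ("birth" in Dynamic Energy Budget terminology, at
age ``t_b``), and grows exponentially afterwards::

    L(t) = L_inf - (L_inf - L0) * exp(-b * t)          for t <= t_b
    L(t) = L(t_b) * exp(c * (t - t_b))                 for t >  t_b

The exponential phase starts from the von Bertalanffy length at ``t_b``, so
the curve is continuous at the changepoint.  ``L_inf = a / b`` links the
asymptote to the size-specific energy-acquisition rate ``a`` and energy-use
rate ``b``; ``a`` is therefore a derived quantity, never a free parameter.
The post-birth rate ``c`` may differ between feeding regimes and may be
negative (starved larvae shrink).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import FED, NON_FED
from .exceptions import ValidationError

__all__ = ["BiphasicParams", "vb_length", "exp_length", "biphasic_length"]


@dataclass(frozen=True)
class BiphasicParams:
    """Parameter set of the biphasic growth model.

    Parameters
    ----------
    L_inf : float
        Asymptotic length of the von Bertalanffy phase, μm.
    b : float
        von Bertalanffy rate (size-specific energy-use rate), per day.
    L0 : float
        Length at fertilization (t = 0), μm.
    t_b : float
        Age at first feeding, days post-fertilization.
    c_fed, c_nonfed : float, optional
        Exponential growth rate after birth under the fed / non-fed
        regime, per day.  Either may be omitted when not needed; negative
        values (shrinkage) are allowed.
    """

    L_inf: float
    b: float
    L0: float
    t_b: float
    c_fed: Optional[float] = None
    c_nonfed: Optional[float] = None

    #: Derived energy-acquisition rate a = L_inf * b, μm/day.
    a: float = field(init=False)

    def __post_init__(self):
        for name in ("L_inf", "b", "L0", "t_b"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
        if self.L0 >= self.L_inf:
            raise ValidationError(
                f"L0 must be below L_inf (got L0={self.L0}, L_inf={self.L_inf})"
            )
        for name in ("c_fed", "c_nonfed"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValidationError(f"{name} must be finite if set, got {v!r}")
        object.__setattr__(self, "a", self.L_inf * self.b)

    def c_for(self, food: str) -> float:
        """Return the post-birth rate for a feeding regime label."""
        if food == FED:
            c = self.c_fed
        elif food == NON_FED:
            c = self.c_nonfed
        else:
            raise ValidationError(
                f"food must be {FED!r} or {NON_FED!r}, got {food!r}"
            )
        if c is None:
            raise ValidationError(f"no exponential rate set for food={food!r}")
        return c


def _check_times(t, *, minimum: float = 0.0, name: str = "t") -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite")
    if np.any(arr < minimum):
        raise ValidationError(f"{name} must be >= {minimum}")
    return arr


def vb_length(t, params: BiphasicParams):
    """von Bertalanffy length at age ``t`` (days), μm.

    Strictly increasing in ``t`` and bounded above by ``params.L_inf``.
    Accepts scalars or arrays; negative or non-finite ages are rejected.
    """
    arr = _check_times(t)
    out = params.L_inf - (params.L_inf - params.L0) * np.exp(-params.b * arr)
    return out if isinstance(out, np.ndarray) and np.ndim(t) else float(out)


def exp_length(t, params: BiphasicParams, food: str):
    """Post-birth exponential length at age ``t > t_b`` (days), μm.

    Continuous with the von Bertalanffy phase at ``t_b``:
    ``exp_length(t_b + 0) == vb_length(t_b)``.
    """
    arr = _check_times(t)
    if np.any(arr <= params.t_b):
        raise ValidationError(
            f"exp_length requires t > t_b={params.t_b}; got min t={arr.min()}"
        )
    c = params.c_for(food)
    start = params.L_inf - (params.L_inf - params.L0) * np.exp(-params.b * params.t_b)
    out = start * np.exp(c * (arr - params.t_b))
    return out if np.ndim(t) else float(out)


def biphasic_length(t, params: BiphasicParams, food: Optional[str] = None):
    """Length at age ``t`` under the full biphasic model, μm.

    Uses the von Bertalanffy phase for ``t <= t_b`` and the exponential
    phase (rate chosen by ``food``) beyond.  ``food`` may be omitted when
    every requested age lies in the pre-birth phase.
    """
    arr = _check_times(t)
    vb = params.L_inf - (params.L_inf - params.L0) * np.exp(-params.b * arr)
    after = arr > params.t_b
    if not np.any(after):
        return vb if np.ndim(t) else float(vb)
    if food is None:
        raise ValidationError("food condition required for ages beyond t_b")
    c = params.c_for(food)
    start = params.L_inf - (params.L_inf - params.L0) * np.exp(-params.b * params.t_b)
    out = np.where(after, start * np.exp(c * (arr - params.t_b)), vb)
    return out if np.ndim(t) else float(out)
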