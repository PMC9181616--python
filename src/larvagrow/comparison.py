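"""Nested-model comparisons for the biphasic growth fits.

The temperature and food effects are tested with the extra-sum-of-squares
F statistic between a pooled fit and richer per-group fits::

    F = [(RSS_all - RSS_ind) / (n_par_ind - n_par_all)]
        / [RSS_ind / (N - n_par_ind)]

with p the upper-tail probability of F_{df1, df2}, df1 = n_par_ind -
n_par_all and df2 = N - n_par_ind.  The lower-tail value is also carried in
the result for transparency, since some published workflows quote the
cumulative distribution instead.

A Welch unequal-variance t-test on two printed (mean, sd, n) summaries
covers the direct end-point comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .constants import DEFAULT_L0_UM
from .exceptions import LarvagrowError, ValidationError
from .fitting import (
    FitResult,
    _build_design,
    _c_groups_present,
    _fit_design,
    _rows_from_observations,
    _rows_from_summaries,
)
from .observations import SummaryObservation

__all__ = [
    "ComparisonResult",
    "WelchResult",
    "extra_ss_f",
    "compare_temperature_effect",
    "compare_food_effect",
    "welch_t_from_summaries",
]


@dataclass
class ComparisonResult:
    """Extra-sum-of-squares F test between nested fits."""

    F: float
    df1: int
    df2: int
    p: float            # upper tail, P(F_{df1,df2} >= F)
    p_lower: float      # lower tail, for transparency
    rss_all: float
    rss_ind: float
    n_par_all: int
    n_par_ind: int
    N: int
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.F < 0:
            raise ValidationError(f"F must be >= 0, got {self.F}")
        if self.df1 < 1 or self.df2 < 1:
            raise ValidationError(f"invalid degrees of freedom ({self.df1}, {self.df2})")

    def to_dict(self) -> dict:
        return {
            "F": self.F, "df1": self.df1, "df2": self.df2,
            "p": self.p, "p_lower": self.p_lower,
            "rss_all": self.rss_all, "rss_ind": self.rss_ind,
            "n_par_all": self.n_par_all, "n_par_ind": self.n_par_ind,
            "N": self.N,
        }


def extra_ss_f(rss_all, rss_ind, n_par_all, n_par_ind, N) -> ComparisonResult:
    """The F statistic of the nested comparison, with df bookkeeping.

    Preconditions are enforced, never silently repaired: the richer model
    must fit at least as well (``rss_ind <= rss_all``) and
    ``n_par_all < n_par_ind < N``.
    """
    if not np.isfinite(rss_all) or not np.isfinite(rss_ind) or rss_ind < 0:
        raise ValidationError("RSS values must be finite and non-negative")
    if rss_ind > rss_all:
        raise ValidationError(
            f"rss_ind ({rss_ind}) exceeds rss_all ({rss_all}); models not nested"
        )
    if not n_par_all < n_par_ind < N:
        raise ValidationError(
            f"need n_par_all < n_par_ind < N, got {n_par_all}, {n_par_ind}, {N}"
        )
    df1 = int(n_par_ind - n_par_all)
    df2 = int(N - n_par_ind)
    if rss_ind == 0.0:
        F = 0.0 if rss_all == 0.0 else float("inf")
    else:
        F = ((rss_all - rss_ind) / df1) / (rss_ind / df2)
    p_upper = float(stats.f.sf(F, df1, df2))
    return ComparisonResult(
        F=float(F), df1=df1, df2=df2, p=p_upper,
        p_lower=float(stats.f.cdf(F, df1, df2)),
        rss_all=float(rss_all), rss_ind=float(rss_ind),
        n_par_all=int(n_par_all), n_par_ind=int(n_par_ind), N=int(N),
    )


def _rows_any(data, t_b):
    """Rows from a collection of individuals or summaries."""
    data = list(data)
    if not data:
        return []
    if isinstance(data[0], SummaryObservation):
        return _rows_from_summaries(data, t_b)
    return _rows_from_observations(data, t_b)


def _rss_at(design, L0, c_groups, x):
    """RSS of a fixed parameter vector on a design (nesting guard)."""
    from .fitting import _BiphasicModel

    model = _BiphasicModel(design, L0, c_groups)
    return float(np.sum(model.residuals(np.asarray(x, float)) ** 2)) + design.rss0


def compare_temperature_effect(
    obs_by_temperature: Mapping[float, Sequence],
    t_b: Mapping[float, float],
    L0=DEFAULT_L0_UM,
    starts=None,
) -> ComparisonResult:
    """Pooled (3-parameter) vs per-temperature (3 each) biphasic fits.

    ``obs_by_temperature`` maps each rearing temperature to its
    observations (individuals or summaries; food conditions pooled under a
    single c).  The pooled model shares L_inf, b, c across temperatures
    while each observation keeps its temperature's changepoint ``t_b``.
    Group fit failures propagate with the temperature label attached.
    """
    temps = sorted(obs_by_temperature)
    if len(temps) < 2:
        raise ValidationError("need at least two temperature groups")
    fits: dict[float, FitResult] = {}
    designs = {}
    for temp in temps:
        rows = _rows_any(obs_by_temperature[temp], t_b[temp])
        designs[temp] = _build_design(rows)
        try:
            fits[temp] = _fit_design(designs[temp], L0, [-2], starts)
        except LarvagrowError as exc:
            raise type(exc)(f"fit failed for temperature {temp}: {exc}") from exc
    all_rows = [r for temp in temps for r in _rows_any(obs_by_temperature[temp], t_b[temp])]
    pooled_design = _build_design(all_rows)
    pooled = _fit_design(pooled_design, L0, [-2], starts)
    # the per-group models nest the pooled one: never report a worse RSS
    # than the pooled solution evaluated group by group
    x_pooled = [pooled.estimates[k] for k in ("L_inf", "b", "c")]
    rss_ind = 0.0
    for temp in temps:
        embedded = _rss_at(designs[temp], L0, [-2], x_pooled)
        rss_ind += min(fits[temp].rss, embedded)
    N = pooled.N
    n_par_ind = sum(f.n_par for f in fits.values())
    result = extra_ss_f(pooled.rss, rss_ind, pooled.n_par, n_par_ind, N)
    result.details = {"pooled": pooled, "groups": fits}
    return result


def compare_food_effect(
    obs_fed: Sequence,
    obs_nonfed: Sequence,
    t_b: float,
    L0=DEFAULT_L0_UM,
    obs_pre: Sequence = (),
    starts=None,
) -> ComparisonResult:
    """Single-c pooled fit vs shared fit with separate c per food condition.

    The richer model keeps L_inf and b common (no food effect before
    birth) and frees c_fed and c_non_fed, so df1 = 1.  Pre-birth data
    shared by both regimes go in ``obs_pre`` and are counted once.
    """
    rows = (
        _rows_any(obs_pre, t_b) + _rows_any(obs_fed, t_b) + _rows_any(obs_nonfed, t_b)
    )
    design = _build_design(rows)
    groups = _c_groups_present(design)
    if groups != [0, 1]:
        raise ValidationError("both food conditions need post-birth data")
    pooled = _fit_design(design, L0, [-2], starts)
    shared = _fit_design(design, L0, groups, starts)
    x_embedded = [
        pooled.estimates["L_inf"], pooled.estimates["b"],
        pooled.estimates["c"], pooled.estimates["c"],
    ]
    rss_ind = min(shared.rss, _rss_at(design, L0, groups, x_embedded))
    result = extra_ss_f(pooled.rss, rss_ind, pooled.n_par, shared.n_par, pooled.N)
    result.details = {"pooled": pooled, "shared": shared}
    return result


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t_from_summaries(
    s1: SummaryObservation, s2: SummaryObservation
) -> WelchResult:
    """Welch's unequal-variance t-test between two printed summaries.

    Uses the Welch–Satterthwaite degrees of freedom and a two-sided p.
    Both groups need n >= 2.  Two zero-variance groups with equal means
    give t = 0, p = 1.
    """
    for s in (s1, s2):
        if s.n < 2:
            raise ValidationError(f"Welch test needs n >= 2 (got n={s.n} at t={s.time})")
    v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
    if v1 + v2 == 0.0:
        if s1.mean == s2.mean:
            return WelchResult(0.0, float(s1.n + s2.n - 2), 1.0)
        return WelchResult(float("inf"), float(s1.n + s2.n - 2), 0.0)
    t = (s1.mean - s2.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (
        v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1)
    )
    p = float(2.0 * stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)
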