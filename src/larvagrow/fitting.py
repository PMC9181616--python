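"""Multi-start nonlinear least squares for the biphasic growth model.

Fits run on individual lengths or on printed per-time summaries.  The two
are equivalent: with summaries (mean, sd, n) the objective

    RSS = sum_i [ n_i * (mean_i - f(t_i))^2 + (n_i - 1) * sd_i^2 ]

equals the individual-level residual sum of squares whenever the summaries
were computed from the individuals, because the within-time scatter term is
constant in the parameters.  Individuals are therefore treated internally
as summaries with n = 1 and sd = 0.

Standard errors come from the linearized covariance (Jacobian
cross-product scaled by RSS / (N - n_par)); per-parameter two-sided
p-values from the t distribution with N - n_par degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .constants import FED, NON_FED, PRE_BIRTH, DEFAULT_L0_UM
from .exceptions import FitConvergenceError, NonIdentifiableError, ValidationError
from .growth import BiphasicParams, biphasic_length
from .observations import LengthObservation, SummaryObservation

__all__ = [
    "FitResult",
    "fit_biphasic",
    "fit_biphasic_shared",
    "fit_from_summaries",
    "rss_from_summaries",
    "standard_errors",
    "DEFAULT_START_GRID",
]

#: Documented default start grid (L_inf μm, b /d, c /d); overridable everywhere.
DEFAULT_LINF_STARTS = (300.0, 500.0, 800.0, 1200.0)
DEFAULT_B_STARTS = (0.02, 0.1, 0.3, 0.6)
DEFAULT_C_STARTS = (-0.01, 0.005, 0.02)
DEFAULT_START_GRID = tuple(
    (L, b, c)
    for L in DEFAULT_LINF_STARTS
    for b in DEFAULT_B_STARTS
    for c in DEFAULT_C_STARTS
)

#: Relative-improvement threshold below which two starts count as tied
#: (ties resolved by start-grid order).
_TIE_RTOL = 1e-9

_GROUP_CODE = {PRE_BIRTH: -1, FED: 0, NON_FED: 1}


@dataclass
class FitResult:
    """Outcome of a converged multi-start least-squares fit."""

    estimates: dict
    se: dict
    p: dict
    rss: float
    N: int
    n_par: int
    start: tuple
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_par >= self.N:
            raise ValidationError(
                f"need more observations than parameters (N={self.N}, n_par={self.n_par})"
            )
        if self.rss < 0:
            raise ValidationError(f"rss must be >= 0, got {self.rss}")
        for k, v in self.se.items():
            # SEs vanish only in the zero-residual limit
            if not np.isfinite(v) or v < 0 or (self.rss > 0 and v == 0):
                raise ValidationError(f"invalid standard error for {k}: {v}")

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "se": dict(self.se),
            "p": dict(self.p),
            "rss": self.rss,
            "N": self.N,
            "n_par": self.n_par,
            "start": list(self.start),
            "converged": self.converged,
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if not isinstance(v, np.ndarray)
            },
        }


# ---------------------------------------------------------------------------
# internal design: every fit is a weighted fit on (t, y, sd, n, group, t_b)
# ---------------------------------------------------------------------------


@dataclass
class _Design:
    t: np.ndarray       # observation ages, days
    y: np.ndarray       # observed mean lengths, μm
    w: np.ndarray       # weights (n per row)
    group: np.ndarray   # -1 pre-birth / 0 fed / 1 non-fed
    t_b: np.ndarray     # per-row changepoint, days
    rss0: float         # constant within-time scatter term Σ(n-1)sd²
    N: int              # total individuals Σn


def _rows_from_observations(
    obs: Sequence[LengthObservation], t_b
) -> list[tuple]:
    return [(o.time, o.length, 0.0, 1, o.food, t_b) for o in obs]


def _rows_from_summaries(summaries: Sequence[SummaryObservation], t_b) -> list[tuple]:
    rows = []
    for s in summaries:
        if s.n >= 2 and s.sd is None:
            raise ValidationError(f"summary at t={s.time} has n={s.n} but no sd")
        rows.append((s.time, s.mean, s.sd or 0.0, s.n, s.food, t_b))
    return rows


def _build_design(rows: Sequence[tuple]) -> _Design:
    if not rows:
        raise ValidationError("no observations supplied")
    t = np.array([r[0] for r in rows], dtype=float)
    y = np.array([r[1] for r in rows], dtype=float)
    sd = np.array([r[2] for r in rows], dtype=float)
    n = np.array([r[3] for r in rows], dtype=float)
    group = np.array([_GROUP_CODE[r[4]] for r in rows], dtype=int)
    t_b = np.array([float(r[5]) for r in rows], dtype=float)
    after = t > t_b
    if np.any(after & (group < 0)):
        bad = t[after & (group < 0)][0]
        raise ValidationError(
            f"observation at t={bad} is beyond t_b but labelled pre-birth"
        )
    return _Design(
        t=t, y=y, w=n, group=group, t_b=t_b,
        rss0=float(np.sum((n - 1.0) * sd**2)), N=int(n.sum()),
    )


def _check_phases(design: _Design):
    before = np.unique(design.t[design.t <= design.t_b])
    after = np.unique(design.t[design.t > design.t_b])
    if len(before) < 2 or len(after) < 2:
        raise ValidationError(
            "observations must span both phases: need >= 2 distinct times at or "
            f"below t_b and >= 2 beyond it (got {len(before)} and {len(after)})"
        )


#: Physical-plausibility parameter bounds (μm and /d): larvae of this size
#: class cannot have a von Bertalanffy asymptote beyond the centimetre
#: scale, and daily rates beyond these magnitudes are biologically absurd.
#: They keep weakly identified fits finite; well-identified optima lie far
#: inside.
_BOUND_L_INF = (1.0, 1e4)
_BOUND_B = (1e-8, 10.0)
_BOUND_L0 = (1.0, 5e3)
_BOUND_C = (-1.0, 1.0)


class _BiphasicModel:
    """Prediction + analytic Jacobian for a free-parameter layout.

    Layout: [L_inf, b, (L0 if free), c …] with one c per post-birth group
    present (single pooled c, or c_fed/c_non_fed in a shared fit).
    """

    def __init__(self, design: _Design, L0, c_groups: Sequence[int]):
        self.d = design
        self.L0_free = isinstance(L0, str) and L0 == "free"
        if not self.L0_free:
            L0 = float(L0)
            if not np.isfinite(L0) or L0 <= 0:
                raise ValidationError(f"L0 must be > 0 or 'free', got {L0!r}")
        self.L0_fixed = None if self.L0_free else float(L0)
        self.c_groups = list(c_groups)
        self.names = ["L_inf", "b"] + (["L0"] if self.L0_free else []) + [
            "c" if len(self.c_groups) == 1 and self.c_groups[0] == -2 else
            ("c_fed" if g == 0 else "c_non_fed") for g in self.c_groups
        ]
        # c column index per group code; -2 means "one pooled c for all"
        self._c_off = 3 if self.L0_free else 2

    def _unpack(self, x):
        L_inf, b = x[0], x[1]
        L0 = x[2] if self.L0_free else self.L0_fixed
        cs = x[self._c_off:]
        return L_inf, b, L0, cs

    def _c_per_row(self, cs):
        d = self.d
        c_row = np.zeros_like(d.t)
        if self.c_groups == [-2]:
            c_row[:] = cs[0]
        else:
            for j, g in enumerate(self.c_groups):
                c_row[d.group == g] = cs[j]
        return c_row

    def predict(self, x):
        d = self.d
        L_inf, b, L0, cs = self._unpack(x)
        vb = L_inf - (L_inf - L0) * np.exp(-b * d.t)
        start = L_inf - (L_inf - L0) * np.exp(-b * d.t_b)
        c_row = self._c_per_row(cs)
        after = d.t > d.t_b
        return np.where(after, start * np.exp(c_row * (d.t - d.t_b)), vb)

    def residuals(self, x):
        return np.sqrt(self.d.w) * (self.predict(x) - self.d.y)

    def jacobian(self, x):
        d = self.d
        L_inf, b, L0, cs = self._unpack(x)
        c_row = self._c_per_row(cs)
        after = d.t > d.t_b
        dt = d.t - d.t_b
        e_t = np.exp(-b * d.t)
        e_tb = np.exp(-b * d.t_b)
        grow = np.exp(c_row * dt)
        start = L_inf - (L_inf - L0) * e_tb

        dLinf = np.where(after, (1.0 - e_tb) * grow, 1.0 - e_t)
        db = np.where(after, (L_inf - L0) * d.t_b * e_tb * grow, (L_inf - L0) * d.t * e_t)
        cols = [dLinf, db]
        if self.L0_free:
            cols.append(np.where(after, e_tb * grow, e_t))
        if self.c_groups == [-2]:
            cols.append(np.where(after, start * grow * dt, 0.0))
        else:
            for g in self.c_groups:
                mask = after & (d.group == g)
                cols.append(np.where(mask, start * grow * dt, 0.0))
        J = np.column_stack(cols)
        return np.sqrt(self.d.w)[:, None] * J

    def bounds(self):
        lo = [_BOUND_L_INF[0], _BOUND_B[0]]
        hi = [_BOUND_L_INF[1], _BOUND_B[1]]
        if self.L0_free:
            lo.append(_BOUND_L0[0])
            hi.append(_BOUND_L0[1])
        lo += [_BOUND_C[0]] * len(self.c_groups)
        hi += [_BOUND_C[1]] * len(self.c_groups)
        return np.array(lo), np.array(hi)


def _multistart(model, starts, xtol=1e-12, ftol=1e-12):
    """Run least squares from every start; lowest converged RSS wins."""
    starts = list(starts)
    if not starts:
        raise ValidationError("start grid must be non-empty")
    bounds = model.bounds() if hasattr(model, "bounds") else (-np.inf, np.inf)
    best = None
    best_start = None
    n_ok = 0
    diags = []
    for p0 in starts:
        try:
            x0 = np.clip(np.asarray(p0, dtype=float), bounds[0], bounds[1])
            res = optimize.least_squares(
                model.residuals, x0,
                jac=model.jacobian, method="trf", bounds=bounds,
                xtol=xtol, ftol=ftol, gtol=1e-12, max_nfev=2000,
            )
        except Exception as exc:  # singular starts etc.
            diags.append(f"start {tuple(p0)}: {exc}")
            continue
        if not res.success or not np.all(np.isfinite(res.x)):
            diags.append(f"start {tuple(p0)}: no convergence ({res.message})")
            continue
        n_ok += 1
        if best is None or res.cost < best.cost * (1.0 - _TIE_RTOL):
            best = res
            best_start = tuple(p0)
    if best is None:
        raise FitConvergenceError(
            f"no start converged out of {len(starts)}", diagnostics=diags
        )
    return best, best_start, n_ok


def standard_errors(estimates: dict, jacobian: np.ndarray, rss: float, N: int):
    """SEs and two-sided t-test p-values from a linearized covariance.

    ``jacobian`` is the (weighted) Jacobian at the solution; ``N`` the
    number of individuals.  Raises :class:`NonIdentifiableError` when the
    Jacobian cross-product is singular.
    """
    names = list(estimates)
    n_par = len(names)
    if N <= n_par:
        raise ValidationError(f"need N > n_par (N={N}, n_par={n_par})")
    jtj = jacobian.T @ jacobian
    if not np.all(np.isfinite(jtj)):
        raise NonIdentifiableError("non-finite Jacobian at the solution")
    # invert on the correlation scale: parameter magnitudes span many
    # orders (μm vs /d), which inflates the raw condition number
    d = np.sqrt(np.diag(jtj))
    if np.any(d == 0):
        raise NonIdentifiableError(
            "singular Jacobian at the solution; parameters not identifiable"
        )
    corr = jtj / np.outer(d, d)
    if np.linalg.cond(corr) > 1e12:
        raise NonIdentifiableError(
            "singular Jacobian at the solution; parameters not identifiable"
        )
    cov = (np.linalg.inv(corr) / np.outer(d, d)) * (rss / (N - n_par))
    se_arr = np.sqrt(np.diag(cov))
    df = N - n_par
    with np.errstate(divide="ignore"):
        tvals = np.array([estimates[k] for k in names]) / se_arr
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return (
        {k: float(s) for k, s in zip(names, se_arr)},
        {k: float(p) for k, p in zip(names, pvals)},
    )


def _fit_design(design: _Design, L0, c_groups, starts, check_phases=True) -> FitResult:
    if check_phases:
        _check_phases(design)
    if np.unique(design.t).size < 2:
        raise ValidationError("degenerate data: all observation times are equal")
    model = _BiphasicModel(design, L0, c_groups)
    n_par = len(model.names)

    grid = DEFAULT_START_GRID if starts is None else list(starts)
    expanded = []
    for p0 in grid:
        p0 = tuple(p0)
        if len(p0) == 3 and n_par != 3:
            # (L_inf, b, c) triples are broadcast to the actual layout
            L, b, c = p0
            full = [L, b] + ([DEFAULT_L0_UM] if model.L0_free else []) + [c] * len(c_groups)
            expanded.append(tuple(full))
        elif len(p0) == n_par:
            expanded.append(p0)
        else:
            raise ValidationError(
                f"start point {p0} has {len(p0)} entries; expected 3 or {n_par}"
            )
    # drop duplicates, keeping grid order
    seen, uniq = set(), []
    for p0 in expanded:
        if p0 not in seen:
            seen.add(p0)
            uniq.append(p0)

    best, start, n_ok = _multistart(model, uniq)
    rss = float(2.0 * best.cost + design.rss0)
    estimates = {k: float(v) for k, v in zip(model.names, best.x)}
    se, p = standard_errors(estimates, model.jacobian(best.x), rss, design.N)
    return FitResult(
        estimates=estimates, se=se, p=p, rss=rss, N=design.N, n_par=n_par,
        start=start, converged=True,
        diagnostics={"n_starts": len(uniq), "n_converged": n_ok},
    )


def _c_groups_present(design: _Design) -> list[int]:
    after = design.t > design.t_b
    return sorted(set(design.group[after].tolist()))


# ---------------------------------------------------------------------------
# public fitting operations
# ---------------------------------------------------------------------------


def fit_biphasic(
    obs: Sequence[LengthObservation], t_b: float, L0=DEFAULT_L0_UM, starts=None
) -> FitResult:
    """Fit {L_inf, b, c} to individual lengths with a single pooled c.

    Observations must span both phases (>= 2 distinct times at or below
    ``t_b`` and >= 2 beyond).  All post-birth rows share one exponential
    rate ``c`` regardless of food label, giving 3 free parameters (the
    pooled model of the nested comparisons).
    """
    design = _build_design(_rows_from_observations(obs, t_b))
    return _fit_design(design, L0, [-2], starts)


def fit_biphasic_shared(
    obs_fed: Sequence[LengthObservation],
    obs_nonfed: Sequence[LengthObservation],
    t_b: float,
    L0=DEFAULT_L0_UM,
    obs_pre: Sequence[LengthObservation] = (),
    starts=None,
) -> FitResult:
    """Joint fit with shared L_inf, b and separate c_fed, c_non_fed (4 params).

    Pre-birth observations common to both regimes go in ``obs_pre`` (or in
    exactly one of the two collections) so they are counted once.
    """
    rows = (
        _rows_from_observations(obs_pre, t_b)
        + _rows_from_observations(obs_fed, t_b)
        + _rows_from_observations(obs_nonfed, t_b)
    )
    design = _build_design(rows)
    groups = _c_groups_present(design)
    if groups != [0, 1]:
        raise ValidationError(
            "shared fit needs post-birth data for both food conditions"
        )
    return _fit_design(design, L0, groups, starts)


def rss_from_summaries(
    params: BiphasicParams, summaries: Sequence[SummaryObservation]
) -> float:
    """Individual-equivalent RSS of fixed parameters against summaries.

    Σ n_i (mean_i − f(t_i))² + Σ (n_i − 1) sd_i², where f uses the
    summary's food label for post-birth times.
    """
    total = 0.0
    for s in summaries:
        if s.n >= 2 and s.sd is None:
            raise ValidationError(f"summary at t={s.time} has n={s.n} but no sd")
        food = s.food if s.time > params.t_b and s.food != PRE_BIRTH else None
        pred = biphasic_length(s.time, params, food=food)
        total += s.n * (s.mean - pred) ** 2 + (s.n - 1) * (s.sd or 0.0) ** 2
    return float(total)


def fit_from_summaries(
    summaries: Sequence[SummaryObservation],
    t_b: float,
    L0=DEFAULT_L0_UM,
    starts=None,
    shared: bool = False,
) -> FitResult:
    """Fit the biphasic model to per-time summaries.

    Minimizes :func:`rss_from_summaries`; equals the individual-level fit
    whenever the summaries fully describe the individuals.  ``N = Σ n`` for
    SE and degrees-of-freedom purposes.  ``shared=True`` estimates separate
    c per food condition with common L_inf and b.
    """
    design = _build_design(_rows_from_summaries(summaries, t_b))
    if shared:
        groups = _c_groups_present(design)
        if groups != [0, 1]:
            raise ValidationError(
                "shared fit needs post-birth summaries for both food conditions"
            )
    else:
        groups = [-2]
    return _fit_design(design, L0, groups, starts)
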