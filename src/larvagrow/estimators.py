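"""scikit-learn style estimators wrapping the package's nonlinear fits.

:class:`BiphasicGrowthRegressor` fits the two-phase larval growth curve;
:class:`ThermalResponseRegressor` fits the DEB upper-boundary temperature
correction to standardized rate data.  Both follow the sklearn contract
(``fit``/``predict``, ``get_params``/``set_params``, fitted attributes with
a trailing underscore) and compose with sklearn model-selection tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import DEFAULT_L0_UM, FED, NON_FED, PRE_BIRTH, T_AH_K, T_REF_K
from .exceptions import ValidationError
from .fitting import FitResult, _Design, _fit_design, _multistart, standard_errors
from .growth import BiphasicParams
from .thermal import ThermalParams, tc_upper

__all__ = ["BiphasicGrowthRegressor", "ThermalResponseRegressor"]

#: integer food codes used in feature matrices
FOOD_CODE = {PRE_BIRTH: -1, FED: 0, NON_FED: 1}
_CODE_FOOD = {v: k for k, v in FOOD_CODE.items()}


def _coerce_growth_X(X):
    """Return (t, food_code) arrays from an (n,1)/(n,2) matrix or DataFrame."""
    if isinstance(X, pd.DataFrame):
        t = X["time_dpf"].to_numpy(dtype=float)
        if "food" in X.columns:
            code = np.array([FOOD_CODE[f] for f in X["food"]], dtype=int)
        else:
            code = np.full(t.shape, -1, dtype=int)
        return t, code
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[1] not in (1, 2):
        raise ValidationError(
            "X must be (n_samples, 1) ages or (n_samples, 2) [age, food_code]"
        )
    t = arr[:, 0]
    if arr.shape[1] == 2:
        code = arr[:, 1].astype(int)
        if not set(code.tolist()) <= {-1, 0, 1}:
            raise ValidationError("food codes must be -1 (pre-birth), 0 (fed) or 1 (non-fed)")
    else:
        code = np.full(t.shape, -1, dtype=int)
    return t, code


class BiphasicGrowthRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares regressor for the biphasic growth curve.

    Parameters
    ----------
    t_b : float
        Age at first feeding (changepoint), days post-fertilization.
        An input of the model, never estimated.
    L0 : float or "free"
        Length at t = 0, μm (default: the mean fertilized-oocyte
        diameter).  Pass ``"free"`` to estimate it.
    shared_food : bool
        When True, estimate separate post-birth rates ``c_fed`` and
        ``c_non_fed`` with common ``L_inf`` and ``b`` (4 free parameters);
        otherwise a single pooled ``c`` (3 free parameters).
    start_grid : sequence of tuples, optional
        Multi-start grid; (L_inf, b, c) triples are broadcast to the
        actual parameter layout.  Lowest converged RSS wins, ties by
        grid order.

    Attributes
    ----------
    params_ : BiphasicParams
        Fitted parameter set (single-c fits populate both food rates).
    result_ : FitResult
        Estimates, standard errors, p-values, RSS and bookkeeping.
    """

    def __init__(self, t_b=17.0, L0=DEFAULT_L0_UM, shared_food=False, start_grid=None):
        self.t_b = t_b
        self.L0 = L0
        self.shared_food = shared_food
        self.start_grid = start_grid

    def fit(self, X, y, sample_weight=None, sd=None):
        """Fit to lengths ``y`` (μm) at ages/foods ``X``.

        ``sample_weight`` may carry per-row replicate counts n (summary
        data); ``sd`` the matching per-row standard deviations.
        """
        t, code = _coerce_growth_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValidationError("X and y lengths differ")
        n = (
            np.ones_like(t)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        s = np.zeros_like(t) if sd is None else np.asarray(sd, dtype=float)
        t_b = float(self.t_b)
        design = _Design(
            t=t, y=y, w=n, group=code, t_b=np.full(t.shape, t_b),
            rss0=float(np.sum((n - 1.0) * s**2)), N=int(n.sum()),
        )
        after = t > t_b
        if np.any(after & (code < 0)):
            raise ValidationError("post-birth rows need a fed/non-fed food code")
        if self.shared_food:
            groups = sorted(set(code[after].tolist()))
            if groups != [0, 1]:
                raise ValidationError(
                    "shared_food=True needs post-birth rows for both food conditions"
                )
        else:
            groups = [-2]
        result = _fit_design(design, self.L0, groups, self.start_grid)
        self.result_ = result
        self.estimates_ = result.estimates
        self.se_ = result.se
        self.pvalues_ = result.p
        self.rss_ = result.rss
        self.n_par_ = result.n_par
        self.n_obs_ = result.N
        self.converged_ = result.converged
        self.start_ = result.start
        est = result.estimates
        c_fed = est.get("c_fed", est.get("c"))
        c_nonfed = est.get("c_non_fed", est.get("c"))
        self.params_ = BiphasicParams(
            L_inf=est["L_inf"], b=est["b"],
            L0=est.get("L0", self.L0 if self.L0 != "free" else DEFAULT_L0_UM),
            t_b=t_b, c_fed=c_fed, c_nonfed=c_nonfed,
        )
        return self

    def predict(self, X):
        """Predicted lengths (μm) at the ages/foods in ``X``."""
        if not hasattr(self, "params_"):
            raise ValidationError("estimator is not fitted yet")
        t, code = _coerce_growth_X(X)
        p = self.params_
        vb = p.L_inf - (p.L_inf - p.L0) * np.exp(-p.b * t)
        start = p.L_inf - (p.L_inf - p.L0) * np.exp(-p.b * p.t_b)
        after = t > p.t_b
        if np.any(after & (code < 0)):
            raise ValidationError("post-birth predictions need a food code")
        c_row = np.zeros_like(t)
        for code_val, c in ((0, p.c_fed), (1, p.c_nonfed)):
            mask = after & (code == code_val)
            if np.any(mask):
                if c is None:
                    raise ValidationError(
                        f"no exponential rate fitted for food code {code_val}"
                    )
                c_row[mask] = c
        return np.where(after, start * np.exp(c_row * (t - p.t_b)), vb)


DEFAULT_TA_STARTS = (2000.0, 6000.0, 10000.0, 14000.0)
DEFAULT_TH_STARTS = (291.0, 294.0, 297.0, 300.0)


class _TCModel:
    """Residual/Jacobian bundle for the upper-boundary TC fit."""

    def __init__(self, T, y, w, t_ref, t_ah_fixed):
        self.T = T
        self.y = y
        self.sw = np.sqrt(w)
        self.t_ref = t_ref
        self.t_ah_fixed = t_ah_fixed  # None when t_ah is free

    def _unpack(self, x):
        if self.t_ah_fixed is None:
            return x[0], x[1], x[2]
        return x[0], x[1], self.t_ah_fixed

    def curve(self, x):
        t_a, t_h, t_ah = self._unpack(x)
        base = np.exp(t_a / self.t_ref - t_a / self.T)
        num = 1.0 + np.exp(t_ah / t_h - t_ah / self.t_ref)
        den = 1.0 + np.exp(t_ah / t_h - t_ah / self.T)
        return base * num / den

    def residuals(self, x):
        return self.sw * (self.curve(x) - self.y)

    def jacobian(self, x):
        t_a, t_h, t_ah = self._unpack(x)
        T, t_ref = self.T, self.t_ref
        base = np.exp(t_a / t_ref - t_a / T)
        e_ref = np.exp(t_ah / t_h - t_ah / t_ref)
        e_T = np.exp(t_ah / t_h - t_ah / T)
        num = 1.0 + e_ref
        den = 1.0 + e_T
        tc = base * num / den
        d_ta = tc * (1.0 / t_ref - 1.0 / T)
        g = t_ah / t_h**2  # -d(t_ah/t_h)/dt_h
        d_th = base * ((-g * e_ref) * den - num * (-g * e_T)) / den**2
        cols = [d_ta, d_th]
        if self.t_ah_fixed is None:
            h_ref = 1.0 / t_h - 1.0 / t_ref
            h_T = 1.0 / t_h - 1.0 / T
            d_tah = base * (h_ref * e_ref * den - num * h_T * e_T) / den**2
            cols.append(d_tah)
        return self.sw[:, None] * np.column_stack(cols)

    def bounds(self):
        # wide physical windows: T_A within ecological Arrhenius range,
        # T_H within liquid-water habitat temperatures
        lo = [100.0, 255.0]
        hi = [1e6, 400.0]
        if self.t_ah_fixed is None:
            lo.append(1e3)
            hi.append(1e7)
        return np.array(lo), np.array(hi)


class ThermalResponseRegressor(RegressorMixin, BaseEstimator):
    """Fits the DEB upper-boundary temperature correction to rate data.

    ``t_a`` (Arrhenius temperature) and ``t_h`` (upper tolerance boundary)
    are free; ``t_ah`` is held fixed by default (it is poorly identified
    from sparse rate curves) but may be freed with ``free_t_ah=True``.
    X holds temperatures in Kelvin, y the standardized rates.
    """

    def __init__(self, t_ah=T_AH_K, t_ref=T_REF_K, free_t_ah=False, start_grid=None):
        self.t_ah = t_ah
        self.t_ref = t_ref
        self.free_t_ah = free_t_ah
        self.start_grid = start_grid

    def fit(self, X, y, sample_weight=None):
        T = np.asarray(X, dtype=float)
        if T.ndim == 2:
            if T.shape[1] != 1:
                raise ValidationError("X must be a single column of temperatures (K)")
            T = T[:, 0]
        y = np.asarray(y, dtype=float)
        if y.shape != T.shape:
            raise ValidationError("X and y lengths differ")
        if np.any(T <= 0):
            raise ValidationError("temperatures must be positive Kelvin")
        if np.unique(T).size < 4:
            raise ValidationError(
                "need >= 4 distinct temperatures to identify t_a and t_h"
            )
        w = (
            np.ones_like(y)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        model = _TCModel(T, y, w, float(self.t_ref),
                         None if self.free_t_ah else float(self.t_ah))
        if self.start_grid is not None:
            grid = [tuple(p) for p in self.start_grid]
        else:
            grid = [
                (ta, th) for ta in DEFAULT_TA_STARTS for th in DEFAULT_TH_STARTS
            ]
            if self.free_t_ah:
                grid = [(ta, th, float(self.t_ah)) for ta, th in grid]
        best, start, n_ok = _multistart(model, grid)
        rss = float(2.0 * best.cost)
        names = ["t_a", "t_h"] + (["t_ah"] if self.free_t_ah else [])
        estimates = {k: float(v) for k, v in zip(names, best.x)}
        se, p = standard_errors(estimates, model.jacobian(best.x), rss, len(y))
        self.result_ = FitResult(
            estimates=estimates, se=se, p=p, rss=rss, N=len(y),
            n_par=len(names), start=start, converged=True,
            diagnostics={"n_starts": len(grid), "n_converged": n_ok},
        )
        self.estimates_ = estimates
        self.se_ = se
        self.pvalues_ = p
        self.rss_ = rss
        self.thermal_params_ = ThermalParams(
            t_a=estimates["t_a"], t_ref=float(self.t_ref),
            t_ah=estimates.get("t_ah", float(self.t_ah)), t_h=estimates["t_h"],
        )
        return self

    def predict(self, X):
        """Correction-factor values at temperatures ``X`` (K)."""
        if not hasattr(self, "thermal_params_"):
            raise ValidationError("estimator is not fitted yet")
        T = np.asarray(X, dtype=float)
        if T.ndim == 2:
            T = T[:, 0]
        return np.asarray(tc_upper(T, self.thermal_params_))
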