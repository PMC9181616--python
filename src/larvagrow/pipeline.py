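"""End-to-end analysis: growth fits → nested comparisons → thermal curve.

``run_pipeline`` mirrors the study workflow: a shared-parameter biphasic
fit per rearing temperature, the temperature-effect F test, the per
temperature food-effect F tests, standardization of rate-versus-
temperature data and — when rates spanning at least four temperatures are
available — the re-estimation of the larval Arrhenius temperature and
upper tolerance boundary.  The report is a plain JSON-serializable dict;
every decision (winning start, convergence, df bookkeeping, fixed
constants) is recorded in its ``log``.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence

from .comparison import compare_food_effect, compare_temperature_effect
from .constants import FED, NON_FED, PRE_BIRTH
from .datasets import fixture_summaries
from .exceptions import LarvagrowError, ValidationError
from .fitting import FitResult, fit_from_summaries
from .io import AnalysisConfig, read_observations, read_rates, read_summaries
from .observations import LengthObservation, SummaryObservation, RateObservation
from .thermal import fit_thermal, standardize_by_max

__all__ = ["run_pipeline"]


def _split_by_food(data):
    groups = {PRE_BIRTH: [], FED: [], NON_FED: []}
    for item in data:
        groups[item.food].append(item)
    return groups


def _load_inputs(cfg: AnalysisConfig, log):
    """Return {temperature: [records]} from config paths or packaged tables."""
    if cfg.observations_path:
        records = read_observations(cfg.observations_path)
        log.append(f"loaded {len(records)} individual observations from {cfg.observations_path}")
    elif cfg.summaries_path:
        records = read_summaries(cfg.summaries_path)
        log.append(f"loaded {len(records)} summary rows from {cfg.summaries_path}")
    else:
        records = [
            s for t in sorted(cfg.t_b) for s in fixture_summaries(t)
        ]
        log.append("no input paths set; using the packaged reference tables")
    by_temp = defaultdict(list)
    for r in records:
        by_temp[float(r.temperature)].append(r)
    return dict(sorted(by_temp.items()))


def _fit_result_report(fit: FitResult) -> dict:
    rep = fit.to_dict()
    est = fit.estimates
    if "L_inf" in est and "b" in est:
        rep["derived"] = {"a": est["L_inf"] * est["b"]}
    return rep


def run_pipeline(cfg: Optional[AnalysisConfig] = None) -> dict:
    """Execute the full analysis described by ``cfg`` and return the report.

    Any stage failure aborts with the stage name attached.
    """
    cfg = cfg or AnalysisConfig()
    log: list[str] = [
        f"constants: L0={cfg.L0} um, t_ref={cfg.t_ref} K, t_ah={cfg.t_ah} K, "
        f"t_b map={ {k: v for k, v in sorted(cfg.t_b.items())} }",
    ]
    report: dict = {"config": cfg.to_dict(), "log": log}

    stage = "load inputs"
    try:
        by_temp = _load_inputs(cfg, log)

        stage = "growth fits per temperature"
        growth: dict = {}
        for temp, records in by_temp.items():
            t_b = cfg.t_b[temp]
            groups = _split_by_food(records)
            summaries = _as_summaries(records)
            has_both = any(s.time > t_b for s in summaries if s.food == FED) and any(
                s.time > t_b for s in summaries if s.food == NON_FED
            )
            fit = fit_from_summaries(
                summaries, t_b=t_b, L0=cfg.L0, starts=cfg.start_grid, shared=has_both
            )
            growth[str(temp)] = _fit_result_report(fit)
            log.append(
                f"{temp} C: {'shared' if has_both else 'pooled'} fit, "
                f"winning start {fit.start}, rss={fit.rss:.1f}, N={fit.N}"
            )

        stage = "temperature comparison"
        if len(by_temp) >= 2:
            cmp_t = compare_temperature_effect(
                by_temp, cfg.t_b, L0=cfg.L0, starts=cfg.start_grid
            )
            report["temperature_effect"] = cmp_t.to_dict()
            log.append(
                f"temperature F({cmp_t.df1}, {cmp_t.df2}) = {cmp_t.F:.3f}, p = {cmp_t.p:.3g}"
            )
        else:
            log.append("temperature comparison skipped (single temperature)")

        stage = "food comparisons"
        food_cmp = {}
        for temp, records in by_temp.items():
            groups = _split_by_food(records)
            t_b = cfg.t_b[temp]
            fed_post = [r for r in groups[FED]]
            non_post = [r for r in groups[NON_FED]]
            if not fed_post or not non_post:
                log.append(f"{temp} C: food comparison skipped (one condition)")
                continue
            cmp_f = compare_food_effect(
                fed_post, non_post, t_b, L0=cfg.L0,
                obs_pre=groups[PRE_BIRTH], starts=cfg.start_grid,
            )
            food_cmp[str(temp)] = cmp_f.to_dict()
            log.append(
                f"{temp} C: food F({cmp_f.df1}, {cmp_f.df2}) = {cmp_f.F:.3f}, p = {cmp_f.p:.3g}"
            )
        if food_cmp:
            report["food_effect"] = food_cmp

        stage = "thermal fit"
        rates: list[RateObservation] = []
        if cfg.rates_path:
            rates.extend(read_rates(cfg.rates_path))
            log.append(f"loaded {len(rates)} rate rows from {cfg.rates_path}")
        rates.extend(_rates_from_growth(growth, by_temp, log))
        std = standardize_by_max([r for r in rates if not r.standardized]) + [
            r for r in rates if r.standardized
        ]
        n_temps = len({round(r.temperature, 6) for r in std})
        if n_temps >= 4:
            thermal_fit = fit_thermal(
                std, t_ah=cfg.t_ah, t_ref=cfg.t_ref, starts=cfg.thermal_start_grid
            )
            report["thermal"] = thermal_fit.to_dict()
            log.append(
                f"thermal fit over {n_temps} temperatures: "
                f"t_a={thermal_fit.estimates['t_a']:.1f} K, "
                f"t_h={thermal_fit.estimates['t_h']:.2f} K (t_ah fixed at {cfg.t_ah})"
            )
        else:
            log.append(
                f"thermal fit skipped: only {n_temps} distinct temperatures "
                "(need >= 4; supply a rates CSV to enable)"
            )
        report["growth"] = growth
    except LarvagrowError as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc
    return report


def _as_summaries(records: Sequence) -> list[SummaryObservation]:
    """View individuals as n=1 summaries so one fit path serves both."""
    out = []
    for r in records:
        if isinstance(r, SummaryObservation):
            out.append(r)
        elif isinstance(r, LengthObservation):
            out.append(
                SummaryObservation(
                    time=r.time, mean=r.length, sd=None, n=1,
                    temperature=r.temperature, food=r.food,
                )
            )
        else:
            raise ValidationError(f"unsupported record type {type(r).__name__}")
    return out


def _rates_from_growth(growth: dict, by_temp: dict, log) -> list[RateObservation]:
    """Growth parameters as rate-vs-temperature datasets (a, b, c per T)."""
    from .thermal import celsius_to_kelvin

    rates = []
    for name, key in (("growth_a", "a"), ("growth_b", "b")):
        for temp_str, rep in growth.items():
            value = (
                rep["derived"]["a"] if key == "a" else rep["estimates"].get("b")
            )
            if value is not None and value > 0:
                rates.append(
                    RateObservation(
                        temperature=celsius_to_kelvin(float(temp_str)),
                        value=float(value), dataset=name,
                    )
                )
    for temp_str, rep in growth.items():
        c = rep["estimates"].get("c_fed", rep["estimates"].get("c"))
        if c is not None and c > 0:
            rates.append(
                RateObservation(
                    temperature=celsius_to_kelvin(float(temp_str)),
                    value=float(c), dataset="growth_c",
                )
            )
    if rates:
        log.append(
            f"derived {len(rates)} rate points from the fitted growth parameters"
        )
    return rates
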