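# larvagrow

Bioenergetic analysis of marine invertebrate larval growth, built around
the early life stages of the lugworm *Arenicola marina*: a biphasic growth
model fitted by multi-start nonlinear least squares, nested-model F tests
for temperature and food effects, and re-estimation of Dynamic Energy
Budget (DEB) Arrhenius temperature-correction parameters from standardized
rate-versus-temperature data.

## The science

Lugworm larvae live on maternal yolk (lecithotrophy) until a functional
gut appears and they start feeding on plankton — the DEB "birth", at age
`t_b`. Body length `L(t)` (μm, `t` in days post-fertilization) follows

```
L(t) = L_inf − (L_inf − L0) · exp(−b·t)          t ≤ t_b   (von Bertalanffy)
L(t) = L(t_b) · exp(c · (t − t_b))               t > t_b   (exponential)
```

with asymptote `L_inf = a/b` linking the size-specific energy-acquisition
rate `a` (μm/day, always derived as `L_inf·b`) and energy-use rate `b`
(/day); `c` (/day) is the post-birth growth rate, which may differ between
feeding regimes and may be negative (starved larvae shrink). The curve is
continuous at the changepoint; `t_b` and `L0` (fertilized-oocyte diameter,
176 μm) are inputs, not fitted.

Treatment effects are tested with the extra-sum-of-squares F statistic
between nested fits,

```
F = [(RSS_all − RSS_ind)/(n_par_ind − n_par_all)] / [RSS_ind/(N − n_par_ind)]
```

with the upper tail of `F(df1, df2)` giving the p-value.

Metabolic rates scale with body temperature `T` (K) by the DEB correction
`TC(T) = exp(T_A/T_ref − T_A/T)`, damped beyond the upper tolerance
boundary `T_H` by the standard Kooijman boundary factor (parameters
`T_AH`, `T_H`). The package fits this curve to rate datasets standardized
by their maxima, with `T_A` and `T_H` free and `T_AH` fixed at 82 380 K —
the procedure used to show that larval stages (subtidal, thermally
stable) carry a higher Arrhenius temperature (~6660 K) and lower upper
boundary (~294.4 K ≈ 21.3 °C) than the intertidal juveniles and adults.

Because the underlying individual measurements are not published, a
first-class synthetic-data module generates cohorts with the study's
exact sampling schedule, group sizes and per-day SDs (packaged reference
tables), so fitting, testing and calibration run end to end without any
download.

## Worked example

```python
import larvagrow as lg

# a cohort with the study's 15 °C sampling design (schedule, ns, SDs)
cfg = lg.default_cohort_config(15.0, seed=42)
obs, summaries = lg.simulate_cohort(cfg)

pre = [o for o in obs if o.food == "pre_birth"]
fed = [o for o in obs if o.food == "fed"]
non = [o for o in obs if o.food == "non_fed"]

fit = lg.fit_biphasic_shared(fed, non, t_b=17.0, obs_pre=pre)
cmp_f = lg.compare_food_effect(fed, non, 17.0, obs_pre=pre)
```

prints (via the estimates/SE fields):

```
simulated 480 larvae over 22 sampling occasions
L_inf        484.7048  (SE 8.5592, p 1.3e-213)
b              0.2563  (SE 0.0215, p 7.3e-29)
c_fed          0.0121  (SE 0.0009, p 5.5e-36)
c_non_fed      0.0054  (SE 0.0010, p 7.1e-08)
a = L_inf*b = 124.21 um/day
food effect: F(1, 476) = 46.32, p = 3.04e-11
```

The generating truth was `L_inf = 481.59`, `b = 0.263`, `c_fed = 0.013`,
`c_non_fed = 0.005`: every parameter is recovered within about one
standard error, and the food effect (fed larvae outgrow starved ones
after birth) is highly significant, as in the original experiment.

The thermal side works the same way:

```python
truth = lg.ThermalParams(t_a=6661.79, t_ah=82380.0, t_h=294.44)
rates = lg.simulate_rate_curves(
    lg.RateCurveConfig(thermal=truth, noise_sd=0.05, seed=42))
tc_fit = lg.fit_thermal(lg.standardize_by_max(rates))
# thermal: T_A = 6516 K (SE 667), T_H = 294.59 K (SE 0.22)
```

Estimator classes (`BiphasicGrowthRegressor`, `ThermalResponseRegressor`)
expose the same fits through the scikit-learn `fit`/`predict` contract,
and a `larvagrow` CLI wraps the pipeline (`simulate-cohort`,
`simulate-rates`, `fit-growth`, `compare`, `fit-tc`, `predict`,
`run-all`).

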