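# Methods

## The biphasic growth model

Larval total length is modelled in two phases joined at the age of first
exogenous feeding ("birth" in DEB terminology), `t_b`:

* **Pre-birth (lecithotrophic):** von Bertalanffy growth
  `L1(t) = L_inf − (L_inf − L0)·exp(−b·t)`, where `L_inf = a/b` is the
  asymptote implied by the size-specific energy-acquisition rate `a`
  (μm/day) and energy-use (maintenance) rate `b` (/day). `a` is always a
  derived quantity (`a = L_inf·b`), never a free parameter.
* **Post-birth (planktotrophic):** exponential growth
  `L2(t) = L1(t_b)·exp(c·(t − t_b))` with rate `c` (/day) specific to the
  feeding regime. Anchoring the exponential at `L1(t_b)` makes the curve
  continuous at the changepoint; the alternative anchor `exp(c·t)`
  sometimes seen in print is discontinuous at `t_b` and over-predicts
  late lengths by ~30%, so the continuous form is used. `c` may be
  negative: starved larvae visibly shrink late in the experiment.

`t_b` is an anatomical observation (concurrent mouth/anus opening and a
functional gut), not an estimate: 21 dpf at 13 °C, 17 dpf at 15 °C and
17 °C. `L0` defaults to the mean fertilized-oocyte diameter (176 μm) and
can optionally be freed; freeing it never worsens the fit but is rarely
identifiable from cohort means alone.

## Fitting

Fits minimize the residual sum of squares by derivative-based least
squares (scipy's trust-region reflective algorithm with an analytic
Jacobian, verified against finite differences in the tests) from a grid
of start points; the converged solution with the lowest RSS wins and ties
are broken by grid order. The default grid is
`L_inf ∈ {300, 500, 800, 1200} μm × b ∈ {0.02, 0.1, 0.3, 0.6}/d ×
c ∈ {−0.01, 0.005, 0.02}/d`, overridable everywhere. Convergence
tolerances are 1e-12 (`xtol`, `ftol`, `gtol`); the tight setting keeps
the two equivalent fit routes (individuals vs summaries, below) within
1e-8 of each other.

Parameters are constrained to wide physical-plausibility windows
(`L_inf ≤ 10⁴ μm`, `b ≤ 10/d`, `|c| ≤ 1/d`): pre-metamorphic polychaete
larvae are sub-millimetre organisms, so these bounds exclude nothing
biologically meaningful. Their role is purely numerical — when a dataset
does not identify the asymptote (see *Limitations*), the profile of RSS
in `L_inf` is monotone and an unbounded optimizer would wander to
infinity; with bounds the fit terminates at the boundary with an honest,
very large standard error.

**Summaries as data.** Printed tables report per-occasion (mean, SD, n).
The objective `Σ nᵢ(meanᵢ − f(tᵢ))² + Σ(nᵢ−1)·sdᵢ²` equals the
individual-level RSS whenever the summaries were computed from the
individuals, because the within-occasion scatter term does not depend on
the parameters. Individuals are therefore handled internally as n = 1
summaries, and summary fits use `N = Σ nᵢ` for all degrees-of-freedom
purposes. The equivalence of the two routes is asserted to 1e-8 in the
tests.

**Standard errors** come from the linearized covariance
`(JᵀJ)⁻¹·RSS/(N − n_par)`; the inversion runs on the correlation-scaled
matrix because parameter magnitudes span seven orders. A scaled condition
number above 1e12 raises an explicit non-identifiability error.
Per-parameter two-sided p-values use the t distribution with `N − n_par`
degrees of freedom.

**Shared fits.** Food has no plausible effect before first feeding, so
the fed/non-fed comparison shares `L_inf` and `b` across regimes and
frees only `c_fed` and `c_non_fed` (4 parameters). Pre-birth data are
passed once (via `obs_pre`) and never double-counted in `N`.

## Nested-model comparisons

The extra-sum-of-squares F statistic compares a pooled fit against richer
per-group fits:

```
F = [(RSS_all − RSS_ind)/df1] / [RSS_ind/df2],
df1 = n_par_ind − n_par_all,  df2 = N − n_par_ind
```

* **Temperature:** three per-temperature fits (3 parameters each, single
  pooled `c`) against one pooled 3-parameter fit → `df1 = 6`. The pooled
  model keeps each observation's own temperature-specific `t_b` (the
  changepoint is an input, and no single pooled value is defensible).
* **Food (per temperature):** the shared 4-parameter fit against the
  pooled single-`c` 3-parameter fit → `df1 = 1`.

P-values use the **upper tail** of the F distribution — the statistically
meaningful direction for a variance-ratio test; the lower-tail value is
carried alongside in every result for transparency, since some published
workflows quote the cumulative distribution function instead. Because
optimizers are inexact, the richer model's RSS is guarded by evaluating
the pooled solution embedded in the richer parameter space and keeping
the better of the two, which preserves the nesting inequality without
ever clamping user-supplied numbers (those are validated and rejected).

Direct end-point contrasts between two (mean, SD, n) summaries use
Welch's unequal-variance t-test with Welch–Satterthwaite degrees of
freedom; with the printed 50-dpf values this reproduces the reported
significance pattern (p ≈ 0.07 at 13 °C, p < 0.001 at 15 °C, p ≈ 0.57 at
17 °C), which the pooled-variance Student test does not.

## Temperature correction

Rates scale with temperature by the Arrhenius factor
`TC(T) = exp(T_A/T_ref − T_A/T)` (`T_ref = 293.15 K`), damped outside the
tolerance range by the standard DEB boundary terms (Kooijman 2010). The
upper-boundary form used for fitting is

```
TC(T) = exp(T_A/T_ref − T_A/T) ·
        [1 + exp(T_AH/T_H − T_AH/T_ref)] / [1 + exp(T_AH/T_H − T_AH/T)]
```

which equals 1 at `T_ref` and declines beyond `T_H`; the five-parameter
form adds the symmetric `T_AL`/`T_L` terms and reduces exactly to the
upper form when the lower boundary is unset. No rate data exist below
5 °C, so the lower boundary is never estimated here.

Each rate dataset (growth parameters per temperature; emulated
fertilization-success curves) is standardized by its own maximum before
fitting, and the raw TC curve is fitted to the standardized values
without renormalization — exactly the procedure used on the real data.
Since TC exceeds 1 between `T_ref` and the peak, standardization by an
observed maximum above `T_ref` compresses the data by the peak value
(~1.06 for the larval parameter set); simulations show this biases the
recovered `T_A` upward by roughly +500–700 K (well within its standard
error of ~1240 K) and `T_H` by < 0.1 K. When the assay temperatures do
not exceed 20 °C the maximum sits at `T_ref`, standardization is the
identity, and noiseless recovery is exact — the identifiability tests use
that configuration.

`T_AH` is poorly identified from sparse rate curves (it was
non-significant when freed on the real data) and is fixed by default at
82 380 K, the value estimated from juvenile/adult rates; `fit_thermal`
exposes `free_t_ah=True` for the first-pass regression. The default start
grid is `T_A ∈ {2000, 6000, 10000, 14000} K × T_H ∈ {291, 294, 297,
300} K`. Mixed datasets are combined unweighted by default; per-point
weights are available for dataset-size weighting.

## The synthetic-data generator

`simulate_cohort` emulates the study's design: for each sampling occasion
of the packaged schedule (the published tables' days, group sizes and
per-day SDs; the three rearing temperatures share the day 1–6
common-rearing occasions), it draws n lengths from a Normal centred on
the biphasic curve, floored at `min_length = 50 μm` (no larva smaller
than a third of an oocyte is measurable). A Gaussian with the occasion's
empirical SD was chosen over a lognormal for transparency: the recovery
targets are means and rates, which the floored Gaussian perturbs by
< 0.1% for typical occasions (closed-form bias, asserted in tests) and by
at most ~0.35% for the two most scattered late non-fed occasions
(CV ≈ 0.45). Summaries are always computed from the drawn individuals,
so mean/SD/n consistency is exact by construction. A global `noise_sd` or
`noise_cv` can replace the per-day SDs — the homoscedastic setting is
what the F-test calibration uses (below). `simulate_rate_curves` draws
Gaussian noise (default SD 0.05 in standardized units) around the TC
curve at the eight assay temperatures {5, 10, 13, 15, 17, 18, 20, 22} °C
and clips at zero.

What the generator does **not** emulate: measurement error correlated
within containers, mortality and its size selectivity, stage-dependent
variance, non-Gaussian tails, or any real fertilization-success values
(those inputs to the original TC fit are unpublished and are emulated
from the fitted curve itself). Passing recovery tests therefore
demonstrate that the estimation machinery is unbiased and calibrated
under the model's own assumptions at the study's design — not that the
model is correct for real larvae.

## Calibration and known limitations

* **F-test size.** Under a homoscedastic null generator (three groups
  from one parameter set, SD 50 μm) the temperature F test rejects at
  ~5% as it should (asserted within [0.01, 0.12] over 200 replicates).
  Under the study's actual per-day SDs — which range from 8 to 258 μm —
  the same test rejects a true null about half the time: the
  extra-sum-of-squares F test assumes iid errors, and strongly
  heteroscedastic cohort data violate that badly. P-values computed from
  such data should be read qualitatively.
* **Asymptote identifiability.** The printed per-occasion means rise
  almost linearly through the pre-birth phase, so refits from the
  packaged summary tables do not identify `L_inf` (the RSS profile in
  `L_inf` is monotone; the fit reports the plausibility bound with an SE
  orders of magnitude above the estimate). The published asymptotes were
  estimated from richer individual-level data (the reported df imply
  more than twice as many individuals as the tables print). The
  post-birth rates `c`, by contrast, are well identified from the tables
  and reproduce the published values to within one SE at every
  temperature.
* **Degenerate inputs.** All-equal observation times, single-phase data,
  empty start grids, unlabelled post-birth rows, missing SDs with n ≥ 2,
  non-positive temperatures and unstandardized rate inputs are rejected
  with explicit validation errors; they are never silently repaired.
* **Problem sizes.** The recovery suites use 50 replicate cohorts per
  growth target, 100 replicate rate curves for the thermal targets and
  200 replicates for the size calibration — enough for the Monte-Carlo
  error of each reported summary to sit well inside the band it is
  compared against.
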