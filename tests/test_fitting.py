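"""Multi-start least squares: recovery, summary/individual equivalence, SEs."""

import numpy as np
import pytest

import larvagrow as lg
from larvagrow.exceptions import NonIdentifiableError, ValidationError
from larvagrow.fitting import _BiphasicModel, _build_design, _rows_from_observations
from larvagrow.observations import LengthObservation, SummaryObservation


def _noiseless_cohort(params, days_pre, days_post, food="fed", n=5):
    obs = []
    for d in days_pre:
        length = lg.vb_length(d, params)
        obs += [
            LengthObservation(time=d, length=length, temperature=15, food="pre_birth")
            for _ in range(n)
        ]
    for d in days_post:
        length = lg.biphasic_length(d, params, food)
        obs += [
            LengthObservation(time=d, length=length, temperature=15, food=food)
            for _ in range(n)
        ]
    return obs


class TestZeroNoiseIdentifiability:
    def test_single_condition_exact_recovery(self, params15):
        obs = _noiseless_cohort(params15, [1, 5, 9, 13, 17], [21, 30, 40, 50])
        fit = lg.fit_biphasic(obs, t_b=params15.t_b)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.estimates["L_inf"] == pytest.approx(params15.L_inf, rel=1e-6)
        assert fit.estimates["b"] == pytest.approx(params15.b, rel=1e-6)
        assert fit.estimates["c"] == pytest.approx(params15.c_fed, rel=1e-6)
        assert fit.n_par == 3 and fit.N == len(obs)

    def test_shared_fit_exact_recovery(self, params15):
        pre = _noiseless_cohort(params15, [1, 5, 9, 13, 17], [])
        fed = _noiseless_cohort(params15, [], [21, 30, 40, 50], food="fed")
        non = _noiseless_cohort(params15, [], [21, 30, 40, 50], food="non_fed")
        fit = lg.fit_biphasic_shared(fed, non, t_b=params15.t_b, obs_pre=pre)
        assert fit.n_par == 4
        assert fit.estimates["c_fed"] == pytest.approx(params15.c_fed, rel=1e-6)
        assert fit.estimates["c_non_fed"] == pytest.approx(params15.c_nonfed, rel=1e-6)

    def test_identical_conditions_give_equal_rates(self, params15):
        pre = _noiseless_cohort(params15, [1, 5, 9, 13, 17], [])
        fed = _noiseless_cohort(params15, [], [21, 30, 40, 50], food="fed")
        non = [
            LengthObservation(time=o.time, length=o.length, temperature=15, food="non_fed")
            for o in fed
        ]
        fit = lg.fit_biphasic_shared(fed, non, t_b=params15.t_b, obs_pre=pre)
        assert fit.estimates["c_fed"] == pytest.approx(
            fit.estimates["c_non_fed"], abs=1e-8
        )


class TestPreconditions:
    def test_single_phase_rejected(self, params15):
        obs = _noiseless_cohort(params15, [1, 5, 9, 13], [])
        with pytest.raises(ValidationError, match="both phases"):
            lg.fit_biphasic(obs, t_b=params15.t_b)

    def test_degenerate_single_time_rejected(self, params15):
        obs = [
            LengthObservation(time=10, length=300 + i, temperature=15, food="pre_birth")
            for i in range(20)
        ]
        with pytest.raises(ValidationError):
            lg.fit_biphasic(obs, t_b=params15.t_b)

    def test_empty_start_grid_rejected(self, params15):
        obs = _noiseless_cohort(params15, [1, 9, 17], [21, 40])
        with pytest.raises(ValidationError, match="non-empty"):
            lg.fit_biphasic(obs, t_b=params15.t_b, starts=[])

    def test_summary_missing_sd_rejected(self):
        with pytest.raises(ValidationError):
            SummaryObservation(time=10, mean=300, sd=None, n=5, temperature=15, food="fed")


class TestSummaryRss:
    def test_zero_when_on_curve(self, params15):
        summaries = [
            SummaryObservation(
                time=d, mean=lg.vb_length(d, params15), sd=0.0, n=4,
                temperature=15, food="pre_birth",
            )
            for d in (1, 5, 9, 13)
        ]
        assert lg.rss_from_summaries(params15, summaries) == pytest.approx(0.0)

    def test_hand_arithmetic(self, params15):
        mean = lg.vb_length(10.0, params15) + 2.0
        s = SummaryObservation(
            time=10.0, mean=mean, sd=3.0, n=5, temperature=15, food="pre_birth"
        )
        # 5 * 2^2 + 4 * 3^2 = 56
        assert lg.rss_from_summaries(params15, [s]) == pytest.approx(56.0)

    def test_matches_individual_rss(self, params15, cohort15):
        obs, summaries = cohort15
        rss_ind = sum(
            (o.length - lg.biphasic_length(
                o.time, params15, None if o.time <= params15.t_b else o.food
            )) ** 2
            for o in obs
        )
        assert lg.rss_from_summaries(params15, summaries) == pytest.approx(
            rss_ind, rel=1e-12
        )


class TestSummaryEquivalence:
    def test_summary_fit_equals_individual_fit(self, cohort15):
        obs, summaries = cohort15
        fed_obs = [o for o in obs if o.food != "non_fed"]
        fed_sum = [s for s in summaries if s.food != "non_fed"]
        fit_ind = lg.fit_biphasic(fed_obs, t_b=17.0)
        fit_sum = lg.fit_from_summaries(fed_sum, t_b=17.0)
        for key in fit_ind.estimates:
            assert fit_sum.estimates[key] == pytest.approx(
                fit_ind.estimates[key], rel=1e-8
            )
        assert fit_sum.rss == pytest.approx(fit_ind.rss, rel=1e-8)
        assert fit_sum.N == fit_ind.N

    def test_single_time_point_rejected(self):
        s = SummaryObservation(time=10, mean=300, sd=5, n=9, temperature=15, food="fed")
        with pytest.raises(ValidationError):
            lg.fit_from_summaries([s], t_b=17.0)


class TestInvariances:
    def test_order_invariance(self, cohort15):
        obs, _ = cohort15
        fit1 = lg.fit_biphasic(obs, t_b=17.0)
        fit2 = lg.fit_biphasic(list(reversed(obs)), t_b=17.0)
        for key in fit1.estimates:
            assert fit2.estimates[key] == pytest.approx(fit1.estimates[key], rel=1e-9)

    def test_nesting_monotonicity(self, cohort15):
        obs, _ = cohort15
        pre = [o for o in obs if o.food == "pre_birth"]
        fed = [o for o in obs if o.food == "fed"]
        non = [o for o in obs if o.food == "non_fed"]
        pooled = lg.fit_biphasic(obs, t_b=17.0)
        shared = lg.fit_biphasic_shared(fed, non, t_b=17.0, obs_pre=pre)
        assert shared.rss <= pooled.rss * (1 + 1e-12)

    def test_free_L0_never_fits_worse(self, cohort15):
        obs, _ = cohort15
        fixed = lg.fit_biphasic(obs, t_b=17.0, L0=176.0)
        free = lg.fit_biphasic(obs, t_b=17.0, L0="free")
        assert free.n_par == fixed.n_par + 1
        assert free.rss <= fixed.rss * (1 + 1e-10)


class TestStandardErrors:
    def test_se_shrinks_with_noise(self, params15):
        rng = np.random.default_rng(5)
        days_pre, days_post = [1, 5, 9, 13, 17], [21, 30, 40, 50]

        def noisy_fit(sd):
            obs = []
            for d in days_pre + days_post:
                food = "pre_birth" if d <= 17 else "fed"
                mu = lg.biphasic_length(d, params15, None if d <= 17 else "fed")
                for v in rng.normal(mu, sd, size=30):
                    obs.append(
                        LengthObservation(time=d, length=max(v, 1.0), temperature=15, food=food)
                    )
            return lg.fit_biphasic(obs, t_b=17.0)

        se_small = noisy_fit(1.0).se["b"]
        se_large = noisy_fit(50.0).se["b"]
        assert se_small < se_large / 10

    def test_se_calibrated_against_replicates(self, params15, small_start_grid):
        # empirical spread of b-hat across seeds within a factor 2 of the
        # mean reported linearized SE
        rng = np.random.default_rng(1234)
        bs, ses = [], []
        for _ in range(30):
            seed = int(rng.integers(0, 2**31 - 1))
            cfg = lg.default_cohort_config(15.0, seed=seed, food="fed")
            obs, _ = lg.simulate_cohort(cfg)
            fit = lg.fit_biphasic(obs, t_b=17.0, starts=small_start_grid)
            bs.append(fit.estimates["b"])
            ses.append(fit.se["b"])
        emp = np.std(bs, ddof=1)
        mean_se = np.mean(ses)
        assert mean_se / 2 < emp < mean_se * 2

    def test_singular_jacobian_raises(self):
        jac = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(NonIdentifiableError):
            lg.standard_errors({"p1": 1.0, "p2": 2.0}, jac, rss=1.0, N=10)


def test_analytic_jacobian_matches_finite_differences(params15):
    obs = _noiseless_cohort(params15, [1, 5, 9, 13, 17], [21, 30, 40, 50], n=2)
    design = _build_design(_rows_from_observations(obs, 17.0))
    model = _BiphasicModel(design, "free", [-2])
    x = np.array([450.0, 0.2, 160.0, 0.012])
    J = model.jacobian(x)
    eps = 1e-6
    for j in range(x.size):
        step = np.zeros_like(x)
        step[j] = eps * max(1.0, abs(x[j]))
        num = (model.residuals(x + step) - model.residuals(x - step)) / (2 * step[j])
        assert np.allclose(J[:, j], num, rtol=1e-5, atol=1e-7)
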