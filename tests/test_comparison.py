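"""Extra-sum-of-squares F tests and the summary-based Welch comparisons."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import larvagrow as lg
from larvagrow.exceptions import ValidationError
from larvagrow.observations import LengthObservation, SummaryObservation


class TestExtraSSF:
    def test_hand_arithmetic_example(self):
        res = lg.extra_ss_f(120.0, 100.0, 3, 9, 1347)
        assert res.F == pytest.approx((20.0 / 6.0) / (100.0 / 1338.0))
        assert res.F == pytest.approx(44.6)
        assert (res.df1, res.df2) == (6, 1338)

    def test_equal_rss_gives_zero_F_unit_p(self):
        res = lg.extra_ss_f(80.0, 80.0, 3, 4, 200)
        assert res.F == 0.0
        assert res.p == 1.0

    @pytest.mark.parametrize(
        "n_all, n_ind, N, expected",
        [
            (3, 9, 1347, (6, 1338)),   # temperature effect
            (3, 4, 560, (1, 556)),     # food effect, optimal temperature
            (3, 4, 289, (1, 285)),     # food effect, cold treatment
            (3, 4, 498, (1, 494)),     # food effect, warm treatment
        ],
    )
    def test_df_bookkeeping_shapes(self, n_all, n_ind, N, expected):
        res = lg.extra_ss_f(2.0, 1.0, n_all, n_ind, N)
        assert (res.df1, res.df2) == expected

    @pytest.mark.parametrize(
        "args",
        [
            (1.0, 2.0, 3, 4, 100),    # richer model fits worse
            (2.0, 1.0, 4, 4, 100),    # no extra parameters
            (2.0, 1.0, 4, 3, 100),    # counts reversed
            (2.0, 1.0, 3, 4, 4),      # N too small
            (-1.0, -2.0, 3, 4, 100),  # negative RSS
        ],
    )
    def test_preconditions_raise_never_clamp(self, args):
        with pytest.raises(ValidationError):
            lg.extra_ss_f(*args)

    @given(
        st.floats(0.0, 1e6),
        st.floats(1e-6, 1e6),
        st.integers(1, 5),
        st.integers(6, 12),
        st.integers(50, 5000),
    )
    def test_matches_formula_on_random_inputs(self, extra, rss_ind, n_all, n_ind, N):
        rss_all = rss_ind + extra
        res = lg.extra_ss_f(rss_all, rss_ind, n_all, n_ind, N)
        df1, df2 = n_ind - n_all, N - n_ind
        F = ((rss_all - rss_ind) / df1) / (rss_ind / df2)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(float(stats.f.sf(F, df1, df2)), rel=1e-12)
        assert res.p_lower == pytest.approx(1.0 - res.p, abs=1e-9)

    def test_scale_invariance(self):
        a = lg.extra_ss_f(120.0, 100.0, 3, 9, 1347)
        b = lg.extra_ss_f(120.0 * 7.3**2, 100.0 * 7.3**2, 3, 9, 1347)
        assert b.F == pytest.approx(a.F, rel=1e-12)


class TestTemperatureComparison:
    def test_requires_two_groups(self, cohort15):
        obs, _ = cohort15
        with pytest.raises(ValidationError):
            lg.compare_temperature_effect({15.0: obs}, {15.0: 17.0})

    def test_distinct_generators_detected(self, small_start_grid):
        groups, t_b = {}, {}
        for temp in (13.0, 15.0, 17.0):
            cfg = lg.default_cohort_config(temp, seed=int(temp * 100))
            groups[temp], _ = lg.simulate_cohort(cfg)
            t_b[temp] = cfg.params.t_b
        res = lg.compare_temperature_effect(groups, t_b, starts=small_start_grid)
        assert res.df1 == 6
        assert res.N == sum(len(v) for v in groups.values())
        assert res.p < 0.001

    def test_scale_invariant_end_to_end(self, small_start_grid):
        groups, t_b = {}, {}
        for temp, seed in ((13.0, 31), (15.0, 32)):
            cfg = lg.default_cohort_config(temp, seed=seed)
            groups[temp], _ = lg.simulate_cohort(cfg)
            t_b[temp] = cfg.params.t_b
        res1 = lg.compare_temperature_effect(groups, t_b, starts=small_start_grid)
        scaled = {
            temp: [
                LengthObservation(
                    time=o.time, length=o.length * 3.0,
                    temperature=o.temperature, food=o.food,
                )
                for o in obs
            ]
            for temp, obs in groups.items()
        }
        grid3 = [(L * 3, b, c) for (L, b, c) in small_start_grid]
        res2 = lg.compare_temperature_effect(scaled, t_b, L0=176.0 * 3, starts=grid3)
        assert res2.F == pytest.approx(res1.F, rel=1e-4)


class TestFoodComparison:
    def test_identical_conditions_give_null_F(self, cohort15, small_start_grid):
        obs, _ = cohort15
        pre = [o for o in obs if o.food == "pre_birth"]
        fed = [o for o in obs if o.food == "fed"]
        mirrored = [
            LengthObservation(time=o.time, length=o.length, temperature=15, food="non_fed")
            for o in fed
        ]
        res = lg.compare_food_effect(
            fed, mirrored, 17.0, obs_pre=pre, starts=small_start_grid
        )
        assert res.F == pytest.approx(0.0, abs=1e-6)
        assert res.df1 == 1

    def test_fed_advantage_detected_at_study_size(self, small_start_grid):
        # generator truth separates the fed and non-fed rates at 15°C
        cfg = lg.default_cohort_config(15.0, seed=88)
        obs, _ = lg.simulate_cohort(cfg)
        pre = [o for o in obs if o.food == "pre_birth"]
        fed = [o for o in obs if o.food == "fed"]
        non = [o for o in obs if o.food == "non_fed"]
        res = lg.compare_food_effect(fed, non, 17.0, obs_pre=pre, starts=small_start_grid)
        assert res.n_par_ind == 4 and res.n_par_all == 3
        assert res.p < 0.001

    def test_single_condition_rejected(self, cohort15):
        obs, _ = cohort15
        fed = [o for o in obs if o.food == "fed"]
        with pytest.raises(ValidationError):
            lg.compare_food_effect(fed, [], 17.0)


class TestWelch:
    def test_cold_treatment_day50(self):
        s1 = SummaryObservation(time=50, mean=659, sd=96, n=12, temperature=13, food="non_fed")
        s2 = SummaryObservation(time=50, mean=800, sd=129, n=5, temperature=13, food="fed")
        res = lg.welch_t_from_summaries(s1, s2)
        assert res.t == pytest.approx(-2.203071214738222, rel=1e-12)
        assert res.p == pytest.approx(0.0702281528954331, rel=1e-9)

    def test_warm_treatment_day50(self):
        s1 = SummaryObservation(time=50, mean=506, sd=212, n=17, temperature=17, food="non_fed")
        s2 = SummaryObservation(time=50, mean=544, sd=186, n=21, temperature=17, food="fed")
        res = lg.welch_t_from_summaries(s1, s2)
        assert res.p == pytest.approx(0.5658968451622816, rel=1e-9)

    def test_identical_summaries(self):
        s = SummaryObservation(time=50, mean=600, sd=50, n=10, temperature=15, food="fed")
        res = lg.welch_t_from_summaries(s, s)
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_equal_means(self):
        s1 = SummaryObservation(time=50, mean=600, sd=0.0, n=5, temperature=15, food="fed")
        s2 = SummaryObservation(time=50, mean=600, sd=0.0, n=7, temperature=15, food="non_fed")
        assert lg.welch_t_from_summaries(s1, s2).p == 1.0

    def test_needs_replication(self):
        s1 = SummaryObservation(time=50, mean=600, sd=None, n=1, temperature=15, food="fed")
        s2 = SummaryObservation(time=50, mean=650, sd=40, n=5, temperature=15, food="non_fed")
        with pytest.raises(ValidationError):
            lg.welch_t_from_summaries(s1, s2)

    def test_matches_scipy(self):
        s1 = SummaryObservation(time=50, mean=487, sd=110, n=23, temperature=15, food="non_fed")
        s2 = SummaryObservation(time=50, mean=746, sd=258, n=22, temperature=15, food="fed")
        ours = lg.welch_t_from_summaries(s1, s2)
        ref = stats.ttest_ind_from_stats(487, 110, 23, 746, 258, 22, equal_var=False)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-12)
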