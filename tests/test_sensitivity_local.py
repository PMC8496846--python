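import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from t1dsim import anova_oneway, local_screen, oat_levels, quartiles, sample_level


class TestOatLevels:
    def test_nine_levels_at_five_percent_steps(self):
        assert oat_levels(100.0) == pytest.approx(
            [80, 85, 90, 95, 100, 105, 110, 115, 120])

    def test_zero_step_degenerates(self):
        assert np.array_equal(oat_levels(100.0, step_frac=0.0), np.full(9, 100.0))

    def test_extremes_span_pm_twenty_percent(self):
        levels = oat_levels(42.0)
        assert levels.min() == pytest.approx(42 * 0.8)
        assert levels.max() == pytest.approx(42 * 1.2)

    def test_nonpositive_default_rejected(self):
        with pytest.raises(ValueError):
            oat_levels(0.0)


class TestSampleLevel:
    def test_zero_sd_is_exact(self):
        rng = np.random.default_rng(0)
        assert sample_level(100.0, 0.0, rng) == 100.0

    def test_moments_of_six_percent_jitter(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_level(100.0, 6.0, rng) for _ in range(10_000)])
        assert draws.mean() == pytest.approx(100.0, abs=0.2)
        assert draws.std() == pytest.approx(6.0, abs=0.2)

    def test_truncated_into_bounds(self):
        rng = np.random.default_rng(2)
        draws = [sample_level(100.0, 50.0, rng, bounds=(90.0, 110.0))
                 for _ in range(500)]
        assert all(90.0 <= d <= 110.0 for d in draws)


class TestQuartiles:
    def test_order_statistic_indices_for_n20(self):
        q1, q2, q3 = quartiles(np.arange(1, 21))
        assert (q1, q3) == (5, 15)          # ceil(.25*20)=5th, ceil(.75*20)=15th
        assert q2 == 10.5

    def test_constant_vector(self):
        assert quartiles([4, 4, 4, 4]) == (4, 4, 4)

    def test_odd_length_median(self):
        assert quartiles(np.arange(1, 22))[1] == 11

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quartiles([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariant(self, xs, rnd):
        shuffled = list(xs)
        rnd.shuffle(shuffled)
        assert quartiles(xs) == quartiles(shuffled)


def _anova_bruteforce(groups):
    """Two-pass sums-of-squares oracle with explicit loops."""
    all_y = [y for g in groups for y in g]
    grand = sum(all_y) / len(all_y)
    ssr = sse = 0.0
    for g in groups:
        gm = sum(g) / len(g)
        ssr += len(g) * (gm - grand) ** 2
        for y in g:
            sse += (y - gm) ** 2
    return ssr, sse


class TestAnova:
    def test_hand_computed_example(self):
        res = anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.SSR == pytest.approx(6.0)
        assert res.SSE == pytest.approx(6.0)
        assert res.F == pytest.approx(3.0)
        assert res.df_between == 2 and res.df_within == 6

    def test_identical_groups(self):
        res = anova_oneway([[1, 1, 1], [1, 1, 1]])
        assert res.F == 0.0 and res.p == 1.0

    def test_dominant_shift_is_significant(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(0, 1, 20)
        res = anova_oneway([g1, g1 + 1000])
        assert res.p < 0.05 and res.significant

    def test_matches_bruteforce_and_scipy(self):
        rng = np.random.default_rng(42)
        groups = [rng.normal(m, 1.0, n) for m, n in ((0, 8), (0.5, 12), (1.2, 9))]
        res = anova_oneway(groups)
        ssr, sse = _anova_bruteforce(groups)
        assert res.SSR == pytest.approx(ssr, rel=1e-12)
        assert res.SSE == pytest.approx(sse, rel=1e-12)
        f_sp, p_sp = stats.f_oneway(*groups)
        assert res.F == pytest.approx(f_sp, rel=1e-10)
        assert res.p == pytest.approx(p_sp, rel=1e-9)

    def test_partition_of_total_variation(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(0, 1, 15) for _ in range(4)]
        res = anova_oneway(groups)
        sst = float(np.sum((np.concatenate(groups)
                            - np.concatenate(groups).mean()) ** 2))
        assert res.SSR + res.SSE == pytest.approx(sst, rel=1e-9)


class TestLocalScreen:
    def test_reduced_screen_with_negative_control(self, aggressive_cfg):
        """The dummy parameter must not test significant; censoring enters as 32."""
        summary, raw = local_screen(
            aggressive_cfg.params, aggressive_cfg,
            param_names=["dummy", "ctl_lifespan_h"],
            n_levels_side=1, n_reps=3, seed=0, max_weeks=6)
        assert set(summary["parameter"]) == {"dummy", "ctl_lifespan_h"}
        dummy = summary.set_index("parameter").loc["dummy"]
        assert not dummy["significant"]
        # 6-week horizon: no onset yet, so every response is the censor value
        assert (raw["onset_week"] == 32.0).all()
        assert len(raw) == 2 * 3 * 3  # params x levels (M=3) x replicates

    def test_design_size_formula(self, quiet_cfg):
        _, raw = local_screen(quiet_cfg.params, quiet_cfg,
                              param_names=["dummy"], n_levels_side=1,
                              n_reps=2, seed=0, max_weeks=0.1)
        assert len(raw) == 3 * 2
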