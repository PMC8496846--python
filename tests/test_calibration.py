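import numpy as np
import pytest

from t1dsim import (ParameterSet, Trajectory, UNKNOWN_PARAMS, fit_score,
                    lhs_sample, weekly_means)
from t1dsim.calibration import select_default


def _traj(values):
    values = np.asarray(values, dtype=float)
    series = {"n_healthy_beta": np.full(values.size, 320.0),
              "n_infiltrating_cd8": values}
    return Trajectory(series=series, onset_week=32.0, censored=True,
                      onset_threshold_frac=0.2, beta_init=320)


class TestLhs:
    def test_stratification_is_exact(self):
        design = lhs_sample({"x": (0.0, 10.0)}, n_strata=10, seed=0)
        s = np.sort(design.samples[:, 0])
        assert all(i <= v < i + 1 for i, v in enumerate(s))

    def test_full_design_occupancy_permutation(self):
        design = lhs_sample(UNKNOWN_PARAMS, n_strata=100, seed=1)
        assert design.samples.shape == (100, 21)
        for j, name in enumerate(design.names):
            lo, hi = design.ranges[j]
            strata = np.floor((design.samples[:, j] - lo) / (hi - lo) * 100)
            assert sorted(strata.astype(int)) == list(range(100))

    def test_single_stratum_uniform_draw(self):
        design = lhs_sample({"x": (2.0, 4.0)}, n_strata=1, seed=2)
        assert 2.0 <= design.samples[0, 0] <= 4.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            lhs_sample({"x": (1.0, 1.0)}, n_strata=10)

    def test_parameter_sets_respect_ranges(self):
        design = lhs_sample(UNKNOWN_PARAMS, n_strata=20, seed=3)
        for ps in design.parameter_sets(ParameterSet()):
            for name, (lo, hi) in UNKNOWN_PARAMS.items():
                assert lo - 0.51 <= getattr(ps, name) <= hi + 0.51


class TestWeeklyMeans:
    def test_constant_series(self):
        traj = _traj(np.full(169 * 15, 7.0))
        assert np.array_equal(weekly_means(traj), np.full(6, 7.0))

    def test_six_requested_weeks(self):
        traj = _traj(np.arange(169 * 15, dtype=float))
        assert weekly_means(traj).shape == (6,)

    def test_linear_ramp_week4_is_672(self):
        traj = _traj(np.arange(169 * 15, dtype=float))
        assert weekly_means(traj)[0] == 672.0

    def test_week_beyond_trajectory_rejected(self):
        traj = _traj(np.zeros(100))
        with pytest.raises(ValueError):
            weekly_means(traj, weeks=(4,))


class TestFitScore:
    def test_perfect_fit(self):
        disc, r2 = fit_score([1, 2, 3], [1, 2, 3])
        assert (disc, r2) == (0.0, 1.0)

    def test_hand_computed_r2_zero(self):
        disc, r2 = fit_score([2, 2, 2], [1, 2, 3])
        assert disc == 2.0 and r2 == 0.0

    def test_hand_computed_discrepancy(self):
        disc, _ = fit_score([1, 2, 4], [1, 2, 3])
        assert disc == 1.0

    def test_zero_variance_data_signalled(self):
        with pytest.raises(ValueError):
            fit_score([1, 2, 3], [2, 2, 2])


class TestSelectDefault:
    def test_single_candidate_returned(self, quiet_cfg):
        best, lb = select_default([quiet_cfg.params], np.zeros(2), quiet_cfg,
                                  n_reps=1, seed=0, weeks=(0.5, 1.0),
                                  max_weeks=1.0)
        assert best == quiet_cfg.params
        assert len(lb) == 1

    def test_leaderboard_covers_all_candidates(self, quiet_cfg):
        cands = [quiet_cfg.params, quiet_cfg.params.replace(dummy=2.0),
                 quiet_cfg.params.replace(dummy=3.0)]
        _, lb = select_default(cands, np.zeros(2), quiet_cfg, n_reps=1,
                               seed=0, weeks=(0.5, 1.0), max_weeks=1.0)
        assert sorted(lb["candidate"]) == [0, 1, 2]
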