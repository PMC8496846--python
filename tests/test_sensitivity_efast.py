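import numpy as np
import pytest

from t1dsim import (analyze_function, build_design, efast_campaign,
                    efast_indices, quantile_transform, search_curve,
                    select_frequencies)
from t1dsim.sensitivity_efast import _assemble


class TestSearchCurve:
    def test_origin_maps_to_half(self):
        for omega in (1, 3, 24):
            assert search_curve(omega, 0.0) == pytest.approx(0.5)

    def test_quarter_period_maps_to_one(self):
        assert search_curve(1, np.pi / 2) == pytest.approx(1.0)

    def test_dense_grid_stays_in_unit_interval(self):
        s = np.linspace(0, 2 * np.pi, 10_001)
        for omega in (1, 2, 11, 24):
            q = search_curve(omega, s)
            assert q.min() >= 0.0 and q.max() <= 1.0

    def test_invalid_omega(self):
        with pytest.raises(ValueError):
            search_curve(0, 0.0)


class TestFrequencySelection:
    def test_reference_design_driver_is_24(self):
        om = select_frequencies(200, 4, 5)
        assert om[0] == 24

    def test_reference_design_complementary_band(self):
        om = select_frequencies(200, 4, 5)
        assert om[1:].max() == 3        # floor(24 / (2*4))

    def test_single_factor(self):
        assert select_frequencies(200, 4, 1).tolist() == [24]

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            select_frequencies(16, 4, 3)

    @pytest.mark.parametrize("n,m,N_l", [(200, 4, 5), (513, 4, 5), (1025, 4, 8)])
    def test_aliasing_guard(self, n, m, N_l):
        om = select_frequencies(n, m, N_l)
        assert all(int(w) * m < om[0] for w in om[1:])


class TestQuantileTransform:
    def test_normal_median(self):
        assert quantile_transform(0.5, ("normal", 100, 20)) == pytest.approx(100.0)

    def test_normal_one_sigma(self):
        assert quantile_transform(0.8413, ("normal", 100, 20)) == \
            pytest.approx(120.0, abs=0.01)

    def test_uniform_linear(self):
        assert quantile_transform(0.25, ("uniform", 0, 8)) == pytest.approx(2.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantile_transform(1.5, ("uniform", 0, 1))


class TestIndices:
    def test_constant_output_flagged(self):
        res = efast_indices(np.full(200, 3.0), [24, 1, 2, 3, 1], m=4)
        assert res.zero_variance
        assert np.all(res.S_first == 0.0) and res.S_total_driver == 0.0

    def test_driver_only_model(self):
        """y = q_driver: nearly all variance sits on the driving frequency."""
        design = build_design({"a": ("uniform", 0, 1), "b": ("uniform", 0, 1),
                               "c": ("uniform", 0, 1)}, n=200, m=4)
        res = efast_indices(design.X[0][:, 0], design.omegas[0], m=4, driver=0)
        assert res.S_first[0] > 0.95
        assert res.S_total_driver > res.S_first[0] - 1e-9

    def test_additive_model_recovers_analytic_fractions(self):
        a = np.array([1.0, 2.0, 0.5, 1.5, 1.0])
        frac = a**2 / np.sum(a**2)          # Var(q_i)=1/12 cancels
        res = analyze_function(lambda x: float(a @ x),
                               {f"p{i}": ("uniform", 0.0, 1.0) for i in range(5)},
                               n=1025, m=4)
        assert np.allclose(res["S_i"], frac, atol=0.05)
        assert (res["S_i"] <= res["S_T"] + 0.02).all()
        assert np.allclose(res["S_i"], res["S_T"], atol=0.05)  # no interactions

    def test_reduced_equals_full_when_all_onsets(self):
        design = build_design({"a": ("uniform", 0, 1), "b": ("uniform", 0, 1)},
                              n=65, m=4)
        outputs = [np.sin(np.linspace(0, 7, 65)) + design.X[r][:, r]
                   for r in range(2)]
        full = _assemble(design, outputs, censor_value=32.0, mode="full")
        reduced = _assemble(design, outputs, censor_value=32.0, mode="reduced")
        assert np.allclose(full["S_i"], reduced["S_i"])
        assert np.allclose(full["S_T"], reduced["S_T"])

    def test_reduced_with_no_onsets_rejected(self):
        design = build_design({"a": ("uniform", 0, 1), "b": ("uniform", 0, 1)},
                              n=65, m=4)
        outputs = [np.full(65, 32.0) for _ in range(2)]
        with pytest.raises(ValueError):
            _assemble(design, outputs, censor_value=32.0, mode="reduced")


class TestCampaign:
    def test_smoke_shape_and_bounds(self, aggressive_cfg):
        """A tiny two-factor campaign returns one (S_i, S_T) pair per factor."""
        lo, hi = 60.0, 180.0
        design = build_design({"ctl_lifespan_h": ("uniform", lo, hi),
                               "dummy": ("uniform", 0.5, 1.5)}, n=65, m=4)
        res = efast_campaign(design, aggressive_cfg, mode="full", seed=0,
                             max_weeks=2)
        assert list(res["factor"]) == ["ctl_lifespan_h", "dummy"]
        assert ((res["S_i"] >= 0) & (res["S_i"] <= 1.01)).all()
        assert (res["S_i"] <= res["S_T"] + 0.02).all()
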