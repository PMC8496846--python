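import numpy as np
import pytest

from t1dsim import (ParameterSet, SimulationConfig, build_world, detect_onset,
                    run_simulation, step)
from t1dsim.agents import Agent, APC, CTL
from t1dsim.kinetics import draw_recruit_rate
from t1dsim.world import BETA_APOPTOTIC, BETA_HEALTHY, PLN


class TestDetectOnset:
    def test_constant_series_censored_at_32(self):
        week, censored = detect_onset(np.full(5000, 320), 320, 0.2)
        assert (week, censored) == (32.0, True)

    def test_crossing_at_hour_2016_is_week_12(self):
        s = np.full(2020, 320.0)
        s[2016:] = 0.29 * 320
        week, censored = detect_onset(s, 320, 0.30)
        assert week == 12.0 and not censored

    def test_never_crossing_low_threshold(self):
        s = np.full(4000, 0.15 * 320)
        week, censored = detect_onset(s, 320, 0.10)
        assert censored and week == 32.0

    def test_crossing_after_window_is_censored(self):
        s = np.full(22 * 168 + 10, 320.0)
        s[21 * 168:] = 10.0
        week, censored = detect_onset(s, 320, 0.30, window_weeks=20)
        assert censored

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_onset([], 320, 0.2)


class TestSingleTick:
    def test_quiet_world_only_clocks_advance(self, quiet_cfg):
        """With no trigger and no immune cells, a tick touches only timers."""
        w = build_world(quiet_cfg, rng_seed=0)
        status0 = w.beta_status.copy()
        pos0 = w.beta_pos.copy()
        q0 = w.beta_quiesc.copy()
        step(w)
        assert np.array_equal(w.beta_status, status0)
        assert np.array_equal(w.beta_pos, pos0)
        assert all(len(v) == 0 for v in w.agents.values())
        # intact islets are at carrying capacity: clocks tick, nothing divides
        assert np.all(w.beta_quiesc == q0 + 1.0)
        assert w.births_total == 0

    def test_apc_past_pln_lifespan_removed(self, quiet_cfg):
        w = build_world(quiet_cfg, rng_seed=0)
        x, y = w.random_patch(w.pln_patches)
        apc = Agent(APC, x, y, lifespan_h=72.0)
        apc.age_h = 73.0
        w.agents["apc"].append(apc)
        step(w)
        assert w.agents["apc"] == []

    def test_ctl_kills_one_adjacent_beta(self):
        """A CTL inside a fully packed islet sets one beta cell apoptotic."""
        params = ParameterSet(init_apoptotic_beta=0, n_naive_pool=0,
                              n_resident_dc=0, ctl_step_cells=1.0)
        cfg = SimulationConfig(n_islets=1, islet_radius=4, n_beta_cells=45,
                               params=params)
        w = build_world(cfg, rng_seed=3)
        cy, cx = w.islet_centers[0]
        w.agents["ctl"].append(Agent(CTL, int(cx), int(cy)))
        step(w)
        assert np.count_nonzero(w.beta_status == BETA_APOPTOTIC) == 1


class TestRunSimulation:
    def test_same_seed_identical_trajectory(self, mini_cfg):
        a = run_simulation(mini_cfg, 3, max_weeks=2)
        b = run_simulation(mini_cfg, 3, max_weeks=2)
        assert a.onset_week == b.onset_week
        for k in a.series:
            assert np.array_equal(a.series[k], b.series[k])

    def test_no_trigger_runs_censored(self, quiet_cfg):
        traj = run_simulation(quiet_cfg, 0, max_weeks=2)
        assert traj.censored and traj.onset_week == 32.0
        assert (traj.series["n_healthy_beta"] == 50).all()

    def test_beta_accounting_conserved(self, mini_cfg):
        """healthy + apoptotic + dead == initial + cumulative births, hourly."""
        traj = run_simulation(mini_cfg, 11, max_weeks=6)
        s = traj.series
        total = s["n_healthy_beta"] + s["n_apoptotic_beta"] + s["n_dead_beta"]
        assert np.array_equal(total, traj.beta_init + s["births_cum"])

    def test_series_length_matches_ticks(self, quiet_cfg):
        traj = run_simulation(quiet_cfg, 0, max_weeks=1)
        assert len(traj.series["n_healthy_beta"]) == 168 + 1

    def test_aggressive_world_reaches_onset(self, aggressive_cfg):
        """Pilot-calibrated check: hot parameters drive onset in >=90% of runs."""
        onsets = [run_simulation(aggressive_cfg, s, max_weeks=20).onset_week
                  for s in range(10)]
        assert sum(o < 32 for o in onsets) >= 9


class TestAgentInvariants:
    def test_no_agent_outlives_its_lifespan(self, aggressive_cfg):
        w = build_world(aggressive_cfg, rng_seed=5)
        p = aggressive_cfg.params
        w.k_r = draw_recruit_rate(p.dc_recruit_mu, p.dc_recruit_sigma, w.rng)
        for t in range(400):
            step(w)
            if t % 40 == 0:
                for cls, lst in w.agents.items():
                    for a in lst:
                        assert a.age_h <= a.lifespan_h
        # APC lifespans in the PLN were drawn from the stated 48-72 h range
        for a in w.agents["apc"]:
            if w.region[a.y, a.x] == PLN:
                assert 48.0 <= a.lifespan_h <= 72.0

    def test_infiltration_counts_only_islet_effectors(self, aggressive_cfg):
        w = build_world(aggressive_cfg, rng_seed=5)
        p = aggressive_cfg.params
        w.k_r = draw_recruit_rate(p.dc_recruit_mu, p.dc_recruit_sigma, w.rng)
        for _ in range(200):
            step(w)
        expected = sum(1 for cls in ("activatedT", "ctl")
                       for a in w.agents[cls]
                       if w.region[a.y, a.x] == 1)
        assert w.counts()["n_infiltrating_cd8"] == expected
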