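"""Hourly tick scheduler: agent rules, trajectories, disease onset.

Each tick advances the world by one hour and fires the rules in a fixed
order (within a class, agent iteration order is reshuffled every tick
with the run RNG, NetLogo-style):

1.  apoptotic beta cells release autoantigens;
2.  islet DCs move every ``dc_move_interval_h`` and engulf antigens by
    phagocytosis, becoming antigen-presenting cells (APCs);
3.  APCs migrate to the PLN after a per-agent 15-18 day delay, where
    their 48-72 h PLN lifespan clock starts;
4.  in the PLN, APCs probe the surrounding eight patches and bind naive
    CD8+ T cells subject to both binding-site caps; a 6-8 h short
    contact followed by a 2-24 h stable contact activates the naive
    cell, after which the APC unbinds and seeks the next one;
5.  activated cells run 4-8 h differentiation cycles, egress the PLN
    after 3-5 days, and transit to islets over 120 h;
6.  in islets, activated cells restimulated by antigen become CTLs;
    CTLs random-walk with an effective per-tick step (the 10-15 um/min
    in-vivo speed rescaled to the grid) and set at most one adjacent
    healthy beta cell apoptotic per tick;
7.  a drawn fraction of CTLs proliferates 4-7 offspring per 120 h cycle;
8.  DC recruitment from circulation follows the mass-action kinetics;
9.  beta-cell quiescence clocks advance; cells past the (dynamically
    shortened) quiescence period replicate over 24 h; apoptotic cells
    clear to dead after ``apoptotic_clear_h``;
10. every mobile agent ages one hour and dies past its drawn lifespan;
    the PLN naive pool is periodically replenished.

Overt T1D (onset) is the first hour at which the healthy beta-cell
fraction falls to the per-run threshold drawn uniformly in [10%, 30%].
Runs with no onset within the 20-week observation window are censored
and reported at 32 weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kinetics
from .agents import Agent, ANTIGEN, DC, APC, NAIVE_T, ACTIVATED_T, CTL
from .config import ParameterSet, SimulationConfig
from .world import (World, build_world, BETA_APOPTOTIC, BETA_DEAD,
                    BETA_HEALTHY, ISLET, PLN)

__all__ = ["Trajectory", "step", "run_simulation", "detect_onset"]

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
          (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Trajectory:
    """Per-hour population record and onset outcome of one run."""

    series: dict[str, np.ndarray]
    onset_week: float
    censored: bool
    onset_threshold_frac: float
    beta_init: int
    seed: int | None = None
    weeks: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.series["n_healthy_beta"])
        self.weeks = np.arange(n) / 168.0

    @property
    def n_ticks(self) -> int:
        return len(self.series["n_healthy_beta"]) - 1

    def at_week(self, week: float, key: str = "n_infiltrating_cd8") -> float:
        """Series value at the tick corresponding to ``week`` (week*168)."""
        tick = int(round(week * 168))
        s = self.series[key]
        if tick >= len(s):
            raise ValueError(f"week {week} beyond trajectory ({self.n_ticks} ticks)")
        return float(s[tick])


def detect_onset(healthy_series, beta_init: int, threshold_frac: float,
                 window_weeks: float = 20.0,
                 censor_weeks: float = 32.0) -> tuple[float, bool]:
    """First time the healthy fraction crosses the onset threshold.

    Returns ``(onset_week, censored)``.  The crossing is the first hour h
    with ``healthy[h] / beta_init <= threshold_frac`` inside the
    observation window; without one, the run is censored at
    ``censor_weeks``.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    s = np.asarray(healthy_series, dtype=float)
    if s.size == 0:
        raise ValueError("empty healthy-beta series")
    below = np.nonzero(s / beta_init <= threshold_frac)[0]
    if below.size and below[0] <= window_weeks * 168:
        return float(below[0]) / 168.0, False
    return float(censor_weeks), True


# ----------------------------------------------------------------------
# per-tick helpers

def _effective_params(world: World, therapy=None) -> ParameterSet:
    params = world.config.params
    if therapy is None:
        return params
    week = world.clock_h / 168.0
    return therapy.effective_params(params, week)


def _shuffled(rng: np.random.Generator, agents: list[Agent]) -> list[Agent]:
    order = rng.permutation(len(agents))
    return [agents[i] for i in order]


def _random_walk(world: World, a: Agent, step_cells: float,
                 mask: np.ndarray, rng: np.random.Generator) -> None:
    """Move an agent a drawn step in a uniform direction, staying on ``mask``."""
    H, W = world.region.shape
    for _ in range(4):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        nx = int(round(a.x + step_cells * math.cos(theta)))
        ny = int(round(a.y + step_cells * math.sin(theta)))
        nx = min(max(nx, 0), W - 1)
        ny = min(max(ny, 0), H - 1)
        if mask[ny, nx]:
            a.x, a.y = nx, ny
            return
    # all attempts left the allowed zone: stay put (reflecting boundary)


def _moore_step(world: World, a: Agent, region_label: int,
                rng: np.random.Generator) -> None:
    H, W = world.region.shape
    dy, dx = _MOORE[int(rng.integers(8))]
    nx = min(max(a.x + dx, 0), W - 1)
    ny = min(max(a.y + dy, 0), H - 1)
    if world.region[ny, nx] == region_label:
        a.x, a.y = nx, ny


def _kill_adjacent_beta(world: World, a: Agent, rng: np.random.Generator) -> bool:
    """Set one healthy beta cell in the Moore neighbourhood apoptotic."""
    H, W = world.region.shape
    y0, y1 = max(a.y - 1, 0), min(a.y + 2, H)
    x0, x1 = max(a.x - 1, 0), min(a.x + 2, W)
    win = world.healthy_grid[y0:y1, x0:x1]
    ys, xs = np.nonzero(win)
    if ys.size == 0:
        return False
    k = int(rng.integers(ys.size))
    py, px = y0 + int(ys[k]), x0 + int(xs[k])
    idx = world.occupancy[py, px]
    world.beta_status[idx] = BETA_APOPTOTIC
    world.beta_apop_since[idx] = world.clock_h + 1  # releases antigen next tick
    world.beta_repl_until[idx] = -1.0
    world.healthy_grid[py, px] = False
    world.lesion_grid[py, px] = True
    return True


def _spawn_beta(world: World, n_new: int, rng: np.random.Generator) -> int:
    """Place ``n_new`` healthy beta cells on free islet-disk patches."""
    placed_pos = []
    K = len(world.disk_patches)
    for _ in range(n_new):
        for _try in range(25):
            i = int(rng.integers(K))
            py, px = world.disk_patches[i]
            if world.occupancy[py, px] < 0:
                placed_pos.append((py, px))
                world.occupancy[py, px] = len(world.beta_pos) + len(placed_pos) - 1
                break
    if not placed_pos:
        return 0
    m = len(placed_pos)
    pos = np.array(placed_pos, dtype=np.int32)
    world.beta_pos = np.concatenate([world.beta_pos, pos])
    world.beta_status = np.concatenate(
        [world.beta_status, np.zeros(m, dtype=np.int8)])
    world.beta_quiesc = np.concatenate([world.beta_quiesc, np.zeros(m)])
    world.beta_repl_until = np.concatenate(
        [world.beta_repl_until, np.full(m, -1.0)])
    world.beta_apop_since = np.concatenate(
        [world.beta_apop_since, np.full(m, -1.0)])
    world.healthy_grid[pos[:, 0], pos[:, 1]] = True
    world.births_total += m
    return m


def step(world: World, rng: np.random.Generator | None = None,
         therapy=None) -> World:
    """Advance the world by one hour in place (also returned)."""
    rng = world.rng if rng is None else rng
    eff = _effective_params(world, therapy)
    t = world.clock_h
    agents = world.agents

    # (1) antigen release from apoptotic beta cells -------------------
    apop = np.nonzero(world.beta_status == BETA_APOPTOTIC)[0]
    if apop.size:
        p_emit = min(1.0, eff.antigens_per_apoptotic / max(eff.antigen_lifespan_h, 1.0))
        new_apop = apop[world.beta_apop_since[apop] == t]
        emit = apop[rng.random(apop.size) < p_emit]
        for idx in new_apop:
            py, px = world.beta_pos[idx]
            for _ in range(int(eff.antigens_per_apoptotic)):
                agents[ANTIGEN].append(
                    Agent(ANTIGEN, int(px), int(py), lifespan_h=eff.antigen_lifespan_h))
        for idx in emit:
            py, px = world.beta_pos[idx]
            agents[ANTIGEN].append(
                Agent(ANTIGEN, int(px), int(py), lifespan_h=eff.antigen_lifespan_h))

    antigen_at: dict[tuple[int, int], list[Agent]] = {}
    for ag in agents[ANTIGEN]:
        antigen_at.setdefault((ag.x, ag.y), []).append(ag)

    # (2) DC movement within islets + phagocytosis --------------------
    became_apc = []
    for dc in _shuffled(rng, agents[DC]):
        if world.region[dc.y, dc.x] != ISLET:
            continue
        if dc.move_at < 0:
            dc.move_at = t + eff.dc_move_interval_h
        if t >= dc.move_at:
            _moore_step(world, dc, ISLET, rng)
            dc.move_at = t + eff.dc_move_interval_h
        here = antigen_at.get((dc.x, dc.y))
        while here and dc.engulfed < eff.dc_engulf_need:
            ag = here.pop()
            ag.alive = False
            dc.engulfed += 1
        if dc.engulfed >= eff.dc_engulf_need:
            dc.cls = APC
            dc.bindings = []
            lo, hi = eff.dc_islet_to_pln_migration_d
            dc.migrate_at = t + rng.uniform(lo, hi) * 24.0
            became_apc.append(dc)
    for dc in became_apc:
        agents[DC].remove(dc)
        agents[APC].append(dc)

    # (3) APC migration islets -> PLN ---------------------------------
    for apc in agents[APC]:
        if world.region[apc.y, apc.x] == ISLET and 0 <= apc.migrate_at <= t:
            apc.x, apc.y = world.random_patch(world.pln_patches)
            apc.age_h = 0.0
            lo, hi = eff.apc_lifespan_range_h
            apc.lifespan_h = float(rng.uniform(lo, hi))
            apc.migrate_at = -1.0

    # (4) APC / naive CD8 binding and activation in PLN ---------------
    naive_at: dict[tuple[int, int], list[Agent]] = {}
    for nv in agents[NAIVE_T]:
        naive_at.setdefault((nv.x, nv.y), []).append(nv)
    activated_now = []
    for apc in _shuffled(rng, agents[APC]):
        if world.region[apc.y, apc.x] != PLN:
            continue
        if apc.bindings is None:
            apc.bindings = []
        _moore_step(world, apc, PLN, rng)
        # progress existing stable contacts
        keep = []
        for binding in apc.bindings:
            nv, activate_at = binding
            if not nv.alive or nv.cls != NAIVE_T:
                continue
            if t >= activate_at:
                nv.cls = ACTIVATED_T
                nv.bound_partners = 0
                nv.age_h = 0.0
                lo, hi = eff.naive_pln_residence_d
                residence = rng.uniform(lo, hi) * 24.0
                nv.egress_at = t + residence
                nv.lifespan_h = residence + eff.activatedT_pln_to_islet_h \
                    + eff.ctl_lifespan_h
                dlo, dhi = eff.naive_diff_cycle_h
                nv.diff_at = t + rng.uniform(dlo, dhi)
                activated_now.append(nv)
            else:
                keep.append(binding)
        apc.bindings = keep
        # seek new naive cells on the surrounding eight patches
        if len(apc.bindings) >= int(eff.apc_max_bind):
            continue
        for dy, dx in _MOORE:
            if len(apc.bindings) >= int(eff.apc_max_bind):
                break
            for nv in naive_at.get((apc.x + dx, apc.y + dy), []):
                if not nv.alive or nv.cls != NAIVE_T:
                    continue
                if nv.bound_partners >= int(eff.max_naive_binding):
                    continue
                slo, shi = eff.apc_short_contact_h
                alo, ahi = eff.naive_activation_h
                contact = rng.uniform(slo, shi) + rng.uniform(alo, ahi)
                nv.bound_partners += 1
                apc.bindings.append([nv, t + contact])
                if len(apc.bindings) >= int(eff.apc_max_bind):
                    break
    for nv in activated_now:
        agents[NAIVE_T].remove(nv)
        agents[ACTIVATED_T].append(nv)

    # (5) activated CD8: differentiation, PLN egress, transit ---------
    for ac in agents[ACTIVATED_T]:
        reg = world.region[ac.y, ac.x]
        if reg == PLN:
            if 0 <= ac.diff_at <= t and ac.diff_cycles_done < int(eff.n_diff_cycles):
                ac.diff_cycles_done += 1
                dlo, dhi = eff.naive_diff_cycle_h
                ac.diff_at = t + rng.uniform(dlo, dhi)
            if 0 <= ac.egress_at <= t and ac.diff_cycles_done >= int(eff.n_diff_cycles):
                # into circulation for the 120 h transit to islets
                ac.x, ac.y = world.random_patch(world.circulation_patches)
                ac.arrive_at = t + eff.activatedT_pln_to_islet_h
                ac.egress_at = -1.0
        elif reg != ISLET:
            if 0 <= ac.arrive_at <= t:
                # arriving effectors home to the islet disks
                ac.x, ac.y = world.random_patch(world.disk_patches)
                ac.arrive_at = -1.0

    # (6) islet phase: restimulation -> CTL; CTL walk and kill --------
    became_ctl = []
    for ac in agents[ACTIVATED_T]:
        if world.region[ac.y, ac.x] != ISLET:
            continue
        # peri-insulitis: not-yet-restimulated effectors stay at the islets
        _random_walk(world, ac, eff.ctl_step_cells, world.disk_mask, rng)
        # restimulation: free antigen or antigen-bearing beta-cell debris
        H, W = world.region.shape
        y0, y1 = max(ac.y - 1, 0), min(ac.y + 2, H)
        x0, x1 = max(ac.x - 1, 0), min(ac.x + 2, W)
        near_antigen = bool(world.lesion_grid[y0:y1, x0:x1].any()) or any(
            (ac.x + dx, ac.y + dy) in antigen_at
            for dy, dx in _MOORE + [(0, 0)])
        if near_antigen:
            ac.cls = CTL
            ac.age_h = 0.0
            ac.lifespan_h = eff.ctl_lifespan_h
            ac.prolif_at = t + eff.ctl_prolif_cycle_h
            became_ctl.append(ac)
    for ac in became_ctl:
        agents[ACTIVATED_T].remove(ac)
        agents[CTL].append(ac)

    offspring = []
    for ctl in _shuffled(rng, agents[CTL]):
        _random_walk(world, ctl, eff.ctl_step_cells, world.islet_mask, rng)
        _kill_adjacent_beta(world, ctl, rng)
        # (7) proliferation gate: a drawn fraction divides each 120 h cycle
        if 0 <= ctl.prolif_at <= t:
            if rng.random() < eff.ctl_prolif_fraction:
                for _ in range(int(eff.ctl_prolif_offspring)):
                    child = Agent(CTL, ctl.x, ctl.y,
                                  lifespan_h=eff.ctl_lifespan_h)
                    child.prolif_at = t + eff.ctl_prolif_cycle_h
                    offspring.append(child)
            ctl.prolif_at = t + eff.ctl_prolif_cycle_h
    agents[CTL].extend(offspring)

    # (8) DC recruitment from circulation (mass-action kinetics) ------
    beta_ap = int(np.count_nonzero(world.beta_status == BETA_APOPTOTIC))
    k_r = world.k_r
    if therapy is not None:
        k_r = therapy.effective_k_r(k_r, world.clock_h / 168.0)
    n_rec = kinetics.dc_recruited(k_r, beta_ap, eff.dc_c, rng=rng, mode="poisson")
    apop_idx = np.nonzero(world.beta_status == BETA_APOPTOTIC)[0]
    for _ in range(n_rec):
        # recruited DCs home to sites of insulitis (apoptotic beta patches)
        if apop_idx.size:
            py, px = world.beta_pos[apop_idx[int(rng.integers(apop_idx.size))]]
            x, y = int(px), int(py)
        else:
            x, y = world.random_patch(world.islet_region_patches)
        ndc = Agent(DC, x, y)
        ndc.move_at = t + eff.dc_move_interval_h
        agents[DC].append(ndc)

    # (9) beta-cell quiescence, replication, apoptotic clearance ------
    healthy = world.beta_status == BETA_HEALTHY
    idle = healthy & (world.beta_repl_until < 0)
    world.beta_quiesc[idle] += 1.0
    T_cur = kinetics.quiescence_period(
        eff.quiescence_T0_h, min(beta_ap, world.beta_init), world.beta_init,
        eff.gamma)
    # homeostatic carrying capacity: replication refills losses up to the
    # initial beta mass; matured cells beyond the budget stay poised
    n_healthy = int(np.count_nonzero(healthy))
    off = max(1, int(eff.beta_offspring))
    in_flight = int(np.count_nonzero(healthy & (world.beta_repl_until >= 0)))
    budget = max(0, (world.beta_init - n_healthy - in_flight * off) // off)
    start_idx = np.nonzero(idle & (world.beta_quiesc >= T_cur))[0]
    if start_idx.size > budget:
        start_idx = start_idx[:budget]
    world.beta_repl_until[start_idx] = t + eff.beta_replication_h
    done = healthy & (world.beta_repl_until >= 0) & (world.beta_repl_until <= t)
    n_done = int(np.count_nonzero(done))
    if n_done:
        world.beta_repl_until[done] = -1.0
        world.beta_quiesc[done] = 0.0
        _spawn_beta(world, n_done * int(eff.beta_offspring), rng)
    clear = (world.beta_status == BETA_APOPTOTIC) & \
        (t - world.beta_apop_since >= eff.apoptotic_clear_h)
    world.beta_status[clear] = BETA_DEAD

    # (10) ageing, lifespan death, pool replenishment -----------------
    for cls in (ANTIGEN, DC, APC, NAIVE_T, ACTIVATED_T, CTL):
        survivors = []
        for a in agents[cls]:
            if not a.alive:
                continue
            a.age_h += 1.0
            if a.age_h > a.lifespan_h:
                a.alive = False
                if a.bindings:
                    for nv, _ in a.bindings:
                        if nv.alive and nv.cls == NAIVE_T:
                            nv.bound_partners = max(0, nv.bound_partners - 1)
            else:
                survivors.append(a)
        agents[cls] = survivors
    interval = max(1, int(round(eff.naive_replenish_h)))
    if (t + 1) % interval == 0:
        lo, hi = eff.naive_lifespan_d
        deficit = int(eff.n_naive_pool) - len(agents[NAIVE_T])
        for _ in range(max(0, deficit)):
            x, y = world.random_patch(world.pln_patches)
            agents[NAIVE_T].append(
                Agent(NAIVE_T, x, y, lifespan_h=float(rng.uniform(lo, hi) * 24.0)))

    world.clock_h = t + 1
    return world


# ----------------------------------------------------------------------

def run_simulation(config: SimulationConfig, seed: int,
                   therapy=None, max_weeks: float | None = None,
                   stop_at_onset: bool = True) -> Trajectory:
    """Run a full seeded simulation and record the hourly trajectory.

    The same ``(config, seed)`` pair always produces an identical
    trajectory.  The run stops early at onset (first crossing of the
    per-run threshold) unless ``stop_at_onset=False``.
    """
    world = build_world(config, rng_seed=seed)
    world.k_r = kinetics.draw_recruit_rate(
        config.params.dc_recruit_mu, config.params.dc_recruit_sigma, world.rng)
    horizon = config.max_weeks if max_weeks is None else max_weeks
    n_ticks = int(round(horizon * 7 * 24))
    keys = ("n_healthy_beta", "n_apoptotic_beta", "n_dead_beta",
            "n_infiltrating_cd8", "n_dc_islet", "n_apc_pln")
    rec = {k: [world.counts()[k]] for k in keys}
    births = [0]
    threshold = world.onset_threshold_frac
    crossed_at = None
    for _ in range(n_ticks):
        step(world, therapy=therapy)
        c = world.counts()
        for k in keys:
            rec[k].append(c[k])
        births.append(world.births_total)
        if crossed_at is None and c["n_healthy_beta"] / world.beta_init <= threshold:
            crossed_at = world.clock_h
            if stop_at_onset:
                break
    series = {k: np.asarray(v, dtype=np.int64) for k, v in rec.items()}
    series["births_cum"] = np.asarray(births, dtype=np.int64)
    onset_week, censored = detect_onset(
        series["n_healthy_beta"], world.beta_init, threshold,
        window_weeks=config.onset_window_weeks,
        censor_weeks=config.censor_weeks)
    return Trajectory(series=series, onset_week=onset_week, censored=censored,
                      onset_threshold_frac=threshold,
                      beta_init=world.beta_init, seed=seed)
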