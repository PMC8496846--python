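"""In-silico therapy campaigns over (strategy, administration week, dose).

Three single-dose strategies target the mechanisms the sensitivity
analyses flag as drivers of disease progression:

* **T1** reduces the longevity of CTLs in islets (``ctl_lifespan_h``);
* **T2** inhibits DC infiltration into islets (the recruiting rate,
  through ``mu_r`` / the per-run draw ``k_r``);
* **T3** mitigates naive CD8+ T-cell binding to DCs
  (``max_naive_binding``).

"Dose" is a fractional reduction applied to the targeted parameter from
the administration week onward, persisting for the rest of the run; up
to two strategies may be combined.  The anchor example is a 0.05 dose of
T1 at week 8: CTL lifespan drops from 120 h to 114 h.  Therapy affects
newly drawn values only (existing CTLs keep the lifespan they were
created with).

Outcomes are summarised as ``P_T1D``, the fraction of replicate seeded
runs reaching onset within the 20-week observation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import ParameterSet, SimulationConfig
from .engine import run_simulation

__all__ = ["TherapySpec", "TherapyOutcome", "apply_therapy",
           "estimate_p_t1d", "therapy_grid"]

_TARGETS = {
    "T1": "ctl_lifespan_h",
    "T2": "dc_recruit_mu",
    "T3": "max_naive_binding",
}


@dataclass(frozen=True)
class TherapySpec:
    """A single-dose intervention: which strategies, when, how much."""

    components: frozenset
    admin_week: float
    dose: float

    def __init__(self, components, admin_week: float, dose: float):
        comps = frozenset(components)
        if not comps:
            raise ValueError("at least one therapy component is required")
        if len(comps) > 2:
            raise ValueError("at most two strategies may be combined")
        unknown = comps - set(_TARGETS)
        if unknown:
            raise ValueError(f"unknown therapy components: {sorted(unknown)}")
        if not 0.0 <= dose <= 1.0:
            raise ValueError("dose must lie in [0, 1]")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "admin_week", float(admin_week))
        object.__setattr__(self, "dose", float(dose))

    # -- hooks used by the engine at each tick -------------------------
    def effective_params(self, params: ParameterSet, week: float) -> ParameterSet:
        return apply_therapy(params, self, week)

    def effective_k_r(self, k_r: float, week: float) -> float:
        """T2 scales the per-run mass-action recruiting-rate draw."""
        if "T2" in self.components and week >= self.admin_week:
            return k_r * (1.0 - self.dose)
        return k_r


def apply_therapy(params: ParameterSet, spec: TherapySpec,
                  current_week: float) -> ParameterSet:
    """Parameter set in force at ``current_week`` under ``spec``.

    Before the administration week the parameters are untouched; from it
    onward each targeted parameter is multiplied by ``(1 - dose)``.
    """
    if current_week < spec.admin_week or spec.dose == 0.0:
        return params
    changes = {}
    for comp in spec.components:
        name = _TARGETS[comp]
        value = getattr(params, name) * (1.0 - spec.dose)
        if name == "max_naive_binding":
            changes[name] = max(1, int(round(value)))
        else:
            changes[name] = value
    return params.replace(**changes)


@dataclass
class TherapyOutcome:
    spec: TherapySpec | None
    n_runs: int
    n_onsets: int
    seeds: list[int] = field(default_factory=list)

    @property
    def p_t1d(self) -> float:
        return self.n_onsets / self.n_runs


def estimate_p_t1d(config: SimulationConfig, spec: TherapySpec | None,
                   n_runs: int = 50, seed: int = 0,
                   max_weeks: float | None = None) -> TherapyOutcome:
    """P_T1D = onsets within 20 weeks / replicate runs, with paired seeds.

    Seeds are ``seed, seed+1, ..`` so campaigns at different doses can be
    compared run-for-run on common random numbers.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    horizon = max_weeks if max_weeks is not None else config.onset_window_weeks
    seeds = [seed + i for i in range(n_runs)]
    n_onsets = 0
    for s in seeds:
        traj = run_simulation(config, s, therapy=spec, max_weeks=horizon)
        if not traj.censored:
            n_onsets += 1
    return TherapyOutcome(spec=spec, n_runs=n_runs, n_onsets=n_onsets, seeds=seeds)


def therapy_grid(config: SimulationConfig, components,
                 weeks, doses, n_runs: int = 50, seed: int = 0,
                 max_weeks: float | None = None) -> pd.DataFrame:
    """P_T1D heatmap table over (administration week, dose) cells."""
    weeks = list(weeks)
    doses = list(doses)
    if not weeks or not doses:
        raise ValueError("weeks and doses grids must be non-empty")
    rows = []
    for w in weeks:
        for d in doses:
            spec = TherapySpec(components, admin_week=w, dose=d)
            out = estimate_p_t1d(config, spec, n_runs=n_runs, seed=seed,
                                 max_weeks=max_weeks)
            rows.append({
                "components": "+".join(sorted(spec.components)),
                "admin_week": w, "dose": d,
                "n_runs": out.n_runs, "n_onsets": out.n_onsets,
                "p_t1d": out.p_t1d,
            })
    return pd.DataFrame(rows)
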