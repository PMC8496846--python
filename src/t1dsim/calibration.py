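"""Latin-hypercube exploration of the unknown parameters.

The 21 unknown parameters are screened with a stratified Latin hypercube
design: each parameter's range is divided into ``n_strata`` equal-width
intervals and every interval is sampled exactly once.  Each candidate
parameter set is simulated ``n_reps`` times, the mean infiltrating-CD8
count is read off at weeks 4, 6, 8, 10, 12 and 14, and candidates are
ranked by their discrepancy (sum of squared differences, optionally
SEM-weighted) against the weekly experimental series; the argmin becomes
the default parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .config import ParameterSet, SimulationConfig
from .engine import Trajectory, run_simulation

__all__ = ["LhsDesign", "FitResult", "lhs_sample", "weekly_means",
           "fit_score", "select_default", "CALIBRATION_WEEKS"]

CALIBRATION_WEEKS = (4, 6, 8, 10, 12, 14)


@dataclass
class LhsDesign:
    """A stratified-uniform sample: one draw per stratum per parameter."""

    names: list[str]
    ranges: np.ndarray        # (d, 2)
    n_strata: int
    samples: np.ndarray       # (n_strata, d)
    seed: int

    def __len__(self) -> int:
        return self.n_strata

    def parameter_sets(self, base: ParameterSet | None = None) -> list[ParameterSet]:
        base = base if base is not None else ParameterSet()
        return [base.with_unknowns(dict(zip(self.names, row)))
                for row in self.samples]

    def stratum_of(self, name: str, value: float) -> int:
        """0-based stratum index of ``value`` on this parameter's range."""
        j = self.names.index(name)
        lo, hi = self.ranges[j]
        k = int(np.floor((value - lo) / (hi - lo) * self.n_strata))
        return min(max(k, 0), self.n_strata - 1)


def lhs_sample(ranges: dict[str, tuple[float, float]], n_strata: int,
               seed: int = 0) -> LhsDesign:
    """Latin hypercube sample with exact per-parameter stratification.

    For every parameter the sorted samples occupy each of the
    ``n_strata`` equal-width strata exactly once (a permutation).
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    names = list(ranges)
    bounds = np.array([ranges[n] for n in names], dtype=float)
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        bad = [n for n, (lo, hi) in ranges.items() if lo >= hi]
        raise ValueError(f"degenerate ranges for: {bad}")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n=n_strata)
    samples = qmc.scale(unit, bounds[:, 0], bounds[:, 1])
    return LhsDesign(names=names, ranges=bounds, n_strata=n_strata,
                     samples=samples, seed=seed)


def weekly_means(traj: Trajectory, weeks=CALIBRATION_WEEKS,
                 key: str = "n_infiltrating_cd8") -> np.ndarray:
    """Series values at the requested weeks (week w -> tick w*168)."""
    return np.array([traj.at_week(w, key=key) for w in weeks], dtype=float)


def fit_score(sim_means, data_means) -> tuple[float, float]:
    """(discrepancy, R^2) of simulated vs experimental weekly means.

    Discrepancy is the unweighted sum of squared differences; R^2 is
    computed about the data mean.  Zero-variance data leaves R^2
    undefined and raises ``ValueError``.
    """
    sim = np.asarray(sim_means, dtype=float)
    data = np.asarray(data_means, dtype=float)
    if sim.shape != data.shape or sim.size < 2:
        raise ValueError("need two equal-length series with >= 2 points")
    ss_res = float(np.sum((data - sim) ** 2))
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero-variance data: R^2 undefined")
    return ss_res, 1.0 - ss_res / ss_tot


@dataclass
class FitResult:
    params: ParameterSet
    sim_means: np.ndarray
    discrepancy: float
    r2: float


def select_default(candidates, data_means, config: SimulationConfig,
                   n_reps: int = 20, seed: int = 0,
                   weeks=CALIBRATION_WEEKS, sem=None,
                   max_weeks: float | None = None
                   ) -> tuple[ParameterSet, pd.DataFrame]:
    """Rank candidate parameter sets by fit to the weekly CD8 series.

    ``candidates`` is an :class:`LhsDesign` or an explicit list of
    :class:`ParameterSet`.  Every candidate is simulated ``n_reps`` times
    (seeds ``seed + rep``, shared across candidates) and scored on the
    mean weekly infiltrating-CD8 counts.  Returns the best candidate and
    the full leaderboard, sorted by discrepancy.
    """
    if isinstance(candidates, LhsDesign):
        candidates = candidates.parameter_sets(config.params)
    data = np.asarray(data_means, dtype=float)
    weights = np.ones_like(data) if sem is None else 1.0 / np.maximum(
        np.asarray(sem, dtype=float), 1e-12) ** 2
    horizon = max_weeks if max_weeks is not None else max(weeks)
    rows = []
    results = []
    for ci, params in enumerate(candidates):
        cfg = config.replace(params=params)
        sims = np.empty((n_reps, len(data)))
        for rep in range(n_reps):
            traj = run_simulation(cfg, seed + rep, max_weeks=horizon,
                                  stop_at_onset=False)
            sims[rep] = weekly_means(traj, weeks)
        sim_mean = sims.mean(axis=0)
        disc = float(np.sum(weights * (sim_mean - data) ** 2))
        try:
            _, r2 = fit_score(sim_mean, data)
        except ValueError:
            r2 = float("nan")
        results.append(FitResult(params, sim_mean, disc, r2))
        row = {"candidate": ci, "discrepancy": disc, "r2": r2}
        row.update({f"week_{w}": m for w, m in zip(weeks, sim_mean)})
        rows.append(row)
    leaderboard = pd.DataFrame(rows).sort_values("discrepancy").reset_index(drop=True)
    best = results[int(leaderboard.loc[0, "candidate"])]
    return best.params, leaderboard
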