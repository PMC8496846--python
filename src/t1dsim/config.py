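"""Configuration objects for the NOD-mouse T1D simulator.

A single :class:`SimulationConfig` is the source of truth for a run: the
world geometry (grid, islet layout, region bands), the initial cell
populations, the onset/censoring conventions, and a :class:`ParameterSet`
holding every model parameter.

Two kinds of parameters live in :class:`ParameterSet`:

* *known* biological constants taken from NOD-mouse experimental studies
  (lifespans, contact times, migration delays) — these are fixed ranges
  that each agent draws from at creation and are never calibrated;
* 21 *unknown* scalar parameters (``UNKNOWN_PARAMS``) whose values are
  not pinned by experiment.  These are the inputs to Latin-hypercube
  calibration and to the local (OAT + ANOVA) and global (eFAST)
  sensitivity analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a configuration cannot produce a valid world."""


# The 21 unknown scalar parameters with their sampling ranges, expressed
# relative to a mini-scale world (counts scale with the world; see
# SimulationConfig.scaled_ranges).  The first five carry the P1..P5 labels
# used throughout the sensitivity and therapy analyses.
UNKNOWN_PARAMS: dict[str, tuple[float, float]] = {
    "ctl_lifespan_h": (60.0, 180.0),          # P1: mean CTL lifespan in islets
    "init_apoptotic_beta": (4.0, 40.0),       # P2: apoptotic beta cells at step 0
    "dc_move_interval_h": (1.0, 6.0),         # P3: DC movement interval in islets
    "max_naive_binding": (1.0, 6.0),          # P4: binding sites per naive CD8 T cell
    "dc_recruit_mu": (1e-5, 4e-4),            # P5: mean DC recruiting rate mu_r
    "dc_recruit_sigma": (1e-6, 1e-4),         # sd of the recruiting rate sigma_r
    "dc_c": (20.0, 120.0),                    # circulating DC count (constant per run)
    "gamma": (0.5, 2.0),                      # glucose-metabolism exponent
    "n_naive_pool": (10.0, 120.0),            # resident naive CD8 pool in PLN
    "n_resident_dc": (1.0, 12.0),             # islet-resident DCs at step 0
    "antigen_lifespan_h": (4.0, 48.0),        # autoantigen persistence
    "antigens_per_apoptotic": (1.0, 4.0),     # antigens released per apoptotic event
    "apc_max_bind": (1.0, 6.0),               # simultaneous naive cells per APC
    "dc_engulf_need": (1.0, 3.0),             # antigens engulfed before DC -> APC
    "apoptotic_clear_h": (72.0, 800.0),       # apoptotic beta -> dead delay
    "naive_replenish_h": (12.0, 96.0),        # PLN pool top-up interval
    "ctl_step_cells": (1.0, 10.0),            # effective CTL displacement per tick
    "n_diff_cycles": (2.0, 8.0),              # differentiation cycles before egress
    "ctl_prolif_fraction": (0.154, 0.238),    # fraction of CTLs proliferating
    "ctl_prolif_offspring": (4.0, 7.0),       # offspring per proliferation cycle
    "beta_offspring": (1.0, 2.0),             # new beta cells per replication
}

# Parameters that are integer counts in the engine.
_INT_PARAMS = {
    "init_apoptotic_beta", "max_naive_binding", "dc_c", "n_naive_pool",
    "n_resident_dc", "antigens_per_apoptotic", "apc_max_bind",
    "dc_engulf_need", "n_diff_cycles", "ctl_prolif_offspring",
    "beta_offspring",
}

# Counts that scale with the fraction of the in-vivo system represented.
_SCALED_PARAMS = {"init_apoptotic_beta", "dc_c", "n_naive_pool", "n_resident_dc"}


@dataclass
class ParameterSet:
    """All model parameters for one run.

    Unknown parameters (see :data:`UNKNOWN_PARAMS`) default to the repo's
    calibrated mini-scale values.  Known experimental constants follow the
    NOD-mouse literature ranges and are drawn per agent at creation.
    """

    # --- unknown parameters (calibration / sensitivity targets) ---
    ctl_lifespan_h: float = 120.0
    init_apoptotic_beta: int = 20
    dc_move_interval_h: float = 2.0
    max_naive_binding: int = 2
    dc_recruit_mu: float = 3.0e-5
    dc_recruit_sigma: float = 7.5e-6
    dc_c: int = 50
    gamma: float = 1.0
    n_naive_pool: int = 40
    n_resident_dc: int = 4
    antigen_lifespan_h: float = 12.0
    antigens_per_apoptotic: int = 2
    apc_max_bind: int = 3
    dc_engulf_need: int = 1
    apoptotic_clear_h: float = 600.0
    naive_replenish_h: float = 24.0
    ctl_step_cells: float = 4.0
    n_diff_cycles: int = 4
    ctl_prolif_fraction: float = 0.196
    ctl_prolif_offspring: int = 5
    beta_offspring: int = 1

    # --- known experimental constants (Table-1 style ranges) ---
    quiescence_T0_h: float = 168.0
    quiescence_glucose_h: float = 48.0
    apc_lifespan_range_h: tuple[float, float] = (48.0, 72.0)
    apc_short_contact_h: tuple[float, float] = (6.0, 8.0)
    naive_activation_h: tuple[float, float] = (2.0, 24.0)
    naive_diff_cycle_h: tuple[float, float] = (4.0, 8.0)
    naive_lifespan_d: tuple[float, float] = (3.0, 5.0)
    naive_pln_residence_d: tuple[float, float] = (3.0, 5.0)
    dc_islet_to_pln_migration_d: tuple[float, float] = (15.0, 18.0)
    activatedT_pln_to_islet_h: float = 120.0
    ctl_prolif_cycle_h: float = 120.0
    ctl_speed_um_min: tuple[float, float] = (10.0, 15.0)
    beta_replication_h: float = 24.0

    # Inert control with no dynamical effect; negative control for the
    # sensitivity screens.
    dummy: float = 1.0

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def unknown_values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in UNKNOWN_PARAMS}

    def with_unknowns(self, values: dict[str, float]) -> "ParameterSet":
        """Return a copy with unknown parameters set (ints coerced)."""
        coerced = {
            k: (int(round(v)) if k in _INT_PARAMS else float(v))
            for k, v in values.items()
        }
        return self.replace(**coerced)


@dataclass
class RegionLayout:
    """Fractional partition of the grid into the three bands.

    The bottom ``islet_frac`` of rows is the islet region; the top band is
    split by column into circulation (left ``circulation_frac`` of columns)
    and PLN (right).
    """

    islet_frac: float = 0.7
    circulation_frac: float = 0.5

    def validate(self) -> None:
        if not 0.0 < self.islet_frac < 1.0:
            raise ConfigurationError("islet_frac must be in (0, 1)")
        if not 0.0 < self.circulation_frac < 1.0:
            raise ConfigurationError("circulation_frac must be in (0, 1)")


@dataclass
class SimulationConfig:
    """World geometry + model parameters + run conventions for one run."""

    grid_width: int = 201
    grid_height: int = 201
    n_islets: int = 25
    islet_radius: int = 38
    n_beta_cells: int = 8080
    islet_diameter_um: float = 100.0
    tick_hours: int = 1               # fixed: one simulation step is one hour
    max_weeks: int = 32
    onset_window_weeks: int = 20      # onsets after this are censored
    censor_weeks: int = 32            # reported value for censored runs
    onset_fraction_low: float = 0.10
    onset_fraction_high: float = 0.30
    scale_factor: float = 0.01        # fraction of in-vivo cell numbers
    region_layout: RegionLayout = field(default_factory=RegionLayout)
    seed: int = 0
    params: ParameterSet = field(default_factory=ParameterSet)

    def validate(self) -> None:
        if self.grid_width < 2 * self.islet_radius or self.grid_height < 2 * self.islet_radius:
            raise ConfigurationError("grid dimensions must be >= 2 x islet_radius")
        if not (0.0 < self.onset_fraction_low < self.onset_fraction_high < 1.0):
            raise ConfigurationError(
                "need 0 < onset_fraction_low < onset_fraction_high < 1")
        if self.n_beta_cells <= 0:
            raise ConfigurationError("n_beta_cells must be positive")
        if self.n_islets < 0 or self.islet_radius <= 0:
            raise ConfigurationError("n_islets must be >= 0 and islet_radius > 0")
        if self.tick_hours != 1:
            raise ConfigurationError("tick_hours is fixed at 1")
        self.region_layout.validate()

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def scaled_ranges(self, reference_beta: int = 320) -> dict[str, tuple[float, float]]:
        """Unknown-parameter ranges with count-like ranges scaled to this world.

        The canonical ranges in :data:`UNKNOWN_PARAMS` are stated for a
        reference mini world of ``reference_beta`` beta cells; population
        counts scale linearly with ``n_beta_cells`` (the same argument
        that downsizes the in-vivo pancreas to 1% in the full world).
        """
        scale = self.n_beta_cells / reference_beta
        out = {}
        for name, (lo, hi) in UNKNOWN_PARAMS.items():
            if name in _SCALED_PARAMS:
                out[name] = (lo * scale, hi * scale)
            else:
                out[name] = (lo, hi)
        return out
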