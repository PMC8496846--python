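"""Synthetic inputs and reduced-scale worlds.

The raw weekly infiltrating-CD8 counts of NOD mice that the calibration
layer targets are not publicly available, so :func:`surrogate_cd8_series`
generates a surrogate weekly series with the qualitative structure the
experiments report: counts stay low through week 6, rise sharply around
week 8, and keep rising (with oscillation) through week 14, with SEM
bands derived from the stated per-week replicate counts (7, 6, 5, 6, 7
and 12 mice).  It is a stand-in, clearly synthetic, for data this
package cannot ship.

:func:`mini_world` builds a desk-scale configuration — the same rule set
and parameter schema as the full world, with populations scaled down the
same way the full model scales down the in-vivo pancreas — so that every
analysis in the package can run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ParameterSet, SimulationConfig

__all__ = ["SurrogateSeries", "surrogate_cd8_series", "mini_world",
           "CD8_WEEKS", "CD8_REPLICATES"]

CD8_WEEKS = (4, 6, 8, 10, 12, 14)
CD8_REPLICATES = (7, 6, 5, 6, 7, 12)   # mice per week in the reference data

# beta-cell count of the reference mini world the canonical parameter
# ranges/defaults are stated for
REFERENCE_BETA = 320


@dataclass
class SurrogateSeries:
    """Synthetic weekly infiltrating-CD8 series (mean +- SEM)."""

    weeks: tuple
    mean: np.ndarray
    sem: np.ndarray
    replicates: tuple
    seed: int
    params: dict

    def __post_init__(self):
        assert len(self.mean) == len(self.weeks) == len(self.sem)


def surrogate_cd8_series(seed: int = 0, amplitude: float = 30.0,
                         rise_week: float = 8.0, rise_scale: float = 1.2,
                         osc_amplitude: float = 0.12, osc_period_weeks: float = 4.0,
                         noise_scale: float = 0.15) -> SurrogateSeries:
    """Noisy sigmoid-with-oscillation weekly CD8 series.

    The deterministic shape is a logistic rise centred at ``rise_week``
    modulated by a slow oscillation; per-week noise and SEM scale with
    ``1/sqrt(n_k)`` for the stated replicate counts.  The shape
    constraint mean(week 10) > mean(week 6) is enforced for every seed;
    ``noise_scale=0`` returns the deterministic shape exactly.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(CD8_WEEKS, dtype=float)
    n_k = np.asarray(CD8_REPLICATES, dtype=float)
    base = amplitude / (1.0 + np.exp(-(w - rise_week) / rise_scale))
    osc = 1.0 + osc_amplitude * np.sin(2.0 * np.pi * (w - rise_week) / osc_period_weeks)
    shape = base * osc
    noise = noise_scale * shape * rng.standard_normal(len(w)) / np.sqrt(n_k)
    mean = np.maximum(shape + noise, 0.0)
    # enforced qualitative structure: the week-8 rise separates early/late
    if mean[3] <= mean[1]:                      # week 10 vs week 6
        mean[3] = mean[1] * 1.5 + 1.0
    sem = noise_scale * np.maximum(mean, 1e-9) / np.sqrt(n_k)
    return SurrogateSeries(
        weeks=CD8_WEEKS, mean=mean, sem=sem, replicates=CD8_REPLICATES,
        seed=seed,
        params={"amplitude": amplitude, "rise_week": rise_week,
                "rise_scale": rise_scale, "osc_amplitude": osc_amplitude,
                "osc_period_weeks": osc_period_weeks,
                "noise_scale": noise_scale})


def mini_world(n_islets: int = 5, cells_per_islet: int = 64,
               pool_scale: float = 1.0,
               params: ParameterSet | None = None) -> SimulationConfig:
    """Desk-scale configuration with the full rule/parameter schema.

    ``n_islets * cells_per_islet`` beta cells are placed in
    radius-10 islet disks on the standard 201 x 201 grid; population
    counts (initial apoptotic cells, DC and naive pools) scale linearly
    with the beta-cell count relative to the 320-cell reference world,
    and the immune pools additionally by ``pool_scale``.
    """
    if n_islets <= 0 or cells_per_islet <= 0 or pool_scale <= 0:
        raise ValueError("mini_world needs positive sizes")
    n_beta = n_islets * cells_per_islet
    base = params if params is not None else ParameterSet()
    scale = n_beta / REFERENCE_BETA
    scaled = base.replace(
        init_apoptotic_beta=max(1, int(round(base.init_apoptotic_beta * scale))),
        dc_c=max(1, int(round(base.dc_c * scale * pool_scale))),
        n_naive_pool=max(1, int(round(base.n_naive_pool * scale * pool_scale))),
        n_resident_dc=max(1, int(round(base.n_resident_dc * scale * pool_scale))),
    )
    return SimulationConfig(
        n_islets=n_islets,
        islet_radius=10,
        n_beta_cells=n_beta,
        params=scaled,
    )
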