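"""Closed-form kinetic submodels coupled to the agent rules.

Two population-level expressions drive the hybrid model:

* **DC recruitment** — mass-action kinetics for dendritic cells entering
  islets from circulation.  Per one-hour step the increment is
  ``k_r * beta_AP * DC_c``, where ``beta_AP`` is the current apoptotic
  beta-cell count and ``DC_c`` the (constant) circulating DC count.  The
  rate ``k_r`` is drawn once per run from ``Normal(mu_r, sigma_r)``
  truncated at zero.

* **Beta-cell quiescence** — the quiescence period of viable beta cells
  shortens as the apoptotic fraction (a proxy for glucose load) rises:
  ``T(t) = (1 - beta_AP/beta_init)**gamma * T0``.  With ``T0 = 7`` days and
  70% apoptotic cells, ``gamma = 1`` gives a 2-day quiescence period,
  matching the glucose-stimulated replication measurements the exponent
  was estimated from.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "dc_recruited",
    "draw_recruit_rate",
    "quiescence_period",
    "estimate_gamma",
]


def dc_recruited(
    k_r: float,
    beta_ap: float,
    dc_c: float,
    rng: np.random.Generator | None = None,
    mode: str = "poisson",
) -> int:
    """Number of DCs recruited from circulation this tick.

    Implements the mass-action increment ``DC_r(t+1) - DC_r(t) =
    k_r * beta_AP(t) * DC_c``.  The expected value is generally
    non-integer; by default a Poisson draw with that mean preserves the
    mean while adding demographic noise (``mode="nearest"`` rounds
    deterministically instead).
    """
    if k_r < 0 or beta_ap < 0 or dc_c < 0:
        raise ValueError("dc_recruited requires non-negative inputs")
    mean = k_r * beta_ap * dc_c
    if mode == "nearest" or rng is None:
        return int(round(mean))
    if mode == "poisson":
        return int(rng.poisson(mean))
    raise ValueError(f"unknown rounding mode: {mode!r}")


def draw_recruit_rate(mu_r: float, sigma_r: float, rng: np.random.Generator) -> float:
    """Draw the per-run recruiting rate k_r ~ Normal(mu_r, sigma_r), >= 0."""
    return max(0.0, float(rng.normal(mu_r, sigma_r)))


def quiescence_period(T0: float, beta_ap: float, beta_init: float, gamma: float) -> float:
    """Current quiescence period of viable beta cells, in the units of ``T0``.

    ``T(t) = (1 - beta_ap/beta_init)**gamma * T0``; non-increasing in the
    apoptotic count and equal to ``T0`` when no cells are apoptotic.
    """
    if beta_init <= 0:
        raise ValueError("beta_init must be positive")
    if beta_ap < 0 or beta_ap > beta_init:
        raise ValueError("beta_ap must lie in [0, beta_init]")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return (1.0 - beta_ap / beta_init) ** gamma * T0


def estimate_gamma(T0_days: float, target_days: float, apoptotic_fraction: float) -> int:
    """Estimate the glucose-metabolism exponent from one calibration point.

    Solves ``T0 * (1 - f)**gamma = target`` for ``gamma`` and returns the
    nearest integer.  With the literature values (7-day baseline, 2-day
    glucose-stimulated period at 70% apoptotic cells) this yields 1.
    """
    if not 0.0 < apoptotic_fraction < 1.0:
        raise ValueError("apoptotic_fraction must lie in (0, 1)")
    if T0_days <= 0 or target_days <= 0:
        raise ValueError("periods must be positive")
    if target_days > T0_days:
        raise ValueError("target period exceeds baseline: gamma would be negative")
    gamma = math.log(target_days / T0_days) / math.log(1.0 - apoptotic_fraction)
    return int(round(gamma))
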