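"""Simulation arena construction.

The world is a bounded 2D patch grid (default 201 x 201) partitioned into
three bands mimicking the anatomy relevant to T1D autoimmunity: the islet
region (bottom of the grid), and a top band split between circulation and
the pancreatic lymph nodes (PLN).  Islets are disks of radius
``islet_radius`` around randomly chosen centre patches; disks may overlap
and form clusters, and beta cells are placed by a uniform random draw over
the union of the disks until exactly ``n_beta_cells`` patches are filled.
Beta cells are immobile and therefore live on patches; all other cell
types are mobile agents.

At the default scale the world holds 8080 beta-cell patches,
approximately one percent of the beta-cell mass of a NOD mouse pancreas,
with a physical grid length of 1.32 um (a 100 um islet spanning a
38-patch radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import Agent, DC, NAIVE_T
from .config import ConfigurationError, SimulationConfig

__all__ = ["World", "build_world", "grid_scale",
           "CIRCULATION", "ISLET", "PLN",
           "BETA_HEALTHY", "BETA_APOPTOTIC", "BETA_DEAD"]

# region labels
CIRCULATION, ISLET, PLN = 0, 1, 2
# beta patch states
BETA_HEALTHY, BETA_APOPTOTIC, BETA_DEAD = 0, 1, 2


def grid_scale(islet_diameter_um: float, islet_radius_cells: int) -> float:
    """Physical length of one grid cell in micrometres, to 2 decimals.

    A single islet of diameter ``islet_diameter_um`` spans
    ``2 * islet_radius_cells`` patches; the default 100 um / 38-cell
    radius gives 1.32 um per cell.
    """
    if islet_diameter_um <= 0 or islet_radius_cells <= 0:
        raise ValueError("islet diameter and radius must be positive")
    return round(islet_diameter_um / (2.0 * islet_radius_cells), 2)


@dataclass
class World:
    """Spatial state, beta-cell patch state, and mobile agent collections."""

    config: SimulationConfig
    region: np.ndarray                   # (H, W) int8 region labels
    islet_centers: np.ndarray            # (n_islets, 2) row/col
    disk_patches: np.ndarray             # (K, 2) union of islet disks
    beta_pos: np.ndarray                 # (N, 2) int32
    beta_status: np.ndarray              # (N,) int8
    beta_quiesc: np.ndarray              # (N,) float64, hours in quiescence
    beta_repl_until: np.ndarray          # (N,) float64, replication end hour (-1 idle)
    beta_apop_since: np.ndarray          # (N,) float64, hour the cell went apoptotic
    occupancy: np.ndarray                # (H, W) int32 beta index or -1
    healthy_grid: np.ndarray             # (H, W) bool
    agents: dict[str, list[Agent]]
    rng: np.random.Generator
    onset_threshold_frac: float
    beta_init: int
    k_r: float = 0.0                     # drawn by the engine at run start
    clock_h: int = 0
    births_total: int = 0
    pln_patches: np.ndarray = field(default=None, repr=False)
    islet_region_patches: np.ndarray = field(default=None, repr=False)
    circulation_patches: np.ndarray = field(default=None, repr=False)
    disk_mask: np.ndarray = field(default=None, repr=False)   # (H, W) bool
    islet_mask: np.ndarray = field(default=None, repr=False)  # (H, W) bool
    lesion_grid: np.ndarray = field(default=None, repr=False)  # apoptotic/dead beta

    # ------------------------------------------------------------------
    def counts(self) -> dict[str, int]:
        """Population tallies used by the per-hour trajectory record."""
        healthy = int(np.count_nonzero(self.beta_status == BETA_HEALTHY))
        apoptotic = int(np.count_nonzero(self.beta_status == BETA_APOPTOTIC))
        dead = int(np.count_nonzero(self.beta_status == BETA_DEAD))
        infiltrating = 0
        for cls in ("activatedT", "ctl"):
            for a in self.agents[cls]:
                if self.region[a.y, a.x] == ISLET:
                    infiltrating += 1
        n_dc_islet = sum(1 for a in self.agents["dc"]
                         if self.region[a.y, a.x] == ISLET)
        n_apc_pln = sum(1 for a in self.agents["apc"]
                        if self.region[a.y, a.x] == PLN)
        return {
            "n_healthy_beta": healthy,
            "n_apoptotic_beta": apoptotic,
            "n_dead_beta": dead,
            "n_infiltrating_cd8": infiltrating,
            "n_dc_islet": n_dc_islet,
            "n_apc_pln": n_apc_pln,
        }

    def random_patch(self, patches: np.ndarray) -> tuple[int, int]:
        i = int(self.rng.integers(len(patches)))
        return int(patches[i, 1]), int(patches[i, 0])  # (x, y)


def _region_map(config: SimulationConfig) -> np.ndarray:
    H, W = config.grid_height, config.grid_width
    layout = config.region_layout
    region = np.full((H, W), ISLET, dtype=np.int8)
    top_rows = H - int(round(H * layout.islet_frac))
    top_rows = max(1, min(H - 1, top_rows))
    circ_cols = int(round(W * layout.circulation_frac))
    circ_cols = max(1, min(W - 1, circ_cols))
    region[:top_rows, :circ_cols] = CIRCULATION
    region[:top_rows, circ_cols:] = PLN
    return region


def build_world(config: SimulationConfig, rng_seed: int | None = None) -> World:
    """Construct the arena and place the initial cell populations.

    The same ``(config, rng_seed)`` pair always yields an identical world.
    Raises :class:`ConfigurationError` if the islet disks cannot hold the
    requested number of beta cells.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    H, W = config.grid_height, config.grid_width
    region = _region_map(config)

    islet_rows, islet_cols = np.nonzero(region == ISLET)
    islet_region_patches = np.column_stack([islet_rows, islet_cols]).astype(np.int32)
    pln_rows, pln_cols = np.nonzero(region == PLN)
    pln_patches = np.column_stack([pln_rows, pln_cols]).astype(np.int32)
    circ_rows, circ_cols = np.nonzero(region == CIRCULATION)
    circulation_patches = np.column_stack([circ_rows, circ_cols]).astype(np.int32)

    # islet centres: distinct patches inside the islet band
    if config.n_islets > 0:
        idx = rng.choice(len(islet_region_patches), size=config.n_islets, replace=False)
        centers = islet_region_patches[idx]
    else:
        centers = np.empty((0, 2), dtype=np.int32)

    # union of islet disks, clipped to the grid and the islet band
    r = config.islet_radius
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = np.column_stack([dy[dy**2 + dx**2 <= r**2], dx[dy**2 + dx**2 <= r**2]])
    if len(centers):
        pts = (centers[:, None, :] + disk[None, :, :]).reshape(-1, 2)
        inb = (pts[:, 0] >= 0) & (pts[:, 0] < H) & (pts[:, 1] >= 0) & (pts[:, 1] < W)
        pts = pts[inb]
        pts = pts[region[pts[:, 0], pts[:, 1]] == ISLET]
        disk_patches = np.unique(pts, axis=0).astype(np.int32)
    else:
        disk_patches = np.empty((0, 2), dtype=np.int32)

    if len(disk_patches) < config.n_beta_cells:
        raise ConfigurationError(
            f"requested {config.n_beta_cells} beta cells but the islet disks "
            f"hold only {len(disk_patches)} patches")

    sel = rng.choice(len(disk_patches), size=config.n_beta_cells, replace=False)
    beta_pos = disk_patches[np.sort(sel)]
    n = config.n_beta_cells

    params = config.params
    n_apop = int(min(params.init_apoptotic_beta, n))
    beta_status = np.zeros(n, dtype=np.int8)
    if n_apop > 0:
        apop_idx = rng.choice(n, size=n_apop, replace=False)
        beta_status[apop_idx] = BETA_APOPTOTIC

    # quiescence clocks staggered uniformly over the 7-day baseline period
    beta_quiesc = rng.uniform(0.0, params.quiescence_T0_h, size=n)
    beta_repl_until = np.full(n, -1.0)
    beta_apop_since = np.where(beta_status == BETA_APOPTOTIC, 0.0, -1.0)

    occupancy = np.full((H, W), -1, dtype=np.int32)
    occupancy[beta_pos[:, 0], beta_pos[:, 1]] = np.arange(n)
    healthy_grid = np.zeros((H, W), dtype=bool)
    hmask = beta_status == BETA_HEALTHY
    healthy_grid[beta_pos[hmask, 0], beta_pos[hmask, 1]] = True
    lesion_grid = np.zeros((H, W), dtype=bool)
    lesion_grid[beta_pos[~hmask, 0], beta_pos[~hmask, 1]] = True

    disk_mask = np.zeros((H, W), dtype=bool)
    if len(disk_patches):
        disk_mask[disk_patches[:, 0], disk_patches[:, 1]] = True

    onset_threshold = float(rng.uniform(config.onset_fraction_low,
                                        config.onset_fraction_high))

    agents: dict[str, list[Agent]] = {cls: [] for cls in
                                      ("antigen", "dc", "apc", "naiveT",
                                       "activatedT", "ctl")}
    world = World(
        config=config, region=region, islet_centers=centers,
        disk_patches=disk_patches, beta_pos=beta_pos, beta_status=beta_status,
        beta_quiesc=beta_quiesc, beta_repl_until=beta_repl_until,
        beta_apop_since=beta_apop_since, occupancy=occupancy,
        healthy_grid=healthy_grid, agents=agents, rng=rng,
        onset_threshold_frac=onset_threshold, beta_init=n,
        pln_patches=pln_patches, islet_region_patches=islet_region_patches,
        circulation_patches=circulation_patches, disk_mask=disk_mask,
        islet_mask=(region == ISLET), lesion_grid=lesion_grid,
    )

    # islet-resident DCs live inside the islet disks
    for _ in range(int(params.n_resident_dc)):
        x, y = world.random_patch(disk_patches)
        agents[DC].append(Agent(DC, x, y))
    # naive CD8 pool resident in PLN
    lo, hi = params.naive_lifespan_d
    for _ in range(int(params.n_naive_pool)):
        x, y = world.random_patch(pln_patches)
        agents[NAIVE_T].append(Agent(NAIVE_T, x, y,
                                     lifespan_h=float(rng.uniform(lo, hi) * 24.0)))
    return world
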