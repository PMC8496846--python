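"""Build the full-scale simulation arena and inspect its geometry.

The default world is a 201 x 201 patch grid: the bottom 70% of rows is
the islet region, the top band splits into circulation and pancreatic
lymph nodes.  25 islet disks of radius 38 hold exactly 8080 beta-cell
patches (about 1% of a NOD mouse's beta-cell mass) at 1.32 um per grid
cell.
"""

import numpy as np

from t1dsim import SimulationConfig, build_world, grid_scale

config = SimulationConfig()
world = build_world(config, rng_seed=0)

print(f"grid: {config.grid_width} x {config.grid_height} patches, "
      f"{grid_scale(config.islet_diameter_um, config.islet_radius)} um per patch")
print(f"islets: {config.n_islets} disks of radius {config.islet_radius}")
print(f"beta cells placed: {len(world.beta_pos)} "
      f"({np.count_nonzero(world.beta_status == 1)} initially apoptotic)")
print(f"onset threshold drawn for this run: "
      f"{world.onset_threshold_frac:.2f} of initial beta mass")
counts = world.counts()
print(f"initial populations: {counts}")
# The onset threshold is redrawn per run in [0.10, 0.30]; a run reaches
# overt T1D when the healthy fraction falls to it.
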