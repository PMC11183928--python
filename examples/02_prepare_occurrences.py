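"""Clean, deduplicate and spatially thin a raw occurrence table.

The cleaning funnel removes invalid and duplicate rows, keeps one record per
2.5-arc-minute cell per species, enforces a minimum of 15 records per
species, and rarefies records to a 1-km minimum spacing.
"""

import numpy as np

import avistack as av

env = av.make_landscape(80, 80, [av.LayerSpec("bio1", "continuous", 0.0)], seed=4)
truth = av.make_virtual_species(env, {"intercept": -2.0, "bio1": 1.5}, species="demo")
raw = av.sample_occurrences(truth, 2000, seed=5)

grid = env.grid
extent = (grid.x_origin, grid.y_origin - grid.n_rows * grid.cell_size,
          grid.x_origin + grid.n_cols * grid.cell_size, grid.y_origin)
prepped, log = av.prepare_occurrences(raw, extent, min_records=15,
                                      dedup_arcmin=2.5, thin_km=1.0, seed=6)

print("record funnel (stage: records / species):")
for stage in log.stages:
    print(f"  {stage['stage']:>12}: {stage['n_records']:5d} / {stage['n_species']}")
if log.flagged_species:
    print("species below the minimum after thinning:", log.flagged_species)

lon = prepped["longitude"].to_numpy()
lat = prepped["latitude"].to_numpy()
d = av.haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
np.fill_diagonal(d, np.inf)
print(f"minimum pairwise distance after thinning: {d.min():.2f} km (>= 1.0 required)")
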