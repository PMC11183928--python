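"""Generate a synthetic landscape with a known virtual species and records.

Builds a 100x100 environmental stack (two correlated climate-like layers and
a categorical land-cover layer), defines a low-prevalence virtual species
responding to the first layer, and samples biased presence records from it.
"""

import numpy as np

import avistack as av

env = av.make_landscape(
    100,
    100,
    [
        av.LayerSpec("bio1", "continuous", 0.0),
        av.LayerSpec("bio12", "continuous", 0.6),
        av.LayerSpec("LC", "categorical", 0.0, n_classes=5),
    ],
    seed=1,
)
r = np.corrcoef(env.layers["bio1"].ravel(), env.layers["bio12"].ravel())[0, 1]
print(f"layers: {env.layer_names}; realized corr(bio1, bio12) = {r:.3f} (target 0.6)")

truth = av.make_virtual_species(env, {"intercept": -3.0, "bio1": 2.0}, species="demo")
print(f"virtual-species prevalence (mean true suitability) = {np.nanmean(truth.surface):.3f}")

occ = av.sample_occurrences(truth, 300, seed=2)
print(f"sampled {len(occ)} presence records; columns: {', '.join(occ.columns)}")

pa = av.make_protected_areas(env, target_fraction=0.25, n_patches=6, seed=3)
print(f"protected-area mask covers {100 * pa.fraction:.1f}% of cells (target 25% +/- 2)")
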