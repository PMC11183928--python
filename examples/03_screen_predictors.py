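"""Collinearity screening of candidate climate layers at |r| > 0.7.

Two of the five candidate layers are generated nearly collinear with the
first; the greedy screen keeps a threshold-feasible subset while elevation
and land cover bypass screening.
"""

import avistack as av

env = av.make_landscape(
    120,
    120,
    [
        av.LayerSpec("bio1", "continuous", 0.0),
        av.LayerSpec("bio2", "continuous", 0.9),   # collinear with bio1
        av.LayerSpec("bio9", "continuous", 0.85),  # collinear with bio1
        av.LayerSpec("bio12", "continuous", 0.2),
        av.LayerSpec("bio13", "continuous", -0.4),
        av.LayerSpec("ele", "continuous", 0.1),
        av.LayerSpec("LC", "categorical", 0.0),
    ],
    seed=7,
)

candidates = ["bio1", "bio2", "bio9", "bio12", "bio13"]
corr = av.pearson_matrix(env, candidates)
print("pairwise Pearson r:")
print(corr.matrix.round(2).to_string())

kept = av.select_variables(corr, threshold=0.7)
print(f"\nkept after screening at |r| > 0.7: {kept}")
print("always kept (bypass screening): ['ele', 'LC']")
print(f"final predictor set: {kept + ['ele', 'LC']}")
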