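"""PCoA-RGB encoding: turn community dissimilarities into station colors.

Embeds a dissimilarity matrix by classical scaling (with the Cailliez
correction when the matrix is not Euclidean) and maps the first three
axes to red/green/blue channels, scaled by their eigenvalue ratios, so
that similar colors mean similar communities.
"""

import numpy as np
import pandas as pd

from seascape import jaccard_dissimilarity, pcoa, rgb_from_ordination

rng = np.random.default_rng(3)
# three groups of samples with group-specific feature blocks
blocks = []
for g in range(3):
    base = np.zeros((4, 90), dtype=int)
    base[:, 30 * g : 30 * (g + 1)] = rng.integers(0, 2, size=(4, 30)) | 1
    blocks.append(base)
table = pd.DataFrame(np.vstack(blocks), index=[f"g{g}s{i}" for g in range(3) for i in range(4)])

D = jaccard_dissimilarity(table)
ordn = pcoa(D)
print("eigenvalue ratios (lambda_r, lambda_g, lambda_b):", ordn.lambda_ratios.round(3))
print("additive (Cailliez) constant applied:", round(ordn.additive_constant, 3))

colors = rgb_from_ordination(ordn, use_eigenvalue_ratios=True)
print("\nstation colors (samples of the same group share similar colors):")
print(colors.to_string())
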