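"""Identify the two signaling states from drug response signatures.

Clusters drugs by their 12-reporter signatures (Euclidean/Ward.D2), fits a
PCA, and computes the per-drug state metrics: conformity (psi), adherence to
PC1, and drug strength.  The phi metric quantifies how well the pre-treatment
coordinate system explains the post-treatment correlations.
"""

import numpy as np
import pandas as pd

from signalome.scoring import score_screen
from signalome.simulate import generate_screen, three_group_design
from signalome.states import cluster_drugs, fit_pca, pathway_correlations, phi_metric

design = three_group_design(
    n_drugs=40,
    cells_per_well=200,
    seed=2,
    timepoints=(0.0, 1.0, 6.0, 12.0, 24.0, 48.0),
)
cells, truth = generate_screen(design)
matrix = score_screen(cells, design.modes)
final = matrix.slice(48.0)

clusters = cluster_drugs(final, k=3)
print("cluster sizes:", clusters.labels.value_counts().to_dict())

system, coords = fit_pca(final)
print(f"PC1 explains {100 * system.explained_fraction[0]:.1f}% of variance")
u = pd.Series(truth.state_axis, index=truth.pathways)
cos = abs(float(system.loadings[:, 0] @ u.loc[list(system.pathways)]))
print(f"|cos(PC1, planted state axis)| = {cos:.3f}")

print("\nper-drug state metrics (first 5):")
print(coords[["PC1", "psi", "adherence", "strength"]].head().round(3))

# phi: project each timepoint's scores onto the pre-treatment PCA basis
reference, _ = fit_pca(matrix.slice(0.0))
print("\nphi trajectory (persistence of the pre-treatment structure):")
for t in matrix.timepoints:
    phi = phi_metric(matrix.slice(t), reference)
    print(f"  phi(t={t:>4.0f} h) = {phi:.3e}")

corr = pathway_correlations(final)
off = corr.to_numpy()[np.triu_indices(len(corr), 1)]
print(f"median |pathway correlation| at 48 h: {np.median(np.abs(off)):.2f}")

# psi near +1/-1 marks drugs conforming to one of the two anticorrelated
# signaling states.  The phi trajectory shows homeostasis dynamics: the
# pre-treatment basis explains the 0-h structure (phi well below 1), loses
# relevance at 1 h when compound-specific shocks scramble the correlations
# (phi rises), then regains it as the shared stress state dominates.
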