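"""The linking statistics: Tukey letters, Spearman, varpart, envfit.

Runs each procedure on a simulated study: which treatments differ in
carbon use efficiency, how soil chemistry correlates with the nematode
indices, how much community variation chemistry and indices explain
jointly, and which variables align with the ordination.
"""

import numpy as np
import pandas as pd

from soilfoodweb import (
    anova_tukey_letters, bray_curtis, compute_index_table,
    envfit_permutation, generate_dataset, physiology_table, rarefy,
    spearman_matrix, variance_partition,
)

ds = generate_dataset(seed=42)
treat = ds.chemistry["treatment"]
physio = physiology_table(ds.incubation, ds.titration)
indices = compute_index_table(ds.nematode_counts, ds.traits)

res = anova_tukey_letters(physio["CUE"], treat)
print(f"CUE one-way ANOVA: F={res.F:.2f}, p={res.p:.4f}")
for g in res.means:
    print(f"  {g:4s} mean={res.means[g]:.3f}  {res.letters[g]}")
# treatments sharing a letter are not significantly different (Tukey HSD)

rho, p = spearman_matrix(
    ds.chemistry[["SOC", "TN", "TP"]], indices[["EI", "CI", "SI"]]
)
print("\nSpearman rho (chemistry x indices):")
print(rho.round(2))

bc = bray_curtis(rarefy(ds.otu_table, 28883, seed=0))
D = bc.to_numpy()
J = np.eye(len(D)) - np.ones_like(D) / len(D)
vals, vecs = np.linalg.eigh(-0.5 * J @ D**2 @ J)
scores = pd.DataFrame(
    vecs[:, np.argsort(vals)[::-1][:2]], index=bc.index,
    columns=["PCo1", "PCo2"],
)
part = variance_partition(
    scores, ds.chemistry[["pH", "SOC", "TN", "TP"]],
    indices[["EI", "SI", "CI", "MI"]],
)
print(f"\nvarpart: chemistry-unique a={part.a:.2f}, shared b={part.b:.2f}, "
      f"indices-unique c={part.c:.2f}, residual d={part.d:.2f}")
# adjusted-R2 shares of bacterial community variation (a+b+c+d=1)

fit = envfit_permutation(
    scores, ds.chemistry[["SOC", "TN", "TP"]], n_perm=199, seed=0
)
print("\nenvfit on the ordination:")
print(fit.round(3))
# p is the permutation probability of an equal-or-larger r2 under
# random reassignment of the variable to samples
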