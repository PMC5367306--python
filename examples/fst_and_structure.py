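"""Pairwise F_ST, FDR correction, genotype PCA and isolation by distance on
the plasticity scenario: nine populations, genetically identical except one
drift-diverged outlier.
"""

import numpy as np

from scallopop import DistanceMatrix, genetic_pca, mantel_test, pairwise_fst
from scallopop.io import read_genepop, write_genepop
from scallopop.pipeline import scenario_genotypes

gt = scenario_genotypes(seed=11, n_loci=300, n_per_pop=10)

# Genepop round trip: the interchange format for both marker types
write_genepop(gt, "scratch_example.gen")
gt = read_genepop("scratch_example.gen")

fst = pairwise_fst(gt, n_perm=499, seed=11)
iu = np.triu_indices(9, 1)
print("pairwise theta, outlier row (pop1 vs others):")
print(np.round(fst.theta[0, 1:], 3))
sig = fst.q[iu] <= 0.05
out_mask = (iu[0] == 0) | (iu[1] == 0)
print(f"significant after FDR: {sig.sum()} of 36 pairs "
      f"({sig[out_mask].sum()} of 8 involve the outlier)")

pca = genetic_pca(gt)
print("\ngenotype PCA, % variance on PC1/PC2:",
      np.round(100 * pca.variance_fractions[:2], 1))
pop1 = [i for i, p in enumerate(gt.pop_labels) if p == "pop1"]
rest = [i for i, p in enumerate(gt.pop_labels) if p != "pop1"]
print("PC1 mean, outlier vs rest: "
      f"{pca.scores[pop1, 0].mean():.2f} vs {pca.scores[rest, 0].mean():.2f}")

coast = np.abs(np.subtract.outer(np.arange(9), np.arange(9))) * 12.0  # km
m = mantel_test(fst.to_distance(), DistanceMatrix(gt.populations, coast),
                n_perm=999, seed=11)
print(f"\nMantel r = {m.statistic:.3f}, p = {m.p:.3f} "
      "(no isolation by distance: divergence is confined to the outlier)")
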