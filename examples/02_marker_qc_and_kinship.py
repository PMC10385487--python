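"""Marker QC and relationship matrices on a simulated parent panel.

Filters SNPs on minor allele frequency and missingness, prunes linked
markers with the kinship-corrected rv2 statistic (keeping the most
informative site of each linked pair), and builds the additive (VanRaden)
and dominance (heterozygosity-coded) relationship matrices.
"""

import numpy as np

from hybridgp.markers import (filter_snps, prune_ld, pic, allele_freqs, pca,
                              grm_vanraden, dominance_matrix)
from hybridgp.simulate import SimConfig, TrialLayout, simulate_dataset, hybrid_dosages

cfg = SimConfig(n_founders=8, n_parents=60, n_snps=150, n_chromosomes=6,
                n_hybrids=80, mosaic_switch_prob=0.02,   # long segments -> real LD
                trials=(TrialLayout("Est", 2019, 10, 16),), seed=3)
ds = simulate_dataset(cfg)
parents = ds["parents"]

kept = filter_snps(parents, maf_min=0.05, miss_max=0.10)
g = parents[kept]
print(f"MAF/missingness filter: {len(kept)}/{parents.shape[1]} SNPs kept")

K = grm_vanraden(g).to_numpy()
K_ridged = K + 0.01 * np.trace(K) / K.shape[0] * np.eye(K.shape[0])
pruned = prune_ld(g, K_ridged, rv2_max=0.5)
print(f"LD pruning (rv2 >= 0.5): {len(pruned)} SNPs survive; mean PIC of "
      f"survivors {np.mean(pic(allele_freqs(g[pruned]).to_numpy())):.3f}")

res = pca(g[pruned])
print(f"PCA: first two components carry "
      f"{100 * res.cum_var[1]:.0f}% of marker variance "
      "(low values = weak population structure)")

Gp = grm_vanraden(g[pruned])
print(f"parent GRM diagonal mean {np.diag(Gp).mean():.2f} "
      "(~2 for fully inbred lines)")
Xh = hybrid_dosages(parents, ds["crossplan"])
D = dominance_matrix(Xh[pruned])
print(f"hybrid dominance matrix: {D.shape[0]} hybrids, "
      f"diagonal mean {np.diag(D).mean():.2f}")
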