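"""Second-stage combining-ability models and the genetic-variance partition.

Fits the GCA model (parental additive effects through the genomic
relationship matrix, genotype-by-trial through I (x) Gh, observations
weighted by their first-stage squared standard errors), then the GCA+SCA
model with the dominance kernel while holding the GCA and G-by-T variances
fixed, and prints the share of genetic variance carried by each component.
"""

import warnings

import numpy as np

from hybridgp.markers import grm_vanraden, dominance_matrix
from hybridgp.simulate import SimConfig, simulate_dataset, hybrid_dosages
from hybridgp.stage1 import run_stage1
from hybridgp.stage2 import fit_gca, fit_gca_sca, partition_variance

cfg = SimConfig.desk_scale(seed=5, n_parents=60, n_hybrids=100, n_snps=120,
                           var_gca=6.0, var_sca=2.0, var_gxt=1.0,
                           var_delta=1.0)
ds = simulate_dataset(cfg)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    blues = run_stage1(ds["plots"], ["TY"])["TY"]

Xh = hybrid_dosages(ds["parents"], ds["crossplan"])
Gp, Gh, D = grm_vanraden(ds["parents"]), grm_vanraden(Xh), dominance_matrix(Xh)

gca = fit_gca(blues.table, ds["crossplan"], Gp, Gh)
sca = fit_gca_sca(blues.table, ds["crossplan"], Gp, Gh, D, gca)

print("variance components (GCA model):")
print(f"  var_gca = {gca.var_gca:.2f}  var_gxt = {gca.var_gxt:.2f}  "
      f"var_delta = {gca.var_delta:.2f}")
print("variance components (GCA+SCA, first two held fixed):")
print(f"  var_sca = {sca.var_sca:.2f}  var_delta = {sca.var_delta:.2f}")

for fit in (gca, sca):
    a, s, d = partition_variance(fit).rounded()
    s_txt = "   --" if s is None else f"{s:5.2f}"
    print(f"{fit.model:8s} additive {a:5.2f}  sca {s_txt}  residual {d:5.2f}")
print("\nShares use sigma2_G = 2*var_gca + var_sca + var_delta; a high "
      "additive share says parental breeding values drive hybrid value.")
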