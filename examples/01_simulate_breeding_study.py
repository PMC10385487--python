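"""Generate a small synthetic hybrid-potato breeding study.

Builds 40 homozygous inbred parents from 8 founders, crosses them into 60
hybrids, and phenotypes every hybrid twice in each of four field trials
with spatially correlated plot errors.  The printed variance components are
the ground truth later examples try to recover.
"""

from hybridgp.simulate import SimConfig, TrialLayout, simulate_dataset

cfg = SimConfig(
    n_founders=8, n_parents=40, n_snps=120, n_chromosomes=6, n_hybrids=60,
    trials=(TrialLayout("Est", 2019, 10, 12), TrialLayout("Hee", 2019, 10, 12),
            TrialLayout("Est", 2020, 10, 12), TrialLayout("Hee", 2020, 10, 12)),
    var_gca=6.0, var_sca=1.0, var_gxt=1.0, var_delta=1.0,
    spatial=(8.0, 0.5, 0.5, 2.0), trait="TY", trait_mean=40.0, seed=7)

ds = simulate_dataset(cfg)
plots, truth = ds["plots"], ds["truth"]

print(f"parents:  {ds['parents'].shape[0]} lines x {ds['parents'].shape[1]} SNPs "
      "(all dosages 0/2: fully homozygous)")
print(f"hybrids:  {len(ds['crossplan'])} crosses, "
      f"{ds['crossplan']['both_years'].sum()} planted in both years")
print(f"plots:    {len(plots)} rows "
      f"({plots.groupby('trial').size().to_dict()})")
print("realized variance components (targets hit exactly by rescaling):")
for k, v in truth.realized.items():
    print(f"  {k:10s} {v:6.2f}")
print("\nEach plot value = trial mean + block + GCA_i + GCA_j + SCA + GxT"
      " + AR1xAR1 field error + nugget.")
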