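# hybridgp

Two-stage genomic prediction of hybrid performance for diploid hybrid
breeding programs (built around the hybrid-potato use case), with a
synthetic-data generator that makes the whole pipeline testable against
known ground truth.

## The problem

A hybrid breeding program crosses inbred parent lines and must decide,
long before every cross can be field-tested, which parents and which
specific crosses are worth making.  Genomic prediction answers this with
mixed models in two stages:

1. **Single-trial spatial analysis.** Each field trial (an RCBD with two
   replicates per hybrid) is fit per trait with a ladder of models — fixed
   hybrid and block effects, optionally a random column effect, crossed
   with four residual structures:

   * (3) `var(ε) = σ²ₑ I` (IID),
   * (4) `σ²ₑ Iᵣ ⊗ Σc(ρc)` (AR1 along columns),
   * (5) `σ²ₑ Iᵣ ⊗ Σc(ρc) + σ²η` (plus a nugget),
   * (6) `σ²ₑ Σr(ρr) ⊗ Σc(ρc) + σ²η` (AR1 rows × AR1 columns + nugget),

   where `Σ(ρ)ᵢⱼ = ρ^|i−j|`.  The minimum-AIC model supplies hybrid BLUEs
   `μ̂ᵢⱼf` with standard errors `ŝf`.

2. **Combining-ability GBLUP.** The BLUEs are modeled as

   `μ̂ᵢⱼf = βf + gᵢ + gⱼ + (sᵢⱼ) + δᵢⱼ + tᵢⱼf + rᵢⱼf`

   with parental general combining ability `g ~ N(0, σ²gca Gp)`
   (VanRaden genomic relationship matrix of the parents), specific
   combining ability `s ~ N(0, σ²sca D)` (dominance relationship matrix of
   the hybrids, GCA+SCA model only), an IID genetic residual `δ`, a
   hybrid-by-trial term `t ~ N(0, σ²gxt I_t ⊗ Gh)`, and a *known* diagonal
   residual fixed at the stage-1 squared standard errors
   (`R = ⊕f Diag(ŝf²)`).  The GCA+SCA model holds `σ²gca` and `σ²gxt`
   fixed at the GCA model's estimates so the additive/dominance partition
   is identifiable.  The share of genetic variance is reported as
   `2σ²gca / σ²G`, `σ²sca / σ²G`, `σ²δ / σ²G` with
   `σ²G = 2σ²gca + σ²sca + σ²δ`.

A separate raw-data multi-trial model with an unstructured
hybrid-by-location covariance provides broad-sense heritabilities,
coefficients of variation, and the across-trial BLUPs used as the
average-performance (AVG) prediction target.

Prediction is evaluated with the **evaluated-parent scheme**: parents are
randomly split into evaluated/unevaluated sets, hybrids with two evaluated
parents train the model, and hybrids with one (1EP) or zero (0EP)
evaluated parents are predicted — mirroring test crosses of elite × novel
parents and fully novel crosses.  Accuracy is the Pearson correlation
between predicted and realized hybrid performance; error is the RMSE as a
percentage of the trait mean.

All mixed models are fit by REML with a purpose-built average-information
solver supporting AR1⊗AR1 residuals, nugget effects, genomic kernels,
Kronecker structures, unstructured low-dimensional blocks, fixed variance
components and known diagonal residual weights.

## Worked example

```bash
python examples/03_spatial_stage1.py
```

prints (simulated single trial with a strong field trend):

```
selected model: (1) + (6)
corr(BLUE, true genetic value) = 0.964
corr(raw plot mean, truth)     = 0.838
```

The AIC ladder picks the AR1-rows × AR1-columns + nugget residual that
generated the field, and the spatially adjusted BLUEs recover the true
genetic ranking much better than raw plot means.  `examples/` contains one
script per capability (simulation, marker QC/kinship, stage 1,
multi-trial ratios, combining-ability partition, cross-validation), each
printing what it computes and what the numbers mean.

The same pipeline is available as a thin CLI:

```bash
hybridgp simulate --seed 1 --scale desk --out sim/
hybridgp qc --genotypes sim/genotypes.csv --out qc/
hybridgp stage1 --plots sim/plots.csv --trait TY --out s1/
hybridgp stage2 --blues s1/blues_TY.csv --genotypes sim/genotypes.csv \
    --crossplan sim/crossplan.csv --out s2/
```

File formats: genotypes as a lines × SNPs CSV dosage matrix (0/1/2,
blank = missing) or VCF; cross plan CSV `hybrid_id,parent1,parent2,...`;
plot table CSV `trial,location,year,row,col,block,hybrid_id,<traits>`;
BLUEs CSV `trial,hybrid_id,blue,se,model`.

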