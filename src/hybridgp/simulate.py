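"""Synthetic hybrid-breeding data with known ground truth.

Emulates a diploid hybrid breeding population: a small founder set, fully
homozygous inbred parent lines built as founder-haplotype mosaics, a sparse
factorial cross plan, and multi-trial RCBD field experiments with
spatially autocorrelated plot errors.  Every genetic quantity that the
downstream models try to estimate (parental GCA, hybrid SCA,
hybrid-by-trial deviations, spatial and nugget variances) is drawn from a
configured value and recorded, so parameter recovery and prediction
accuracy can be scored against truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["TrialLayout", "SimConfig", "TruthRecord", "simulate_founders",
           "simulate_inbreds", "simulate_crossplan", "simulate_phenotypes",
           "simulate_dataset", "hybrid_dosages"]


@dataclass(frozen=True)
class TrialLayout:
    """One field trial: a location-year with an n_rows x n_cols plot grid.

    Blocks split the field column-wise into ``n_blocks`` contiguous panels;
    each planted hybrid appears once per block (RCBD with two replicates by
    default).
    """
    location: str
    year: int
    n_rows: int
    n_cols: int
    n_blocks: int = 2

    @property
    def name(self) -> str:
        return f"{self.location}{self.year % 100:02d}"

    @property
    def capacity(self) -> int:
        return self.n_rows * (self.n_cols // self.n_blocks)


@dataclass
class SimConfig:
    """Parameters of the synthetic breeding study.

    Defaults reproduce the study conditions: 16 founders, 456 homozygous
    inbred parents genotyped at 704 SNPs, 769 hybrids from a sparse mating
    design, and four trials (two locations x two years) each laid out as an
    RCBD with two replicates per hybrid.  Variance defaults give a trait
    with mostly additive genetic variance and visible spatial trend.
    """
    n_founders: int = 16
    n_parents: int = 456
    n_snps: int = 704
    n_chromosomes: int = 12
    mosaic_switch_prob: float = 0.05
    n_hybrids: int = 769
    trials: tuple[TrialLayout, ...] = (
        TrialLayout("Est", 2019, 30, 40),
        TrialLayout("Hee", 2019, 30, 40),
        TrialLayout("Est", 2020, 30, 40),
        TrialLayout("Hee", 2020, 30, 40),
    )
    # trait variance components (trait units squared)
    var_gca: float = 6.0
    var_sca: float = 2.0
    var_gxt: float = 2.0
    var_delta: float = 1.5
    var_block: float = 1.0
    # residual plot error: sigma2_e spatial, AR1 correlations, nugget
    spatial: tuple[float, float, float, float] = (8.0, 0.5, 0.5, 2.0)
    trait: str = "TY"
    trait_mean: float = 40.0
    trial_offsets: tuple[float, ...] | None = None
    frac_year1: float = 0.62       # share of hybrids first evaluated in year 1
    frac_shared: float = 0.056     # share of hybrids planted in both years
    seed: int = 0

    def __post_init__(self):
        for nm in ("var_gca", "var_sca", "var_gxt", "var_delta", "var_block"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        s2e, rr, rc, s2n = self.spatial
        if s2e < 0 or s2n < 0:
            raise ValueError("spatial variances must be >= 0")
        if not (abs(rr) < 1 and abs(rc) < 1):
            raise ValueError("spatial autocorrelations must satisfy |rho| < 1")
        if not 0 <= self.mosaic_switch_prob <= 1:
            raise ValueError("mosaic_switch_prob must be in [0, 1]")
        if self.n_founders < 2 or self.n_snps < 1:
            raise ValueError("need n_founders >= 2 and n_snps >= 1")
        if self.n_hybrids > self.n_parents * (self.n_parents - 1) // 2:
            raise ValueError("n_hybrids exceeds the number of possible crosses")

    @classmethod
    def desk_scale(cls, seed: int = 0, **kw) -> "SimConfig":
        """Quarter-scale configuration: 120 parents, 200 hybrids, 4 trials."""
        defaults = dict(
            n_parents=120, n_snps=300, n_hybrids=200,
            trials=(
                TrialLayout("Est", 2019, 16, 22),
                TrialLayout("Hee", 2019, 16, 22),
                TrialLayout("Est", 2020, 16, 22),
                TrialLayout("Hee", 2020, 16, 22),
            ),
            seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class TruthRecord:
    """Ground truth of one simulated trait, stored with its seed."""
    seed: int
    gca: pd.Series                 # per parent
    sca: pd.Series                 # per hybrid
    gxt: pd.DataFrame              # hybrid x trial deviations
    delta: pd.Series               # per-hybrid genetic residual
    realized: dict[str, float]     # realized variance components
    plot_effects: pd.DataFrame     # per-plot spatial and nugget draws

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "gca": self.gca.to_dict(),
            "sca": self.sca.to_dict(),
            "gxt": {c: self.gxt[c].to_dict() for c in self.gxt.columns},
            "delta": self.delta.to_dict(),
            "realized": self.realized,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, stream])


def simulate_founders(cfg: SimConfig) -> np.ndarray:
    """Founder haplotypes: (2*n_founders, n_snps) binary array.

    Per-SNP allele frequencies are uniform on [0.1, 0.9]; any SNP that comes
    out monomorphic among the founder haplotypes is redrawn.
    """
    rng = _rng(cfg, 1)
    H = np.empty((2 * cfg.n_founders, cfg.n_snps), dtype=np.int8)
    for j in range(cfg.n_snps):
        while True:
            p = rng.uniform(0.1, 0.9)
            col = (rng.random(2 * cfg.n_founders) < p).astype(np.int8)
            if 0 < col.sum() < col.size:
                break
        H[:, j] = col
    return H


def _snp_ids(cfg: SimConfig) -> list[str]:
    chroms = np.array_split(np.arange(cfg.n_snps), cfg.n_chromosomes)
    ids = []
    for c, idx in enumerate(chroms, start=1):
        ids.extend(f"c{c:02d}_s{k + 1:04d}" for k in range(len(idx)))
    return ids


def snp_positions(cfg: SimConfig) -> pd.DataFrame:
    """Chromosome label and position (bp, synthetic) for each SNP."""
    chroms = np.array_split(np.arange(cfg.n_snps), cfg.n_chromosomes)
    rows = []
    for c, idx in enumerate(chroms, start=1):
        for k in range(len(idx)):
            rows.append((f"chr{c:02d}", (k + 1) * 1000))
    return pd.DataFrame(rows, columns=["chrom", "pos"], index=_snp_ids(cfg))


def simulate_inbreds(founders: np.ndarray, cfg: SimConfig,
                     return_mosaic: bool = False):
    """Fully homozygous parent lines as founder-haplotype mosaics.

    Each line follows a first-order Markov chain along every chromosome:
    with probability ``mosaic_switch_prob`` per adjacent SNP it jumps to a
    different founder haplotype, so segment lengths are geometric.  The line
    genotype doubles the mosaic haplotype, hence dosages are 0 or 2 at every
    SNP (no heterozygous calls).
    """
    rng = _rng(cfg, 2)
    n_hap = founders.shape[0]
    chroms = np.array_split(np.arange(cfg.n_snps), cfg.n_chromosomes)
    G = np.empty((cfg.n_parents, cfg.n_snps), dtype=np.int8)
    mosaic = np.empty((cfg.n_parents, cfg.n_snps), dtype=np.int16)
    for i in range(cfg.n_parents):
        for idx in chroms:
            cur = rng.integers(n_hap)
            for j in idx:
                if j != idx[0] and rng.random() < cfg.mosaic_switch_prob:
                    step = rng.integers(1, n_hap)
                    cur = (cur + step) % n_hap  # uniform over the other haplotypes
                G[i, j] = 2 * founders[cur, j]
                mosaic[i, j] = cur
    labels = [f"P{i + 1:03d}" for i in range(cfg.n_parents)]
    out = pd.DataFrame(G, index=pd.Index(labels, name="line"),
                       columns=_snp_ids(cfg))
    if return_mosaic:
        return out, mosaic
    return out


def simulate_crossplan(parents: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Sparse mating design: distinct unordered parent pairs, no selfs.

    Hybrids are split into year cohorts (nursery year before first trial
    year) with a thin shared set planted in both years.
    """
    rng = _rng(cfg, 3)
    names = list(parents.index)
    n = len(names)
    if cfg.n_hybrids > n * (n - 1) // 2:
        raise ValueError("requested more hybrids than available crosses")
    seen: set[tuple[int, int]] = set()
    pairs: list[tuple[int, int]] = []
    while len(pairs) < cfg.n_hybrids:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(key)
    years = sorted({t.year for t in cfg.trials})
    y1 = years[0]
    y2 = years[-1]
    n_shared = int(round(cfg.frac_shared * cfg.n_hybrids)) if len(years) > 1 else 0
    cohort = np.where(rng.random(cfg.n_hybrids) < cfg.frac_year1, y1, y2)
    shared = np.zeros(cfg.n_hybrids, dtype=bool)
    if n_shared:
        shared[rng.choice(cfg.n_hybrids, size=n_shared, replace=False)] = True
    rows = []
    for h, (i, j) in enumerate(pairs):
        rows.append({
            "hybrid_id": f"H{h + 1:04d}",
            "parent1": names[i],
            "parent2": names[j],
            "nursery": int(cohort[h]) - 1,
            "year_first": int(cohort[h]),
            "both_years": bool(shared[h]),
        })
    return pd.DataFrame(rows).set_index("hybrid_id", drop=False)


def hybrid_dosages(parents: pd.DataFrame, crossplan: pd.DataFrame) -> pd.DataFrame:
    """F1 dosages (parent_i + parent_j)/2 — deterministic for homozygous parents."""
    missing = sorted((set(crossplan["parent1"]) | set(crossplan["parent2"]))
                     - set(parents.index))
    if missing:
        raise KeyError(f"parents missing from genotype matrix: {missing[:5]}")
    a = parents.loc[crossplan["parent1"]].to_numpy(dtype=float)
    b = parents.loc[crossplan["parent2"]].to_numpy(dtype=float)
    return pd.DataFrame((a + b) / 2.0, index=crossplan.index.copy(),
                        columns=parents.columns)


def _scale_to_var(x: np.ndarray, target: float, ddof: int = 1) -> np.ndarray:
    """Center and rescale draws so their realized variance is exactly target."""
    x = x - x.mean()
    v = x.var(ddof=ddof) if x.size > ddof else 0.0
    if target <= 0 or v <= 0:
        return np.zeros_like(x)
    return x * np.sqrt(target / v)


def _planted_in(trial: TrialLayout, crossplan: pd.DataFrame,
                years: list[int]) -> pd.Index:
    if len(years) <= 1:
        return crossplan.index
    mask = (crossplan["year_first"] == trial.year) | crossplan["both_years"]
    return crossplan.index[mask]


def simulate_phenotypes(parents: pd.DataFrame, crossplan: pd.DataFrame,
                        cfg: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Plot-level phenotypes for every trial, plus the generating truth.

    The generative model mirrors the analysis models: parental GCA from
    marker additive effects, hybrid SCA from per-locus dominance effects,
    hybrid-by-trial deviations drawn with the hybrids' own additive kernel,
    an IID genetic residual per hybrid, random block effects, and an
    AR1xAR1 spatial field error plus nugget.  Additive, dominance, G-by-T
    and genetic-residual draws are rescaled post hoc so their realized
    variances equal the configured targets exactly.
    """
    cross_parents = set(crossplan["parent1"]) | set(crossplan["parent2"])
    missing = sorted(set(cross_parents) - set(parents.index))
    if missing:
        drop = crossplan["parent1"].isin(missing) | crossplan["parent2"].isin(missing)
        warnings.warn(f"dropping {int(drop.sum())} hybrids with ungenotyped "
                      f"parents (e.g. {missing[:3]})")
        crossplan = crossplan.loc[~drop]
    rng = _rng(cfg, 4)
    Xh = hybrid_dosages(parents, crossplan)
    hybrids = Xh.index
    n_h = len(hybrids)

    # parental GCA from marker additive effects, scaled to var_gca
    Zp = parents.to_numpy(dtype=float) - parents.to_numpy(dtype=float).mean(axis=0)
    alpha = rng.standard_normal(parents.shape[1])
    g_all = _scale_to_var(Zp @ alpha, cfg.var_gca)
    gca = pd.Series(g_all, index=parents.index)

    # hybrid SCA from per-locus dominance (heterozygosity) effects
    het = (Xh.to_numpy() == 1).astype(float)
    dom = rng.standard_normal(parents.shape[1])
    sca = pd.Series(_scale_to_var(het @ dom, cfg.var_sca), index=hybrids)

    # per-hybrid genetic residual (non-additive, non-dominance remainder)
    delta = pd.Series(_scale_to_var(rng.standard_normal(n_h), cfg.var_delta),
                      index=hybrids)

    # hybrid-by-trial deviations with the hybrids' additive kernel
    from .markers import grm_vanraden
    gxt = pd.DataFrame(0.0, index=hybrids, columns=[t.name for t in cfg.trials])
    if cfg.var_gxt > 0 and n_h > 1:
        Gh = grm_vanraden(Xh).to_numpy()
        L = np.linalg.cholesky(Gh + 1e-6 * np.eye(n_h))
        for t in cfg.trials:
            gxt[t.name] = _scale_to_var(L @ rng.standard_normal(n_h), cfg.var_gxt)

    years = sorted({t.year for t in cfg.trials})
    offsets = cfg.trial_offsets or tuple(0.0 for _ in cfg.trials)
    s2e, rho_r, rho_c, s2n = cfg.spatial
    rows = []
    plot_fx = []
    for t_idx, trial in enumerate(cfg.trials):
        planted = _planted_in(trial, crossplan, years)
        if len(planted) > trial.capacity:
            raise ValueError(
                f"trial {trial.name}: {len(planted)} hybrids exceed block "
                f"capacity {trial.capacity}")
        # spatially correlated field error on the full grid
        if s2e > 0:
            from .lmm import ar1_matrix
            Lr = np.linalg.cholesky(ar1_matrix(trial.n_rows, rho_r) +
                                    1e-10 * np.eye(trial.n_rows))
            Lc = np.linalg.cholesky(ar1_matrix(trial.n_cols, rho_c) +
                                    1e-10 * np.eye(trial.n_cols))
            E = np.sqrt(s2e) * (Lr @ rng.standard_normal(
                (trial.n_rows, trial.n_cols)) @ Lc.T)
        else:
            E = np.zeros((trial.n_rows, trial.n_cols))
        block_fx = rng.normal(0.0, np.sqrt(cfg.var_block), trial.n_blocks) \
            if cfg.var_block > 0 else np.zeros(trial.n_blocks)
        cols_per_block = trial.n_cols // trial.n_blocks
        for b in range(trial.n_blocks):
            cells = [(r, b * cols_per_block + c)
                     for r in range(trial.n_rows) for c in range(cols_per_block)]
            slots = rng.permutation(len(cells))[:len(planted)]
            order = rng.permutation(len(planted))
            for slot, h_idx in zip(slots, order):
                r, c = cells[slot]
                h = planted[h_idx]
                nug = rng.normal(0.0, np.sqrt(s2n)) if s2n > 0 else 0.0
                i, j = crossplan.loc[h, "parent1"], crossplan.loc[h, "parent2"]
                value = (cfg.trait_mean + offsets[t_idx] + block_fx[b]
                         + gca[i] + gca[j] + sca[h] + delta[h]
                         + gxt.loc[h, trial.name] + E[r, c] + nug)
                rows.append({
                    "trial": trial.name, "location": trial.location,
                    "year": trial.year, "row": r + 1, "col": c + 1,
                    "block": b + 1, "hybrid_id": h, cfg.trait: value,
                })
                plot_fx.append({
                    "trial": trial.name, "row": r + 1, "col": c + 1,
                    "spatial": E[r, c], "nugget": nug,
                })
    plots = pd.DataFrame(rows)
    realized = {
        "var_gca": float(gca.loc[sorted(cross_parents - set(missing))].var(ddof=1))
        if n_h else 0.0,
        "var_sca": float(sca.var(ddof=1)) if n_h > 1 else 0.0,
        "var_delta": float(delta.var(ddof=1)) if n_h > 1 else 0.0,
        "var_gxt": float(np.mean([gxt[c].var(ddof=1) for c in gxt.columns])),
    }
    truth = TruthRecord(seed=cfg.seed, gca=gca, sca=sca, gxt=gxt, delta=delta,
                        realized=realized, plot_effects=pd.DataFrame(plot_fx))
    return plots, truth


def simulate_stage2_response(crossplan: pd.DataFrame, Gp: pd.DataFrame,
                             Gh: pd.DataFrame, D: pd.DataFrame | None,
                             trials: list[str], varcomps: dict[str, float],
                             se: float | np.ndarray = 1.0,
                             trial_means: dict[str, float] | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Hybrid-by-trial responses drawn directly from the combining model.

    Draws g ~ N(0, var_gca * Gp), s ~ N(0, var_sca * D),
    t ~ N(0, var_gxt * I (x) Gh), delta ~ N(0, var_delta * I) and a residual
    with known standard errors, and returns a BLUE-shaped table
    (trial, hybrid_id, blue, se).  Unlike the plot-level generator, truth is
    expressed exactly on the model's kernel scale, which is what a variance
    -component recovery study needs.
    """
    rng = np.random.default_rng(seed)
    cp = crossplan.reset_index(drop=True)
    parents = list(Gp.index)
    hybrids = list(cp["hybrid_id"])
    n_h = len(hybrids)

    def _mvn(K, scale):
        if scale <= 0:
            return np.zeros(K.shape[0])
        L = np.linalg.cholesky(K + 1e-9 * np.eye(K.shape[0]))
        return np.sqrt(scale) * (L @ rng.standard_normal(K.shape[0]))

    g = pd.Series(_mvn(Gp.to_numpy(), varcomps.get("var_gca", 0.0)),
                  index=parents)
    Gh_al = Gh.loc[hybrids, hybrids].to_numpy()
    s = np.zeros(n_h)
    if D is not None and varcomps.get("var_sca", 0.0) > 0:
        s = _mvn(D.loc[hybrids, hybrids].to_numpy(), varcomps["var_sca"])
    delta = rng.normal(0.0, np.sqrt(varcomps.get("var_delta", 0.0)), n_h) \
        if varcomps.get("var_delta", 0.0) > 0 else np.zeros(n_h)
    rows = []
    se = np.broadcast_to(np.asarray(se, dtype=float), (len(trials), n_h))
    for t_i, trial in enumerate(trials):
        t_dev = _mvn(Gh_al, varcomps.get("var_gxt", 0.0))
        mu_t = (trial_means or {}).get(trial, 0.0)
        for h_i, h in enumerate(hybrids):
            p1, p2 = cp.loc[h_i, "parent1"], cp.loc[h_i, "parent2"]
            e = rng.normal(0.0, se[t_i, h_i])
            rows.append({"trial": trial, "hybrid_id": h,
                         "blue": mu_t + g[p1] + g[p2] + s[h_i] + delta[h_i]
                         + t_dev[h_i] + e,
                         "se": se[t_i, h_i]})
    return pd.DataFrame(rows)


def simulate_dataset(cfg: SimConfig) -> dict:
    """Full synthetic study: genotypes, cross plan, plots and truth."""
    founders = simulate_founders(cfg)
    parents = simulate_inbreds(founders, cfg)
    crossplan = simulate_crossplan(parents, cfg)
    plots, truth = simulate_phenotypes(parents, crossplan, cfg)
    return {"founders": founders, "parents": parents, "crossplan": crossplan,
            "plots": plots, "truth": truth, "config": cfg}
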