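"""File readers and writers: genotype CSV/VCF, cross plan, plot table.

CSV is the canonical interchange format.  Genotype matrices are written as
lines x SNPs dosage tables (header row of SNP IDs); VCF input is supported
for genotypes, with dosage taken as the ALT-allele count of the GT field.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["read_genotypes", "write_genotypes_csv", "write_genotypes_vcf",
           "read_crossplan", "write_crossplan", "read_plots", "write_plots",
           "read_blues", "write_blues", "RunConfig", "write_run_metadata"]

PLOT_COLUMNS = ("trial", "location", "year", "row", "col", "block", "hybrid_id")


def read_genotypes(path) -> pd.DataFrame:
    """Read a dosage matrix from CSV (lines x SNPs) or VCF (biallelic SNPs)."""
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        return _read_vcf(path)
    try:
        g = pd.read_csv(path, index_col=0)
    except Exception as e:
        raise ValueError(f"malformed genotype CSV {path}: {e}") from e
    bad = ~(g.isna() | g.isin([0, 1, 2]))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"genotype CSV {path}: dosage outside {{0,1,2,missing}} at "
            f"line {g.index[r]!r}, SNP {g.columns[c]!r} (file row {r + 2})")
    if g.index.has_duplicates or g.columns.has_duplicates:
        raise ValueError("duplicate line or SNP identifiers")
    return g.astype(float)


def _read_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, columns = [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic-SNP record at "
                          f"{var.CHROM}:{var.POS}")
            continue
        dosage = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            dosage[i] = float(sum(alleles)) if alleles else np.nan
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        columns.append(dosage)
    g = pd.DataFrame(np.column_stack(columns) if columns else [],
                     index=pd.Index(samples, name="line"), columns=snp_ids)
    return g


def write_genotypes_csv(g: pd.DataFrame, path) -> None:
    g.to_csv(path, index_label="line")


def write_genotypes_vcf(g: pd.DataFrame, path,
                        positions: pd.DataFrame | None = None) -> None:
    """Write dosages as a plain (uncompressed) VCF with GT fields only.

    ``positions`` optionally maps SNP ID -> (chrom, pos); otherwise SNPs are
    placed consecutively on a single synthetic chromosome.
    """
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(map(str, g.index))]
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, snp in enumerate(g.columns):
        if positions is not None and snp in positions.index:
            chrom, pos = positions.loc[snp, "chrom"], int(positions.loc[snp, "pos"])
        else:
            chrom, pos = "chr01", (j + 1) * 100
        gts = "\t".join(code.get(float(v), "./.") if pd.notna(v) else "./."
                        for v in g[snp])
        lines.append(f"{chrom}\t{pos}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_crossplan(path) -> pd.DataFrame:
    cp = pd.read_csv(path)
    needed = {"hybrid_id", "parent1", "parent2"}
    missing = needed - set(cp.columns)
    if missing:
        raise ValueError(f"cross plan lacks columns {sorted(missing)}")
    if cp["hybrid_id"].duplicated().any():
        raise ValueError("duplicate hybrid_id in cross plan")
    if (cp["parent1"] == cp["parent2"]).any():
        raise ValueError("self-crosses present in cross plan")
    return cp.set_index("hybrid_id", drop=False)


def write_crossplan(cp: pd.DataFrame, path) -> None:
    cp.reset_index(drop=True).to_csv(path, index=False)


def read_plots(path, crossplan: pd.DataFrame | None = None) -> pd.DataFrame:
    plots = pd.read_csv(path)
    missing = set(PLOT_COLUMNS) - set(plots.columns)
    if missing:
        raise ValueError(f"plot table lacks columns {sorted(missing)}")
    if crossplan is not None:
        orphans = sorted(set(plots["hybrid_id"]) - set(crossplan["hybrid_id"]))
        if orphans:
            raise ValueError(
                f"plots reference hybrids absent from the cross plan: "
                f"{orphans[:10]}")
    return plots


def write_plots(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, index=False)


def read_blues(path) -> pd.DataFrame:
    blues = pd.read_csv(path)
    missing = {"trial", "hybrid_id", "blue", "se"} - set(blues.columns)
    if missing:
        raise ValueError(f"BLUE table lacks columns {sorted(missing)}")
    return blues


def write_blues(blues: pd.DataFrame, path) -> None:
    blues.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Pipeline configuration loaded from YAML."""
    genotypes: str | None = None
    crossplan: str | None = None
    plots: str | None = None
    traits: list[str] = field(default_factory=lambda: ["TY"])
    maf_min: float = 0.05
    miss_max: float = 0.10
    rv2_max: float = 0.5
    cv_reps: int = 100
    cv_evaluated_fraction: float = 0.5
    seed: int = 0
    outdir: str = "hybridgp_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("genotypes", "crossplan", "plots"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {key}={p!r} does not exist")
        if not (0 <= cfg.maf_min <= 0.5 and 0 <= cfg.miss_max <= 1):
            raise ValueError("QC thresholds outside documented ranges")
        return cfg


def write_run_metadata(outdir, config_obj, seed: int) -> None:
    """Stamp every run with its configuration hash and seed."""
    payload = json.dumps(config_obj, default=str, sort_keys=True)
    meta = {"config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
            "seed": int(seed), "config": config_obj}
    Path(outdir).mkdir(parents=True, exist_ok=True)
    (Path(outdir) / "run_metadata.json").write_text(
        json.dumps(meta, indent=1, default=str))
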