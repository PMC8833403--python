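"""Readers and writers for the TSV/VCF interchange formats.

TSV (tab-separated, UTF-8, '.' decimal) is the canonical interchange;
VCF reading is a convenience (dosage from the DS field when present, else
the GT allele count).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simdata import GenotypePanel

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_genotype_panel",
    "write_genotype_panel",
    "read_vcf_dosages",
    "read_cohort",
    "write_cohort",
    "load_config",
    "save_config",
]

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "P"]


class ParseError(ValueError):
    """Malformed input file."""


def read_sumstats(path) -> pd.DataFrame:
    """Read and validate a GWAS summary-statistics TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    dup = df["SNP"][df["SNP"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated SNP id {dup.iloc[0]!r}")
    bad_p = ~((df["P"] > 0) & (df["P"] <= 1))
    if bad_p.any():
        line = int(df.index[bad_p][0]) + 2  # header is line 1
        raise ParseError(f"{path}: line {line}: p-value outside (0, 1]")
    if not np.isfinite(df["BETA"]).all():
        line = int(df.index[~np.isfinite(df["BETA"])][0]) + 2
        raise ParseError(f"{path}: line {line}: non-finite BETA")
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_genotype_panel(panel: GenotypePanel, prefix) -> None:
    """Write <prefix>.dosages.tsv, <prefix>.snps.tsv, <prefix>.samples.tsv."""
    prefix = str(prefix)
    dos = pd.DataFrame(panel.dosages, columns=panel.snps["snp"])
    dos.insert(0, "iid", panel.samples["iid"].to_numpy())
    dos.to_csv(prefix + ".dosages.tsv", sep="\t", index=False)
    panel.snps.to_csv(prefix + ".snps.tsv", sep="\t", index=False)
    panel.samples.to_csv(prefix + ".samples.tsv", sep="\t", index=False)


def read_genotype_panel(prefix) -> GenotypePanel:
    prefix = str(prefix)
    dos = pd.read_csv(prefix + ".dosages.tsv", sep="\t")
    snps = pd.read_csv(prefix + ".snps.tsv", sep="\t")
    samples = pd.read_csv(prefix + ".samples.tsv", sep="\t")
    iids = dos.pop("iid")
    if not (iids.to_numpy() == samples["iid"].to_numpy()).all():
        raise ParseError("sample ids in dosage and sample tables disagree")
    d = dos.to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise ParseError("dosages outside [0, 2]")
    panel = GenotypePanel(samples=samples, snps=snps, dosages=d)
    panel.validate()
    return panel


def read_vcf_dosages(path, samples: pd.DataFrame | None = None) -> GenotypePanel:
    """Read dosages from a VCF: DS format field when present, else GT count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    iids = list(vcf.samples)
    rows = []
    dosages = []
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            d = np.where((gt < 0).any(axis=1), np.nan, np.clip(gt, 0, None).sum(axis=1)).astype(float)
        if np.nanmax(d) > 2 or np.nanmin(d) < 0:
            raise ParseError(f"{path}: dosage out of range at {var.ID or var.POS}")
        rows.append(
            {
                "snp": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": int(str(var.CHROM).removeprefix("chr")),
                "pos": var.POS,
                "a1": var.ALT[0] if var.ALT else ".",
                "a2": var.REF,
                "freq": float(np.nanmean(d)) / 2.0,
                "info": 1.0,
                "block": -1,
            }
        )
        dosages.append(d)
    snps = pd.DataFrame(rows)
    dos = np.array(dosages).T if dosages else np.zeros((len(iids), 0))
    if samples is None:
        samples = pd.DataFrame(
            {"iid": iids, "pair": range(len(iids)), "order": 1, "zygosity": "DZ", "array": "Psych"}
        )
    else:
        unknown = set(iids) - set(samples["iid"])
        if unknown:
            raise ParseError(f"VCF samples missing from sample table: {sorted(unknown)[:5]}")
        samples = samples.set_index("iid").loc[iids].reset_index()
    return GenotypePanel(samples=samples, snps=snps, dosages=dos)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"iid", "pair", "order", "zygosity", "ad"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing cohort columns {sorted(missing)}")
    if set(df["ad"].unique()) - {0, 1}:
        raise ParseError(f"{path}: AD status must be binary 0/1")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2))
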