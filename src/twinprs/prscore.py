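"""Clumping-and-thresholding polygenic score construction.

QC filtering and allele harmonization, greedy LD clumping on dosage r²,
per-threshold allele-weighted scoring, APOE-region exclusion, ancestry PCA,
PC residualization with within-array standardization, and epsilon-allele
derivation from the two APOE markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import APOE_REGION, GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "PRSConfig",
    "qc_filter",
    "ld_clump",
    "compute_prs",
    "exclude_apoe_region",
    "pca_ancestry",
    "residualize_standardize",
    "apoe_alleles",
    "build_prs_panel",
]

DEFAULT_THRESHOLDS = (1.0, 0.5, 0.05, 0.01, 1e-3, 1e-4, 1e-5, 5e-8)

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class PRSConfig:
    p_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    clump_r2: float = 0.01
    clump_window_bp: int = 250_000
    maf_floor: float = 0.01
    info_floor: float = 0.8
    apoe_region: tuple[int, int, int] = APOE_REGION  # chrom, start, end (1-based closed)
    n_pcs: int = 4

    def validate(self) -> None:
        if not all(0.0 < t <= 1.0 for t in self.p_thresholds):
            raise ValueError("p thresholds must lie in (0, 1]")
        if not (0.0 < self.clump_r2 <= 1.0):
            raise ValueError("clump r2 must lie in (0, 1]")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValueError("MAF floor must lie in (0, 0.5)")


def qc_filter(
    sumstats: pd.DataFrame, panel: GenotypePanel, config: PRSConfig | None = None
) -> pd.DataFrame:
    """Drop strand-ambiguous / absent / rare / poorly imputed SNPs and
    harmonize effect alleles against the panel.

    The effect (``BETA``) sign is flipped when the summary-statistics effect
    allele matches the panel's other allele; irreconcilable allele pairs are
    dropped with a logged count.
    """
    config = config or PRSConfig()
    config.validate()
    ss = sumstats.copy()

    ambiguous = ss.apply(lambda r: (r["A1"], r["A2"]) in _AMBIGUOUS, axis=1)
    ss = ss[~ambiguous.to_numpy()]

    panel_meta = panel.snps.set_index("snp")
    present = ss["SNP"].isin(panel_meta.index)
    ss = ss[present.to_numpy()]

    freq = panel.effect_allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    maf_by_snp = pd.Series(maf, index=panel.snps["snp"])
    ss = ss[maf_by_snp.reindex(ss["SNP"]).to_numpy() >= config.maf_floor]

    if "info" in panel_meta.columns:
        info = panel_meta["info"].reindex(ss["SNP"]).to_numpy()
        ss = ss[info > config.info_floor]
    elif "INFO" in ss.columns:
        ss = ss[ss["INFO"].to_numpy() > config.info_floor]

    pa1 = panel_meta["a1"].reindex(ss["SNP"]).to_numpy()
    pa2 = panel_meta["a2"].reindex(ss["SNP"]).to_numpy()
    same = (ss["A1"].to_numpy() == pa1) & (ss["A2"].to_numpy() == pa2)
    flipped = (ss["A1"].to_numpy() == pa2) & (ss["A2"].to_numpy() == pa1)
    n_dropped = int((~(same | flipped)).sum())
    if n_dropped:
        logger.info("qc_filter: dropped %d SNPs with irreconcilable alleles", n_dropped)
    ss = ss[same | flipped]
    flip = flipped[same | flipped]
    ss = ss.copy()
    ss.loc[flip, "BETA"] = -ss.loc[flip, "BETA"].to_numpy()
    ss.loc[flip, ["A1", "A2"]] = ss.loc[flip, ["A2", "A1"]].to_numpy()
    return ss.reset_index(drop=True)


def _standardized_dosages(panel: GenotypePanel, ids) -> np.ndarray:
    idx = panel.snp_index(ids)
    d = panel.dosages[:, idx].astype(float)
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    return d / sd


def ld_clump(
    sumstats: pd.DataFrame, panel: GenotypePanel, config: PRSConfig | None = None
) -> list[str]:
    """Greedy p-value-ordered clumping on allelic (dosage) r².

    A SNP is accepted iff its squared dosage correlation with every
    previously accepted SNP on the same chromosome within the window is
    below ``clump_r2``.  Ties break deterministically on (p, chrom, pos).
    """
    config = config or PRSConfig()
    config.validate()
    ss = sumstats.sort_values(["P", "CHR", "BP"], kind="mergesort").reset_index(drop=True)
    z = _standardized_dosages(panel, ss["SNP"])
    n = z.shape[0]
    kept: list[int] = []
    kept_by_chrom: dict[int, list[int]] = {}
    chroms = ss["CHR"].to_numpy()
    pos = ss["BP"].to_numpy()
    for i in range(len(ss)):
        ok = True
        for j in kept_by_chrom.get(chroms[i], []):
            if abs(pos[i] - pos[j]) > config.clump_window_bp:
                continue
            r = float(z[:, i] @ z[:, j]) / n
            if r * r >= config.clump_r2:
                ok = False
                break
        if ok:
            kept.append(i)
            kept_by_chrom.setdefault(chroms[i], []).append(i)
    return ss["SNP"].iloc[kept].tolist()


def compute_prs(
    panel: GenotypePanel,
    sumstats: pd.DataFrame,
    threshold: float,
    index_snps: list[str],
) -> np.ndarray:
    """Raw allele-weighted score over index SNPs passing the p threshold.

    Missing dosages are mean-imputed per SNP (counts logged).
    """
    ss = sumstats.set_index("SNP")
    use = [s for s in index_snps if s in ss.index and ss.loc[s, "P"] <= threshold]
    if not use:
        return np.zeros(panel.n_samples)
    idx = panel.snp_index(use)
    d = panel.dosages[:, idx].astype(float)
    n_missing = int(np.isnan(d).sum())
    if n_missing:
        logger.info("compute_prs: mean-imputed %d missing dosages", n_missing)
        col_mean = np.nanmean(d, axis=0)
        inds = np.where(np.isnan(d))
        d[inds] = np.take(col_mean, inds[1])
    betas = ss.loc[use, "BETA"].to_numpy(float)
    return d @ betas


def exclude_apoe_region(
    sumstats: pd.DataFrame, config: PRSConfig | None = None
) -> pd.DataFrame:
    """Remove SNPs inside the (closed, 1-based) APOE region interval."""
    config = config or PRSConfig()
    chrom, start, end = config.apoe_region
    in_region = (
        (sumstats["CHR"] == chrom) & (sumstats["BP"] >= start) & (sumstats["BP"] <= end)
    )
    return sumstats[~in_region.to_numpy()].reset_index(drop=True)


def pca_ancestry(panel: GenotypePanel, k: int) -> np.ndarray:
    """Top-k ancestry principal component coordinates for every individual.

    The decomposition is fitted excluding one member of each MZ pair
    (duplicate genomes would bias the axes); coordinates are projected for
    everyone from the same loadings.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    samples = panel.samples
    is_dup_mz = (samples["zygosity"] == "MZ") & (samples["order"] == 2)
    fit_rows = ~is_dup_mz.to_numpy()

    d = panel.dosages.astype(float)
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    mean = d[fit_rows].mean(axis=0)
    sd = d[fit_rows].std(axis=0)
    if np.all(sd == 0):
        raise ValueError("panel has no variable SNPs; PCs undefined")
    sd[sd == 0] = 1.0
    x_fit = (d[fit_rows] - mean) / sd
    u, s, vt = np.linalg.svd(x_fit, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the standardized panel")
    x_all = (d - mean) / sd
    return x_all @ vt[:k].T


def residualize_standardize(
    raw_scores: np.ndarray, pcs: np.ndarray | None, array_labels
) -> np.ndarray:
    """OLS-residualize scores on the PCs, then z-score within each array."""
    y = np.asarray(raw_scores, float)
    if pcs is not None and pcs.size:
        x = np.column_stack([np.ones(len(y)), pcs])
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
    else:
        resid = y - y.mean()
    labels = np.asarray(array_labels)
    out = np.empty_like(resid)
    for lab in np.unique(labels):
        mask = labels == lab
        if mask.sum() < 2:
            raise ValueError(f"array group {lab!r} has fewer than 2 members")
        grp = resid[mask]
        sd = grp.std(ddof=0)
        if sd == 0:
            raise ValueError(f"array group {lab!r} has zero score variance")
        out[mask] = (grp - grp.mean()) / sd
    return out


def apoe_alleles(rs429358_c_dosage, rs7412_t_dosage) -> tuple[np.ndarray, np.ndarray]:
    """(epsilon2 count, epsilon4 count) from the two-marker genotype.

    Haplotypes: e2 = (rs429358-T, rs7412-T), e3 = (T, C), e4 = (C, C); with
    e1/e3r absent, the e4 count equals the rs429358 C dosage and the e2
    count equals the rs7412 T dosage.  The double heterozygote (1, 1)
    therefore resolves to e2/e4.  Combinations needing more than two
    haplotypes raise.
    """
    c_dos = np.atleast_1d(np.asarray(rs429358_c_dosage))
    t_dos = np.atleast_1d(np.asarray(rs7412_t_dosage))
    as_int = np.rint(c_dos).astype(int), np.rint(t_dos).astype(int)
    if not (np.allclose(c_dos, as_int[0]) and np.allclose(t_dos, as_int[1])):
        raise ValueError("APOE dosages must be integer 0-2")
    e4, e2 = as_int
    if ((e4 < 0) | (e4 > 2) | (e2 < 0) | (e2 > 2)).any():
        raise ValueError("APOE dosages must lie in 0-2")
    if ((e2 + e4) > 2).any():
        raise ValueError("impossible APOE genotype: e2 + e4 counts exceed 2 haplotypes")
    if np.isscalar(rs429358_c_dosage) and np.isscalar(rs7412_t_dosage):
        return int(e2[0]), int(e4[0])
    return e2, e4


@dataclass
class PRSPanel:
    """Per-individual scores per (threshold, variant set)."""

    scores: pd.DataFrame  # iid-indexed; columns prs_<set>_<thr> (standardized)
    n_snps: dict[str, int] = field(default_factory=dict)
    index_snps: dict[str, list[str]] = field(default_factory=dict)


def _thr_tag(thr: float) -> str:
    return f"{thr:g}"


def build_prs_panel(
    panel: GenotypePanel,
    sumstats: pd.DataFrame,
    config: PRSConfig | None = None,
    variant_sets: tuple[str, ...] = ("full", "noapoe"),
) -> PRSPanel:
    """End-to-end C+T scoring: QC → clump → score per threshold and variant
    set → PC-residualize → standardize within array.

    MZ co-twins with missing genotypes receive the genotyped twin's score
    (copy imputation) before standardization.
    """
    config = config or PRSConfig()
    config.validate()
    ss = qc_filter(sumstats, panel, config)
    samples = panel.samples
    arrays = samples["array"].to_numpy()

    genotyped = ~np.all(np.isnan(panel.dosages), axis=1) if panel.n_samples else np.array([], bool)
    pcs = pca_ancestry(panel, config.n_pcs) if panel.n_samples else None

    out = pd.DataFrame({"iid": samples["iid"]})
    n_snps: dict[str, int] = {}
    index_sets: dict[str, list[str]] = {}
    for vset in variant_sets:
        ss_v = exclude_apoe_region(ss, config) if vset == "noapoe" else ss
        index = ld_clump(ss_v, panel, config)
        index_sets[vset] = index
        p_of = ss_v.set_index("SNP")["P"]
        for thr in config.p_thresholds:
            key = f"prs_{vset}_{_thr_tag(thr)}"
            use = [s for s in index if p_of[s] <= thr]
            raw = compute_prs(panel, ss_v, thr, use)
            raw = _copy_impute_mz(raw, samples, genotyped)
            out[key] = residualize_standardize(raw, pcs, arrays)
            n_snps[key] = len(use)
    return PRSPanel(scores=out.set_index("iid"), n_snps=n_snps, index_snps=index_sets)


def _copy_impute_mz(raw: np.ndarray, samples: pd.DataFrame, genotyped: np.ndarray) -> np.ndarray:
    out = raw.copy()
    if genotyped.all():
        return out
    for pair, grp in samples.groupby("pair"):
        idx = grp.index.to_numpy()
        if len(idx) != 2 or (grp["zygosity"] != "MZ").any():
            continue
        g = genotyped[idx]
        if g[0] and not g[1]:
            out[idx[1]] = out[idx[0]]
        elif g[1] and not g[0]:
            out[idx[0]] = out[idx[1]]
    return out
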