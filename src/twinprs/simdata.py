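"""Synthetic twin-cohort generation.

Produces block-LD haplotype pools, MZ/DZ genotype panels with mendelian
transmission, APOE-like two-marker haplotypes, noisy GWAS summary statistics
and binary liability-threshold phenotypes whose variance decomposition
(polygenic, background genetic, shared and unique environment, with an
optional A–C covariance) is known by construction.

All randomness flows through :class:`numpy.random.Generator` instances
spawned deterministically from a single seed, so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

__all__ = [
    "HaplotypePool",
    "GenotypePanel",
    "CohortSimConfig",
    "simulate_haplotype_pool",
    "draw_haplotypes",
    "simulate_twin_genotypes",
    "simulate_apoe",
    "simulate_gwas_sumstats",
    "simulate_liability_cohort",
    "apply_missingness",
]

ARRAY_LABELS = ("Omni", "Psych")  # coded 0 / 1 downstream
APOE_REGION = (19, 44_400_000, 46_500_000)
RS429358_POS = 45_411_941
RS7412_POS = 45_412_079

_BASES = np.array(list("ACGT"))


class ParameterError(ValueError):
    """Invalid simulation parameter."""


class ConstraintError(ValueError):
    """Variance-share constraint violated."""


# ---------------------------------------------------------------------------
# haplotype pool


@dataclass
class HaplotypePool:
    """Block-structured SNP panel with latent-Gaussian AR(1) LD.

    ``snps`` columns: snp, chrom, pos, a1 (effect), a2, freq, info, block.
    """

    snps: pd.DataFrame
    rho: float
    block_sizes: list[int] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def validate(self) -> None:
        s = self.snps
        if not ((s["freq"] > 0) & (s["freq"] <= 0.5)).all():
            raise ParameterError("allele frequencies must lie in (0, 0.5]")
        for _, grp in s.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ParameterError("positions must be strictly increasing per chromosome")


def simulate_haplotype_pool(
    n_blocks: int,
    block_size: int,
    freq_range: tuple[float, float] = (0.05, 0.5),
    rho: float = 0.0,
    seed: int = 0,
    info_range: tuple[float, float] = (0.81, 1.0),
    chrom: int = 1,
    spacing: int = 5_000,
    apoe_region_blocks: int = 0,
) -> HaplotypePool:
    """Create SNP metadata for ``n_blocks`` independent LD blocks.

    Haplotypes are drawn later by thresholding a latent Gaussian AR(1)
    process with parameter ``rho`` inside each block; blocks (and hence
    chromosome arms) are independent by construction.  The last
    ``apoe_region_blocks`` blocks are placed inside the default APOE region
    on chromosome 19 so region-exclusion logic can be exercised without real
    coordinates.
    """
    if n_blocks < 1 or block_size < 1:
        raise ParameterError("n_blocks and block_size must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise ParameterError("rho must lie in [0, 1)")
    lo, hi = freq_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError("freq_range must lie within (0, 0.5]")
    if apoe_region_blocks > n_blocks:
        raise ParameterError("apoe_region_blocks exceeds n_blocks")

    rng = np.random.default_rng(seed)
    m = n_blocks * block_size
    freq = rng.uniform(lo, hi, size=m)
    info = rng.uniform(info_range[0], info_range[1], size=m)
    block = np.repeat(np.arange(n_blocks), block_size)

    chroms = np.full(m, chrom, int)
    pos = np.zeros(m, int)
    main_blocks = n_blocks - apoe_region_blocks
    in_main = block < main_blocks
    pos[in_main] = 1_000_000 + np.arange(in_main.sum()) * spacing
    if apoe_region_blocks:
        n_ap = (~in_main).sum()
        chroms[~in_main] = APOE_REGION[0]
        ap_spacing = min(spacing, (APOE_REGION[2] - APOE_REGION[1] - 2) // max(n_ap, 1))
        pos[~in_main] = APOE_REGION[1] + 1 + np.arange(n_ap) * max(ap_spacing, 1)

    a_idx = rng.integers(0, 4, size=m)
    # pick a non-ambiguous partner base (not self, not the complement)
    comp = np.array([3, 2, 1, 0])  # A<->T, C<->G
    b_idx = np.array(
        [rng.choice([j for j in range(4) if j != i and j != comp[i]]) for i in a_idx]
    )
    snps = pd.DataFrame(
        {
            "snp": [f"snp{i}" for i in range(m)],
            "chrom": chroms,
            "pos": pos,
            "a1": _BASES[a_idx],
            "a2": _BASES[b_idx],
            "freq": freq,
            "info": info,
            "block": block,
        }
    )
    pool = HaplotypePool(snps=snps, rho=rho, block_sizes=[block_size] * n_blocks)
    pool.validate()
    return pool


def draw_haplotypes(pool: HaplotypePool, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` haplotypes (0/1 effect-allele indicators) from the pool."""
    m = pool.n_snps
    z = np.empty((n, m))
    rho = pool.rho
    start = 0
    for size in pool.block_sizes:
        eps = rng.standard_normal((n, size))
        blk = np.empty((n, size))
        blk[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, size):
            blk[:, j] = rho * blk[:, j - 1] + scale * eps[:, j]
        z[:, start : start + size] = blk
        start += size
    thresh = ndtri(pool.snps["freq"].to_numpy())
    return (z < thresh[None, :]).astype(np.int8)


# ---------------------------------------------------------------------------
# genotype panel


@dataclass
class GenotypePanel:
    """Dosage matrix plus sample and SNP metadata.

    ``samples`` columns: iid, pair, order, zygosity, array.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    dosages: np.ndarray  # individuals x SNPs, float, NaN = missing

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def snp_index(self, ids) -> np.ndarray:
        lookup = pd.Index(self.snps["snp"])
        idx = lookup.get_indexer(ids)
        if (idx < 0).any():
            missing = np.asarray(ids)[idx < 0]
            raise KeyError(f"SNPs absent from panel: {missing[:5].tolist()}")
        return idx

    def effect_allele_freq(self) -> np.ndarray:
        return np.nanmean(self.dosages, axis=0) / 2.0

    def validate(self) -> None:
        d = self.dosages
        with np.errstate(invalid="ignore"):
            if np.nanmin(d) < 0 or np.nanmax(d) > 2:
                raise ParameterError("dosages must lie in [0, 2]")
        counts = self.samples.groupby("pair")["zygosity"].agg(["size", "nunique"])
        if (counts["size"] > 2).any() or (counts["nunique"] > 1).any():
            raise ParameterError("pairs must have <= 2 members with one zygosity")


def _pair_layout(n_mz: int, n_dz: int) -> pd.DataFrame:
    pair = np.repeat(np.arange(n_mz + n_dz), 2)
    order = np.tile([1, 2], n_mz + n_dz)
    zyg = np.repeat(["MZ"] * n_mz + ["DZ"] * n_dz, 2)
    return pd.DataFrame(
        {
            "iid": [f"p{p}_t{o}" for p, o in zip(pair, order)],
            "pair": pair,
            "order": order,
            "zygosity": zyg,
        }
    )


def _transmit(parent_h: np.ndarray, choices: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """Build gametes: pick one parental haplotype per LD block (no within-
    block recombination, free recombination between blocks)."""
    # parent_h: (n, 2, m); choices: (n, n_blocks) in {0,1}
    sel = choices[:, blocks]  # (n, m)
    return np.take_along_axis(parent_h, sel[:, None, :], axis=1)[:, 0, :]


def simulate_twin_genotypes(
    pool: HaplotypePool,
    n_mz: int,
    n_dz: int,
    seed: int = 0,
    array_props: tuple[float, float] = (0.085, 0.915),
) -> GenotypePanel:
    """Mendelian twin genotypes: MZ pairs share a zygote, DZ pairs share
    parents and draw independent gametes (expected dosage correlation 0.5)."""
    if n_mz < 0 or n_dz < 0:
        raise ParameterError("pair counts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    n_pairs = n_mz + n_dz
    samples = _pair_layout(n_mz, n_dz)
    m = pool.n_snps
    if n_pairs == 0:
        panel = GenotypePanel(samples=samples, snps=pool.snps.copy(), dosages=np.zeros((0, m)))
        return panel

    blocks = pool.snps["block"].to_numpy()
    n_blocks = blocks.max() + 1
    mother = draw_haplotypes(pool, 2 * n_pairs, rng).reshape(n_pairs, 2, m)
    father = draw_haplotypes(pool, 2 * n_pairs, rng).reshape(n_pairs, 2, m)

    choice = rng.integers(0, 2, size=(n_pairs, 2, 2, n_blocks))  # pair, twin, parent, block
    is_mz = samples["zygosity"].to_numpy()[::2] == "MZ"
    choice[is_mz, 1] = choice[is_mz, 0]  # MZ twins share the zygote

    dos = np.empty((2 * n_pairs, m), float)
    for t in range(2):
        g_m = _transmit(mother, choice[:, t, 0, :], blocks)
        g_f = _transmit(father, choice[:, t, 1, :], blocks)
        dos[t::2] = g_m + g_f

    arrays = rng.choice(ARRAY_LABELS, size=n_pairs, p=list(array_props))
    samples["array"] = np.repeat(arrays, 2)
    panel = GenotypePanel(samples=samples, snps=pool.snps.copy(), dosages=dos)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# APOE


def _draw_apoe_counts(
    n_pairs: int, is_mz: np.ndarray, hap_freqs, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-twin (e2, e4) allele counts respecting parental transmission.

    Returns two (n_pairs, 2) arrays.
    """
    f = np.asarray(hap_freqs, float)
    if f.shape != (3,) or abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
        raise ParameterError("hap_freqs must be (f_e2, f_e3, f_e4) summing to 1")
    # haplotype codes 0=e2, 1=e3, 2=e4
    parents = rng.choice(3, size=(n_pairs, 2, 2), p=f)  # pair, parent, haplotype
    pick = rng.integers(0, 2, size=(n_pairs, 2, 2))  # pair, twin, parent
    pick[is_mz, 1] = pick[is_mz, 0]
    alleles = np.empty((n_pairs, 2, 2), int)  # pair, twin, transmitted allele
    for t in range(2):
        for p in range(2):
            alleles[:, t, p] = parents[np.arange(n_pairs), p, pick[:, t, p]]
    e2 = (alleles == 0).sum(axis=2)
    e4 = (alleles == 2).sum(axis=2)
    return e2, e4


def simulate_apoe(
    panel: GenotypePanel,
    hap_freqs=(0.094, 0.742, 0.164),
    seed: int = 0,
) -> GenotypePanel:
    """Append rs429358 / rs7412 dosages from epsilon haplotypes.

    Haplotype definitions: e2 = (rs429358-T, rs7412-T), e3 = (T, C),
    e4 = (C, C); the rs429358 C dosage equals the e4 count and the rs7412
    T dosage equals the e2 count.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    pairs = panel.samples["pair"].to_numpy()
    uniq, inv = np.unique(pairs, return_inverse=True)
    n_pairs = len(uniq)
    zyg = np.empty(n_pairs, dtype=object)
    zyg[inv] = panel.samples["zygosity"].to_numpy()
    is_mz = zyg == "MZ"

    e2, e4 = _draw_apoe_counts(n_pairs, is_mz, hap_freqs, rng)
    order = panel.samples["order"].to_numpy() - 1
    e2_ind = e2[inv, order].astype(float)
    e4_ind = e4[inv, order].astype(float)

    new_snps = pd.DataFrame(
        {
            "snp": ["rs429358", "rs7412"],
            "chrom": [APOE_REGION[0]] * 2,
            "pos": [RS429358_POS, RS7412_POS],
            "a1": ["C", "T"],
            "a2": ["T", "C"],
            "freq": [float(hap_freqs[2]), float(hap_freqs[0])],
            "info": [1.0, 1.0],
            "block": [-1, -1],
        }
    )
    snps = pd.concat([panel.snps, new_snps], ignore_index=True)
    dosages = np.column_stack([panel.dosages, e4_ind, e2_ind])
    return GenotypePanel(samples=panel.samples.copy(), snps=snps, dosages=dosages)


# ---------------------------------------------------------------------------
# summary statistics


def simulate_gwas_sumstats(
    pool: HaplotypePool,
    true_betas,
    n_gwas: int,
    seed: int = 0,
    se_floor: float = 0.0,
) -> pd.DataFrame:
    """Noisy per-SNP effect estimates: beta_hat ~ N(beta, se) with
    se = 1/sqrt(2 n f (1-f)), two-sided Wald p-values."""
    beta = np.asarray(true_betas, float)
    if beta.shape != (pool.n_snps,):
        raise ParameterError("need one true beta per SNP")
    if n_gwas < 10:
        raise ParameterError("n_gwas must be >= 10")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    f = pool.snps["freq"].to_numpy()
    se = np.maximum(1.0 / np.sqrt(2.0 * n_gwas * f * (1.0 - f)), se_floor)
    beta_hat = beta + se * rng.standard_normal(pool.n_snps)
    z = beta_hat / se
    p = np.clip(2.0 * ndtr(-np.abs(z)), np.nextafter(0, 1), 1.0)
    out = pool.snps[["snp", "chrom", "pos", "a1", "a2", "info"]].copy()
    out.columns = ["SNP", "CHR", "BP", "A1", "A2", "INFO"]
    out["BETA"] = beta_hat
    out["P"] = p
    out["SE"] = se
    return out[["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "INFO"]]


# ---------------------------------------------------------------------------
# liability cohort


@dataclass
class CohortSimConfig:
    """Generating configuration for a liability-threshold twin cohort.

    Variance shares are liability-scale fractions and must satisfy
    ``sigma2_ap + sigma2_ab + sigma2_ae4 + sigma2_c + 2*cov_ac + sigma2_e == 1``.
    """

    n_mz: int
    n_dz: int
    sigma2_ap: float = 0.0
    sigma2_ab: float = 0.0
    sigma2_c: float = 0.0
    cov_ac: float = 0.0
    sigma2_e: float = 1.0
    sigma2_ae4: float = 0.0
    prevalence: float = 0.272
    beta_sex: float = 0.44
    beta_age: float = 0.97
    beta_age2: float = -0.55
    p_female: float = 0.56
    age_mean: float = 85.28
    age_sd: float = 7.02
    incomplete_rate: float = 0.0
    mz_single_genotyped_rate: float = 0.0
    seed: int = 0
    mode: str = "direct"  # 'direct' or 'genotype'
    covac_split: float | None = None  # fraction of cov_ac loaded on A_P
    e4_hap_freqs: tuple[float, float, float] = (0.094, 0.742, 0.164)
    array_props: tuple[float, float] = (0.085, 0.915)
    debug_components: bool = False

    def validate(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ParameterError("pair counts must be >= 0")
        total = (
            self.sigma2_ap
            + self.sigma2_ab
            + self.sigma2_ae4
            + self.sigma2_c
            + 2.0 * self.cov_ac
            + self.sigma2_e
        )
        if abs(total - 1.0) > 1e-9:
            raise ConstraintError(f"variance shares sum to {total!r}, not 1")
        for rate in (self.incomplete_rate, self.mz_single_genotyped_rate):
            if not (0.0 <= rate <= 1.0):
                raise ParameterError("missingness rates must lie in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ParameterError("prevalence must lie in (0, 1)")
        if self.cov_ac != 0.0 and self.covac_split is None:
            raise ParameterError("cov_ac != 0 requires an explicit covac_split")
        if self.mode not in ("direct", "genotype"):
            raise ParameterError("mode must be 'direct' or 'genotype'")


def _latent_pair_draws(
    n_pairs: int,
    is_mz: np.ndarray,
    r_pc: float,
    r_bc: float,
    rng: np.random.Generator,
    z_p_obs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (Z_P, Z_B, Z_C) with twin correlation r_g on P and B and
    corr(Z_C, Z_P) = r_pc, corr(Z_C, Z_B) = r_bc for both twins.

    Returns (n_pairs, 2) arrays for Z_P and Z_B and (n_pairs,) for Z_C.
    When ``z_p_obs`` is given (genotype mode), Z_P is taken as observed and
    r_pc must be 0.
    """
    z_b = np.empty((n_pairs, 2))
    z_p = np.empty((n_pairs, 2))
    z_c = np.empty(n_pairs)

    for mz, mask in ((True, is_mz), (False, ~is_mz)):
        n = int(mask.sum())
        if n == 0:
            continue
        r_g = 1.0 if mz else 0.5
        if z_p_obs is None:
            order = ["p1", "p2", "b1", "b2", "c"]
            corr = np.eye(5)
            corr[0, 1] = corr[1, 0] = r_g
            corr[2, 3] = corr[3, 2] = r_g
            corr[0, 4] = corr[4, 0] = r_pc
            corr[1, 4] = corr[4, 1] = r_pc
            corr[2, 4] = corr[4, 2] = r_bc
            corr[3, 4] = corr[4, 3] = r_bc
            try:
                chol = np.linalg.cholesky(corr + 1e-12 * np.eye(5))
            except np.linalg.LinAlgError as exc:
                raise ConstraintError("A-C covariance split is not PSD") from exc
            draw = rng.standard_normal((n, 5)) @ chol.T
            if mz:  # enforce exact sharing despite the jittered Cholesky
                draw[:, 1] = draw[:, 0]
                draw[:, 3] = draw[:, 2]
            z_p[mask] = draw[:, :2]
            z_b[mask] = draw[:, 2:4]
            z_c[mask] = draw[:, 4]
        else:
            corr = np.eye(3)
            corr[0, 1] = corr[1, 0] = r_g
            corr[0, 2] = corr[2, 0] = r_bc
            corr[1, 2] = corr[2, 1] = r_bc
            try:
                chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
            except np.linalg.LinAlgError as exc:
                raise ConstraintError("A-C covariance split is not PSD") from exc
            draw = rng.standard_normal((n, 3)) @ chol.T
            if mz:
                draw[:, 1] = draw[:, 0]
            z_b[mask] = draw[:, :2]
            z_c[mask] = draw[:, 2]
            z_p[mask] = z_p_obs[mask]
    return z_p, z_b, z_c


def simulate_liability_cohort(
    config: CohortSimConfig,
    panel: GenotypePanel | None = None,
    prs_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate a twin cohort with a binary liability-threshold phenotype.

    In ``direct`` mode the standardized PRS is the latent polygenic factor
    itself; in ``genotype`` mode it is the standardized true-weight score
    computed from ``panel`` dosages.  The liability threshold is solved by
    root-finding on the covariate-marginal normal CDF so the expected case
    fraction equals ``config.prevalence``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 4]))
    n_pairs = config.n_mz + config.n_dz

    if config.mode == "genotype":
        if panel is None or prs_weights is None:
            raise ParameterError("genotype mode requires a panel and true weights")
        if len(panel.samples) != 2 * n_pairs:
            raise ParameterError("panel size does not match pair counts")
        samples = panel.samples
    else:
        samples = _pair_layout(config.n_mz, config.n_dz)
        arrays = rng.choice(ARRAY_LABELS, size=n_pairs, p=list(config.array_props))
        samples = samples.assign(array=np.repeat(arrays, 2))

    is_mz_pair = samples["zygosity"].to_numpy()[::2] == "MZ"

    a_p = np.sqrt(max(config.sigma2_ap, 0.0))
    a_b = np.sqrt(max(config.sigma2_ab, 0.0))
    a_e4 = np.sqrt(max(config.sigma2_ae4, 0.0))
    c = np.sqrt(max(config.sigma2_c, 0.0))
    e = np.sqrt(max(config.sigma2_e, 0.0))

    r_pc = r_bc = 0.0
    if config.cov_ac != 0.0:
        s = config.covac_split
        if config.mode == "genotype" and s not in (0.0,):
            raise ParameterError("genotype mode supports cov_ac on A_B only (covac_split=0)")
        if c == 0.0:
            raise ParameterError("cov_ac != 0 requires sigma2_c > 0")
        sig_apc = s * config.cov_ac
        sig_abc = (1.0 - s) * config.cov_ac
        if sig_apc != 0.0 and a_p == 0.0:
            raise ParameterError("cov_ac split on A_P requires sigma2_ap > 0")
        if sig_abc != 0.0 and a_b == 0.0:
            raise ParameterError("cov_ac split on A_B requires sigma2_ab > 0")
        r_pc = sig_apc / (a_p * c) if sig_apc != 0.0 else 0.0
        r_bc = sig_abc / (a_b * c) if sig_abc != 0.0 else 0.0

    z_p_obs = None
    if config.mode == "genotype":
        idx = panel.snp_index(prs_weights_index(prs_weights, panel))
        w = np.asarray(prs_weights_values(prs_weights), float)
        score = np.nan_to_num(panel.dosages[:, idx]) @ w
        score = (score - score.mean()) / score.std(ddof=0)
        z_p_obs = score.reshape(n_pairs, 2)

    z_p, z_b, z_c = _latent_pair_draws(n_pairs, is_mz_pair, r_pc, r_bc, rng, z_p_obs)
    z_e = rng.standard_normal((n_pairs, 2))

    z_e4 = np.zeros((n_pairs, 2))
    e2_cnt = np.zeros((n_pairs, 2), int)
    e4_cnt = np.zeros((n_pairs, 2), int)
    if config.sigma2_ae4 > 0.0 or config.mode == "genotype":
        e2_cnt, e4_cnt = _draw_apoe_counts(n_pairs, is_mz_pair, config.e4_hap_freqs, rng)
        q4 = float(config.e4_hap_freqs[2])
        z_e4 = (e4_cnt - 2.0 * q4) / np.sqrt(2.0 * q4 * (1.0 - q4))

    comp = a_p * z_p + a_b * z_b + a_e4 * z_e4 + c * z_c[:, None] + e * z_e

    n = 2 * n_pairs
    sex = rng.binomial(1, config.p_female, size=n).astype(float)
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    age_c = (age - 80.0) / 10.0
    mean = config.beta_sex * sex + config.beta_age * age_c + config.beta_age2 * age_c**2

    def excess(t: float) -> float:
        return float(np.mean(ndtr(mean - t))) - config.prevalence

    threshold = brentq(excess, -20.0, 20.0, xtol=1e-12)
    liability = comp.reshape(-1) + mean
    ad = (liability > threshold).astype(int)

    cohort = samples.copy().reset_index(drop=True)
    cohort["sex"] = sex
    cohort["last_age"] = age
    cohort["age_c"] = age_c
    cohort["age_c2"] = age_c**2
    cohort["ad"] = ad
    cohort["mz"] = (cohort["zygosity"] == "MZ").astype(int)
    cohort["array_code"] = (cohort["array"] == "Psych").astype(int)
    cohort["complete_pair"] = True
    cohort["prs_imputed"] = False
    cohort["zprs"] = z_p.reshape(-1)
    cohort["apoe_e2"] = e2_cnt.reshape(-1)
    cohort["apoe_e4"] = e4_cnt.reshape(-1)
    cohort.attrs["threshold"] = threshold
    if config.debug_components:
        cohort["true_a_p"] = (a_p * z_p).reshape(-1)
        cohort["true_a_b"] = (a_b * z_b).reshape(-1)
        cohort["true_c"] = np.repeat(c * z_c, 2)
        cohort["true_e"] = (e * z_e).reshape(-1)
        cohort["true_liability"] = liability
    return cohort


def prs_weights_index(prs_weights, panel: GenotypePanel):
    """Accept either a pandas Series indexed by SNP id or a raw vector."""
    if isinstance(prs_weights, pd.Series):
        return prs_weights.index.to_numpy()
    return panel.snps["snp"].to_numpy()[: len(np.asarray(prs_weights))]


def prs_weights_values(prs_weights):
    if isinstance(prs_weights, pd.Series):
        return prs_weights.to_numpy()
    return np.asarray(prs_weights, float)


# ---------------------------------------------------------------------------
# missingness


def apply_missingness(
    cohort: pd.DataFrame,
    panel: GenotypePanel | None,
    config: CohortSimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GenotypePanel | None]:
    """Mark pairs incomplete and copy-impute MZ co-twin scores.

    A random ``incomplete_rate`` fraction of pairs loses one member from the
    phenotype analysis set (row dropped, remaining twin flagged incomplete).
    A random ``mz_single_genotyped_rate`` fraction of the remaining complete
    MZ pairs loses one twin's genotypes; that twin's PRS is flagged as
    copied from the genotyped co-twin.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed if seed is None else seed), 5])
    )
    out = cohort.copy().reset_index(drop=True)
    panel_out = panel

    pairs = out["pair"].unique()
    n_inc = int(round(config.incomplete_rate * len(pairs)))
    if n_inc > 0:
        inc_pairs = rng.choice(pairs, size=n_inc, replace=False)
        drop_order = rng.integers(1, 3, size=n_inc)
        drop_mask = np.zeros(len(out), bool)
        for p, o in zip(inc_pairs, drop_order):
            drop_mask |= (out["pair"] == p).to_numpy() & (out["order"] == o).to_numpy()
        out.loc[out["pair"].isin(inc_pairs), "complete_pair"] = False
        out = out[~drop_mask].reset_index(drop=True)

    if config.mz_single_genotyped_rate > 0:
        mz_complete = out[(out["zygosity"] == "MZ") & out["complete_pair"]]["pair"].unique()
        n_imp = int(round(config.mz_single_genotyped_rate * len(mz_complete)))
        if n_imp > 0:
            imp_pairs = rng.choice(mz_complete, size=n_imp, replace=False)
            lost_order = rng.integers(1, 3, size=n_imp)
            if panel_out is not None:
                panel_out = GenotypePanel(
                    samples=panel_out.samples.copy(),
                    snps=panel_out.snps.copy(),
                    dosages=panel_out.dosages.copy(),
                )
            for p, o in zip(imp_pairs, lost_order):
                mask = (out["pair"] == p) & (out["order"] == o)
                out.loc[mask, "prs_imputed"] = True
                keep = (out["pair"] == p) & (out["order"] != o)
                prs_cols = [c for c in out.columns if c.startswith("zprs") or c.startswith("prs_")]
                prs_cols = [c for c in prs_cols if c != "prs_imputed"]
                for col in prs_cols:
                    out.loc[mask, col] = out.loc[keep, col].to_numpy()
                if panel_out is not None:
                    pm = (panel_out.samples["pair"] == p) & (panel_out.samples["order"] == o)
                    panel_out.dosages[pm.to_numpy()] = np.nan
    return out, panel_out
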