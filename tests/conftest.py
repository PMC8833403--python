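import numpy as np
import pandas as pd
import pytest

from twinprs.simdata import (
    CohortSimConfig,
    simulate_apoe,
    simulate_gwas_sumstats,
    simulate_haplotype_pool,
    simulate_liability_cohort,
    simulate_twin_genotypes,
)


@pytest.fixture(scope="session")
def small_pool():
    return simulate_haplotype_pool(
        n_blocks=30, block_size=5, rho=0.7, seed=11, apoe_region_blocks=3
    )


@pytest.fixture(scope="session")
def small_panel(small_pool):
    panel = simulate_twin_genotypes(small_pool, n_mz=120, n_dz=180, seed=11)
    return simulate_apoe(panel, seed=11)


@pytest.fixture(scope="session")
def small_sumstats(small_pool):
    rng = np.random.default_rng(12)
    betas = rng.normal(0.0, 0.05, small_pool.n_snps)
    return simulate_gwas_sumstats(small_pool, betas, n_gwas=50_000, seed=12)


@pytest.fixture(scope="session")
def table2_reduced1_config():
    """Generating shares of the best-fitting AE+PRS decomposition."""
    return CohortSimConfig(
        n_mz=1000,
        n_dz=1000,
        sigma2_ap=0.101,
        sigma2_ab=0.614,
        sigma2_e=0.285,
        prevalence=0.27,
        seed=21,
    )


@pytest.fixture(scope="session")
def medium_cohort(table2_reduced1_config):
    return simulate_liability_cohort(table2_reduced1_config)


def make_clustered_binary(n_mz, n_dz, v_mz, v_dz, beta, seed):
    """Random-intercept probit generative model for recovery oracles."""
    from scipy.special import ndtr

    rng = np.random.default_rng(seed)
    frames = []
    for zyg, n, v in (("MZ", n_mz, v_mz), ("DZ", n_dz, v_dz)):
        u = rng.normal(0.0, np.sqrt(v), n)
        x = rng.normal(0.0, 1.0, (n, 2))
        for t in range(2):
            eta = beta[0] + beta[1] * x[:, t] + u
            y = (rng.uniform(size=n) < ndtr(eta)).astype(int)
            frames.append(
                pd.DataFrame(
                    {
                        "iid": [f"{zyg}{i}_t{t}" for i in range(n)],
                        "pair": [f"{zyg}{i}" for i in range(n)],
                        "order": t + 1,
                        "zygosity": zyg,
                        "x": x[:, t],
                        "ad": y,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
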