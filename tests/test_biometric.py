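import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest, multivariate_normal, norm

from twinprs.biometric import (
    BiometricParams,
    ModelFlags,
    build_pair_covariance,
    compare_minus2ll,
    compare_models,
    fit_biometric,
    fit_criteria_sem,
    measured_genetic_share,
    pair_loglik,
    power_sim,
    profile_ci,
    profile_interval,
    tetrachoric,
)
from twinprs.simdata import CohortSimConfig, simulate_liability_cohort


def _reduced1_params(p=None):
    return BiometricParams(
        sigma2_ap=0.101, sigma2_ab=0.614, p=1.0 / np.sqrt(0.101) if p is None else p
    )


class TestPairCovariance:
    def test_table_arithmetic(self):
        # r_MZ = 0.614 + 0.101 = 0.715, r_DZ = 0.3575
        params = _reduced1_params()
        mz = build_pair_covariance(params, "MZ")
        dz = build_pair_covariance(params, "DZ")
        li = mz.variables.index("L1")
        assert mz.matrix[li, li + 1] == pytest.approx(0.715)
        assert dz.matrix[li, li + 1] == pytest.approx(0.3575)
        assert mz.matrix[li, li] == 1.0

    def test_no_familial_components(self):
        params = BiometricParams(sigma2_ap=0.0, sigma2_ab=0.0)
        flags = ModelFlags()
        mz = build_pair_covariance(params, "MZ", flags)
        dz = build_pair_covariance(params, "DZ", flags)
        np.testing.assert_allclose(mz.matrix, dz.matrix)
        np.testing.assert_allclose(mz.matrix, np.eye(2))

    def test_mz_prs_block_singular(self):
        params = BiometricParams(sigma2_ap=0.25, p=2.0)  # p^2 sigma2 = 1
        mz = build_pair_covariance(params, "MZ")
        np.testing.assert_allclose(mz.matrix[:2, :2], np.ones((2, 2)))

    def test_symmetry_and_e4_block(self):
        params = BiometricParams(
            sigma2_ap=0.021, sigma2_ae4=0.093, sigma2_ab=0.596, p=3.0, q=2.0
        )
        flags = ModelFlags(include_prs=True, include_e4=True)
        cov = build_pair_covariance(params, "DZ", flags)
        assert cov.variables == ["PRS1", "PRS2", "E41", "E42", "L1", "L2"]
        np.testing.assert_allclose(cov.matrix, cov.matrix.T)
        assert cov.matrix[2, 2] == pytest.approx(4 * 0.093)
        assert cov.matrix[2, 3] == pytest.approx(0.5 * 4 * 0.093)
        assert cov.matrix[2, 4] == pytest.approx(2 * 0.093)  # q * sigma2_ae4
        assert cov.matrix[0, 2] == 0.0  # PRS and e4 factors uncorrelated


class TestPairLoglik:
    def test_pure_e_factorizes(self):
        # no familial variance, no measured block: pair likelihood is the
        # product of two independent univariate probits
        params = BiometricParams(mean_coefs=np.array([0.2, 0.4]))
        obs = {"y": [1, 0], "x": [[1.0, 0.5], [1.0, -0.2]]}
        ll = pair_loglik(obs, params, "MZ", ModelFlags())
        m1 = 0.2 + 0.4 * 0.5
        m2 = 0.2 + 0.4 * -0.2
        assert ll == pytest.approx(norm.logcdf(m1) + norm.logcdf(-m2), abs=1e-10)

    def test_mz_prs_hand_factorization(self):
        # MZ pair, sigma2_ap = 0.2, p = 1: conditional on the shared PRS the
        # latent A_P is known exactly, so the binary part factorizes into
        # univariate probits with mean shifted by the PRS and residual
        # variance 1 - 0.2 (hand arithmetic)
        params = BiometricParams(sigma2_ap=0.2, p=1.0, mean_coefs=np.array([0.2, 0.4]))
        obs = {"y": [1, 0], "x": [[1.0, 0.5], [1.0, -0.2]], "prs": [0.3, 0.3]}
        ll = pair_loglik(obs, params, "MZ", ModelFlags(include_prs=True))
        m1 = 0.2 + 0.4 * 0.5 + 0.3
        m2 = 0.2 + 0.4 * -0.2 + 0.3
        sd = np.sqrt(1 - 0.2)
        expected = (
            norm.logpdf(0.3, scale=np.sqrt(0.2))
            + norm.logcdf(m1 / sd)
            + norm.logcdf(-m2 / sd)
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_rectangle_vs_monte_carlo_oracle(self):
        # brute-force oracle: conditional orthant probability estimated from
        # 200k draws of the implied joint normal (via build_pair_covariance
        # and numpy Schur complement, independent of the likelihood path)
        rng = np.random.default_rng(7)
        flags = ModelFlags(include_prs=True)
        for trial in range(4):
            params = BiometricParams(
                sigma2_ap=rng.uniform(0.05, 0.2),
                sigma2_ab=rng.uniform(0.2, 0.5),
                sigma2_c=rng.uniform(0.0, 0.15),
                p=rng.uniform(1.5, 3.0),
                mu_prs=rng.normal(0, 0.3),
                mean_coefs=np.array([rng.normal(0, 0.5)]),
            )
            cov = build_pair_covariance(params, "DZ", flags).matrix
            prs = rng.normal(params.mu_prs, np.sqrt(cov[0, 0]), 2)
            y = rng.integers(0, 2, 2)
            obs = {"y": y, "x": [[1.0], [1.0]], "prs": prs}

            s_mm = cov[:2, :2]
            s_lm = cov[2:, :2]
            s_ll = cov[2:, 2:]
            b = s_lm @ np.linalg.inv(s_mm)
            cond_mean = params.mean_coefs[0] + b @ (prs - params.mu_prs)
            cond_cov = s_ll - b @ s_lm.T
            draws = rng.multivariate_normal(cond_mean, cond_cov, size=200_000)
            hit = ((draws[:, 0] > 0) == y[0]) & ((draws[:, 1] > 0) == y[1])
            p_mc = hit.mean()
            se_mc = np.sqrt(p_mc * (1 - p_mc) / len(draws))

            ll = pair_loglik(obs, params, "DZ", flags)
            log_meas = multivariate_normal(
                np.full(2, params.mu_prs), s_mm
            ).logpdf(prs)
            p_model = np.exp(ll - log_meas)
            assert p_model == pytest.approx(p_mc, abs=3 * se_mc + 1e-4)

    def test_conditional_schur_by_hand(self):
        # hand 4x4 check of the conditional liability correlation for a DZ
        # pair: explicit scalar Schur complement
        params = _reduced1_params(p=2.5)
        cov = build_pair_covariance(params, "DZ").matrix
        v = cov[0, 0]
        rg = 0.5
        alpha = cov[0, 2]
        beta = cov[0, 3]
        denom = v * (1 - rg**2)
        red_d = (alpha**2 + beta**2 - 2 * rg * alpha * beta) / denom
        red_o = (2 * alpha * beta - rg * (alpha**2 + beta**2)) / denom
        s_mm = cov[:2, :2]
        s_lm = cov[2:, :2]
        cond = cov[2:, 2:] - s_lm @ np.linalg.inv(s_mm) @ s_lm.T
        assert cond[0, 0] == pytest.approx(1 - red_d, abs=1e-12)
        assert cond[0, 1] == pytest.approx(cov[2, 3] - red_o, abs=1e-12)

    def test_nonfinite_covariates_raise(self):
        params = _reduced1_params()
        obs = {"y": [1, 0], "x": [[1.0, np.nan], [1.0, 0.0]], "prs": [0.1, 0.2]}
        params.mean_coefs = np.array([0.0, 0.1])
        with pytest.raises(ValueError):
            pair_loglik(obs, params, "DZ", ModelFlags(include_prs=True))


class TestFitCriteriaSem:
    def test_printed_model0(self):
        aic, bic = fit_criteria_sem(888.71, 7, 449)
        assert aic == pytest.approx(902.71, abs=0.005)
        assert bic == pytest.approx(931.46, abs=0.005)
        aic, bic = fit_criteria_sem(889.52, 6, 449)
        assert aic == pytest.approx(901.52, abs=0.005)
        assert bic == pytest.approx(926.16, abs=0.005)

    def test_k_zero(self):
        aic, _ = fit_criteria_sem(100.0, 0, 10)
        assert aic == 100.0


class TestCompareModels:
    def test_printed_delta(self):
        comp = compare_minus2ll(888.71, 889.52, 1)
        assert comp.delta_chisq == pytest.approx(0.81, abs=1e-9)
        assert comp.p_value == pytest.approx(0.369, abs=0.002)

    def test_identical(self):
        comp = compare_minus2ll(100.0, 100.0, 0)
        assert comp.delta_chisq == 0.0
        assert comp.p_value == 1.0


class TestFitBiometric:
    def test_ae_recovery(self):
        cfg = CohortSimConfig(
            n_mz=1500, n_dz=1500, sigma2_ab=0.707, sigma2_e=0.293, prevalence=0.27, seed=70
        )
        coh = simulate_liability_cohort(cfg)
        fit = fit_biometric(coh, "ae", seed=0)
        a_hat = fit.shares["A_B"]
        se = fit.se["sigma2_ab"]
        assert abs(a_hat - 0.707) < 3 * se
        assert sum(fit.shares[k] for k in ("A_P", "A_e4", "A_B", "C", "E")) + 2 * fit.shares[
            "covAC"
        ] == pytest.approx(1.0, abs=1e-8)
        assert fit.total_a == pytest.approx(fit.shares["A_B"], abs=1e-12)
        assert fit.k == 6  # A, E(derived counted), b0 + 3 covariates
        assert fit.aic == pytest.approx(fit.minus2ll + 2 * fit.k)

    def test_ae_prs_recovery(self, medium_cohort):
        fit = fit_biometric(medium_cohort, "ae_prs", seed=0)
        assert abs(fit.shares["A_P"] - 0.101) < 3 * max(fit.se["sigma2_ap"], 0.01)
        assert abs(fit.shares["A_B"] - 0.614) < 3 * max(fit.se["sigma2_ab"], 0.04)
        assert fit.k == 9

    def test_c_generating_structure(self):
        cfg = CohortSimConfig(
            n_mz=1200, n_dz=1200, sigma2_ab=0.0, sigma2_c=0.45, sigma2_e=0.55,
            prevalence=0.3, seed=71,
        )
        coh = simulate_liability_cohort(cfg)
        fit = fit_biometric(coh, "ace", seed=0, compute_se=False)
        assert fit.shares["C"] > 0.3
        assert abs(fit.shares["A_B"]) < 0.15
        # implied MZ and DZ correlations approximately equal
        p = fit.estimates
        r_mz = p["sigma2_ab"] + p["sigma2_c"]
        r_dz = 0.5 * p["sigma2_ab"] + p["sigma2_c"]
        assert r_mz == pytest.approx(r_dz, abs=0.15)

    def test_falconer_consistency(self):
        # classical oracle: A ~ 2(r_MZ - r_DZ) from tetrachoric correlations
        cfg = CohortSimConfig(
            n_mz=5000, n_dz=5000, sigma2_ab=0.6, sigma2_e=0.4, prevalence=0.3,
            beta_sex=0.0, beta_age=0.0, beta_age2=0.0, seed=72,
        )
        coh = simulate_liability_cohort(cfg)
        y = coh["ad"].to_numpy().reshape(-1, 2)
        zyg = coh["zygosity"].to_numpy()[::2]
        r_mz = tetrachoric(y[zyg == "MZ", 0], y[zyg == "MZ", 1])
        r_dz = tetrachoric(y[zyg == "DZ", 0], y[zyg == "DZ", 1])
        falconer = 2 * (r_mz - r_dz)
        fit = fit_biometric(coh, "ae", covariates=(), seed=0, compute_se=False)
        assert fit.shares["A_B"] == pytest.approx(falconer, abs=0.1)

    def test_direct_and_genotype_modes_agree(self):
        from twinprs.simdata import simulate_haplotype_pool, simulate_twin_genotypes

        shares = dict(sigma2_ap=0.2, sigma2_ab=0.4, sigma2_e=0.4)
        cfg_d = CohortSimConfig(n_mz=800, n_dz=800, seed=73, **shares)
        coh_d = simulate_liability_cohort(cfg_d)
        pool = simulate_haplotype_pool(n_blocks=80, block_size=1, rho=0.0, seed=73)
        panel = simulate_twin_genotypes(pool, 800, 800, seed=73)
        rng = np.random.default_rng(74)
        weights = pd.Series(rng.normal(0, 0.1, pool.n_snps), index=pool.snps["snp"])
        cfg_g = CohortSimConfig(n_mz=800, n_dz=800, seed=73, mode="genotype", **shares)
        coh_g = simulate_liability_cohort(cfg_g, panel=panel, prs_weights=weights)
        fit_d = fit_biometric(coh_d, "ae_prs", seed=0, compute_se=False)
        fit_g = fit_biometric(coh_g, "ae_prs", seed=0, compute_se=False)
        assert fit_d.shares["A_P"] == pytest.approx(fit_g.shares["A_P"], abs=0.06)
        assert fit_d.shares["A_B"] == pytest.approx(fit_g.shares["A_B"], abs=0.12)

    def test_requires_both_zygosities(self, medium_cohort):
        with pytest.raises(ValueError):
            fit_biometric(medium_cohort[medium_cohort["zygosity"] == "MZ"], "ae")


class TestProfileCi:
    def test_quadratic_toy_matches_wald(self):
        # closed form: m2ll(v) = ((v - mu)/sd)^2 -> CI = mu +/- 1.95996 sd
        mu, sd = 0.4, 0.07
        lo, hi = profile_interval(
            lambda v: ((v - mu) / sd) ** 2, mu, sd, 0.0, 0.95, xtol=1e-8
        )
        z = norm.ppf(0.975)
        assert lo == pytest.approx(mu - z * sd, abs=1e-3)
        assert hi == pytest.approx(mu + z * sd, abs=1e-3)

    def test_level_zero_degenerate(self):
        cfg = CohortSimConfig(n_mz=150, n_dz=150, sigma2_ab=0.6, sigma2_e=0.4, seed=75)
        coh = simulate_liability_cohort(cfg)
        fit = fit_biometric(coh, "ae", seed=0)
        lo, hi, _ = profile_ci(fit, "sigma2_ab", level=0.0)
        assert lo == hi == pytest.approx(fit.estimates["sigma2_ab"])

    def test_fixed_component_errors(self):
        cfg = CohortSimConfig(n_mz=150, n_dz=150, sigma2_ab=0.6, sigma2_e=0.4, seed=75)
        coh = simulate_liability_cohort(cfg)
        fit = fit_biometric(coh, "ae", seed=0)
        with pytest.raises(ValueError):
            profile_ci(fit, "sigma2_c")

    def test_profile_on_small_fit_brackets_truth(self):
        cfg = CohortSimConfig(n_mz=400, n_dz=400, sigma2_ab=0.6, sigma2_e=0.4, seed=76)
        coh = simulate_liability_cohort(cfg)
        fit = fit_biometric(coh, "ae", seed=0)
        lo, hi, profiled = profile_ci(fit, "sigma2_ab")
        assert profiled
        assert lo < fit.estimates["sigma2_ab"] < hi
        assert lo < 0.6 < hi


class TestPowerSim:
    def test_deterministic(self):
        cfg = CohortSimConfig(n_mz=120, n_dz=120, sigma2_ab=0.5, sigma2_c=0.0,
                              sigma2_e=0.5, seed=0)
        a = power_sim(cfg, "ace", "ae", n_reps=4, seed=5, compute_se=False)
        b = power_sim(cfg, "ace", "ae", n_reps=4, seed=5, compute_se=False)
        assert a == b

    def test_strong_effect_power_one(self):
        cfg = CohortSimConfig(n_mz=250, n_dz=250, sigma2_ap=0.35, sigma2_ab=0.25,
                              sigma2_e=0.4, seed=0)
        res = power_sim(cfg, "ae_prs", "ae_prs_null", n_reps=5, seed=6, compute_se=False)
        assert res["power"] == 1.0


def test_measured_genetic_share():
    assert measured_genetic_share({"A_P": 0.021, "A_e4": 0.093}) == pytest.approx(0.114)
    assert measured_genetic_share({"A_P": 0.101}) == pytest.approx(0.101)
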