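"""Extended ACE liability-threshold twin model with measured genetic scores.

Decomposes binary-trait liability into a latent polygenic factor identified
by the measured standardized PRS (A_P), an optional factor identified by the
measured APOE e4 allele count (A_e4), background additive genetic variance
(A_B), shared (C) and unique (E) environment, with an optional A–C
covariance.  The total liability variance is fixed at 1 with E derived, the
threshold is fixed at 0 with the liability mean estimated, and all variance
components are estimated without sign bounds so likelihood-ratio tests keep
nominal type-I error.

Likelihood per complete pair = Gaussian density of the measured block
(PRS and/or e4 count) times the bivariate-normal rectangle probability of
the binary statuses under the conditional liability distribution.  MZ pairs
carry an implied cross-twin measured correlation of 1, so their measured
block is collapsed to the pair-level mean with a univariate density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import ndtr, ndtri
from scipy.stats import chi2, norm

from ._bvn import bvn_upper, rectangle_prob

__all__ = [
    "ModelFlags",
    "BiometricParams",
    "BiometricFit",
    "ModelComparison",
    "build_pair_covariance",
    "pair_loglik",
    "fit_biometric",
    "compare_models",
    "compare_minus2ll",
    "fit_criteria_sem",
    "profile_ci",
    "profile_interval",
    "power_sim",
    "tetrachoric",
    "measured_genetic_share",
]

_PENALTY = -1e9
_TINY = 1e-10

DEFAULT_COVARIATES = ("sex", "age_c", "age_c2")


@dataclass(frozen=True)
class ModelFlags:
    """Which structural pieces are free."""

    include_prs: bool = False
    include_e4: bool = False
    include_a: bool = True  # background additive genetic variance free
    free_c: bool = True
    free_covac: bool = True
    split_covac: bool = False  # free both sides of the A-C covariance
    covac_on: str = "ab"  # single-path A-C covariance loads on 'ab' or 'ap'
    # with the link off, the measured variable keeps its twin-covariance
    # block (free variance, r_g cross-twin correlation) but loads zero on
    # liability — the nested null for testing a measured component
    prs_link: bool = True
    e4_link: bool = True

    @classmethod
    def from_name(cls, name: str) -> "ModelFlags":
        table = {
            "ace": cls(),
            "ae": cls(free_c=False, free_covac=False),
            "e": cls(include_a=False, free_c=False, free_covac=False),
            "ace_prs": cls(include_prs=True),
            "ae_prs": cls(include_prs=True, free_c=False, free_covac=False),
            "ae_prs_null": cls(include_prs=True, prs_link=False, free_c=False, free_covac=False),
            "ace_prs_e4": cls(include_prs=True, include_e4=True),
            "ae_prs_e4": cls(include_prs=True, include_e4=True, free_c=False, free_covac=False),
            "ae_prs_e4_null": cls(
                include_prs=True, include_e4=True, e4_link=False,
                free_c=False, free_covac=False,
            ),
        }
        if name not in table:
            raise ValueError(f"unknown model {name!r}; options: {sorted(table)}")
        return table[name]


@dataclass
class BiometricParams:
    """Structural parameters on the liability scale; sigma2_e is derived."""

    sigma2_ap: float = 0.0
    sigma2_ab: float = 0.0
    sigma2_ae4: float = 0.0
    sigma2_c: float = 0.0
    sigma_apc: float = 0.0
    sigma_abc: float = 0.0
    p: float = 1.0
    q: float = 1.0
    mu_prs: float = 0.0
    mu_e4: float = 0.0
    v_prs: float = 0.0  # free measured-PRS variance when the link is off
    v_e4: float = 0.0
    mean_coefs: np.ndarray = field(default_factory=lambda: np.zeros(1))  # b0, covariates...

    @property
    def cov_ac(self) -> float:
        return self.sigma_apc + self.sigma_abc

    @property
    def sigma2_e(self) -> float:
        return 1.0 - (
            self.sigma2_ap
            + self.sigma2_ab
            + self.sigma2_ae4
            + self.sigma2_c
            + 2.0 * self.cov_ac
        )


@dataclass
class ImpliedPairCovariance:
    variables: list[str]
    matrix: np.ndarray
    zygosity: str


def _r_g(zygosity: str) -> float:
    if zygosity == "MZ":
        return 1.0
    if zygosity == "DZ":
        return 0.5
    raise ValueError("zygosity must be 'MZ' or 'DZ'")


def liability_cross_cov(params: BiometricParams, zygosity: str) -> float:
    """Cross-twin liability covariance: r_g (A_B + A_P + A_e4) + C + 2 covAC."""
    rg = _r_g(zygosity)
    return (
        rg * (params.sigma2_ab + params.sigma2_ap + params.sigma2_ae4)
        + params.sigma2_c
        + 2.0 * params.cov_ac
    )


def build_pair_covariance(
    params: BiometricParams, zygosity: str, flags: ModelFlags = ModelFlags(include_prs=True)
) -> ImpliedPairCovariance:
    """Model-implied covariance of (PRS1, PRS2[, E41, E42], L1, L2)."""
    rg = _r_g(zygosity)
    blocks: list[tuple[str, float, float, float]] = []
    if flags.include_prs:
        if flags.prs_link:
            blocks.append(
                ("PRS", params.p**2 * params.sigma2_ap,
                 params.p * (params.sigma2_ap + params.sigma_apc),
                 params.p * (rg * params.sigma2_ap + params.sigma_apc))
            )
        else:
            blocks.append(("PRS", params.v_prs, 0.0, 0.0))
    if flags.include_e4:
        if flags.e4_link:
            blocks.append(
                ("E4", params.q**2 * params.sigma2_ae4,
                 params.q * params.sigma2_ae4,
                 params.q * rg * params.sigma2_ae4)
            )
        else:
            blocks.append(("E4", params.v_e4, 0.0, 0.0))

    names: list[str] = []
    for name, *_ in blocks:
        names += [f"{name}1", f"{name}2"]
    names += ["L1", "L2"]
    d = len(names)
    m = np.zeros((d, d))
    li = d - 2
    m[li, li] = m[li + 1, li + 1] = 1.0
    m[li, li + 1] = m[li + 1, li] = liability_cross_cov(params, zygosity)
    for bi, (name, v_m, own, cross) in enumerate(blocks):
        i = 2 * bi
        m[i, i] = m[i + 1, i + 1] = v_m
        m[i, i + 1] = m[i + 1, i] = rg * v_m
        m[i, li] = m[li, i] = own
        m[i + 1, li + 1] = m[li + 1, i + 1] = own
        m[i, li + 1] = m[li + 1, i] = cross
        m[i + 1, li] = m[li, i + 1] = cross
    return ImpliedPairCovariance(variables=names, matrix=m, zygosity=zygosity)


# ---------------------------------------------------------------------------
# vectorized likelihood over prepared pair data


def _block_terms(v, alpha, beta, rg, collapse):
    """Likelihood ingredients for one measured factor block.

    ``v`` is the measured variance, ``alpha``/``beta`` the own/cross-twin
    covariances with liability.  ``B`` gives the conditional-mean loading of
    (L1, L2) on the centered observations and ``red`` the (diag, offdiag)
    variance reduction of the liability block.
    """
    if v <= _TINY:
        return None
    if collapse:
        b11 = alpha / v
        return {
            "v": v,
            "B": (b11, b11),  # loading of L1 and L2 on the single collapsed value
            "red": (alpha * alpha / v, alpha * alpha / v),
            "collapsed": True,
        }
    det = v * v * (1.0 - rg * rg)
    if det <= _TINY:
        return None
    denom = v * (1.0 - rg * rg)
    b_own = (alpha - rg * beta) / denom
    b_oth = (beta - rg * alpha) / denom
    red_d = (alpha * alpha + beta * beta - 2.0 * rg * alpha * beta) / denom
    red_o = (2.0 * alpha * beta - rg * (alpha * alpha + beta * beta)) / denom
    return {"v": v, "rg": rg, "B": (b_own, b_oth), "red": (red_d, red_o), "collapsed": False}


def _group_loglik(params: BiometricParams, flags: ModelFlags, zygosity: str, data) -> float:
    """Sum of pair log-likelihood contributions for one zygosity group."""
    y = data["y"]
    n = y.shape[0]
    if n == 0:
        return 0.0
    rg = _r_g(zygosity)
    collapse = zygosity == "MZ"
    mean_l = data["x"] @ params.mean_coefs  # (n, 2)

    ll = 0.0
    cond_mean = mean_l.copy()
    red_d = red_o = 0.0

    specs = []
    if flags.include_prs:
        if flags.prs_link:
            specs.append(("prs", params.p**2 * params.sigma2_ap,
                          params.p * (params.sigma2_ap + params.sigma_apc),
                          params.p * (rg * params.sigma2_ap + params.sigma_apc),
                          params.mu_prs))
        else:
            specs.append(("prs", params.v_prs, 0.0, 0.0, params.mu_prs))
    if flags.include_e4:
        if flags.e4_link:
            specs.append(("e4", params.q**2 * params.sigma2_ae4,
                          params.q * params.sigma2_ae4,
                          params.q * rg * params.sigma2_ae4,
                          params.mu_e4))
        else:
            specs.append(("e4", params.v_e4, 0.0, 0.0, params.mu_e4))

    for key, v_m, alpha, beta, mu in specs:
        terms = _block_terms(v_m, alpha, beta, rg, collapse)
        if terms is None:
            return _PENALTY * (1.0 + abs(v_m))
        obs = data[key]  # (n, 2)
        if terms["collapsed"]:
            val = obs.mean(axis=1) - mu
            v = terms["v"]
            ll += -0.5 * n * math.log(2.0 * math.pi * v) - 0.5 * float((val**2).sum()) / v
            b = terms["B"][0]
            cond_mean += (b * val)[:, None]
        else:
            d1 = obs[:, 0] - mu
            d2 = obs[:, 1] - mu
            v = terms["v"]
            det = v * v * (1.0 - rg * rg)
            quad = (d1 * d1 + d2 * d2 - 2.0 * rg * d1 * d2) / (v * (1.0 - rg * rg))
            ll += -n * math.log(2.0 * math.pi) - 0.5 * n * math.log(det) - 0.5 * float(quad.sum())
            b_own, b_oth = terms["B"]
            cond_mean[:, 0] += b_own * d1 + b_oth * d2
            cond_mean[:, 1] += b_oth * d1 + b_own * d2
        red_d += terms["red"][0]
        red_o += terms["red"][1]

    c_var = 1.0 - red_d
    c_off = liability_cross_cov(params, zygosity) - red_o
    if c_var <= _TINY:
        return _PENALTY * (1.0 + abs(c_var))
    rho = c_off / c_var
    if abs(rho) >= 1.0 - 1e-9:
        return _PENALTY * (1.0 + abs(rho))
    sd = math.sqrt(c_var)
    probs = rectangle_prob(y[:, 0], y[:, 1], cond_mean[:, 0], cond_mean[:, 1], sd, sd, rho)
    probs = np.maximum(probs, 1e-300)
    ll += float(np.log(probs).sum())
    return ll


def pair_loglik(
    observations: dict,
    params: BiometricParams,
    zygosity: str,
    flags: ModelFlags = ModelFlags(include_prs=True),
) -> float:
    """Log-likelihood contribution of one complete pair.

    ``observations`` carries ``y`` (two 0/1 statuses), covariate rows ``x``
    (two rows, intercept included), and ``prs``/``e4`` pairs as required by
    the flags.
    """
    data = {
        "y": np.asarray(observations["y"], float).reshape(1, 2),
        "x": np.asarray(observations["x"], float).reshape(1, 2, -1),
    }
    if flags.include_prs:
        data["prs"] = np.asarray(observations["prs"], float).reshape(1, 2)
    if flags.include_e4:
        data["e4"] = np.asarray(observations["e4"], float).reshape(1, 2)
    if not np.all(np.isfinite(data["x"])):
        raise ValueError("non-finite covariates")
    return _group_loglik(params, flags, zygosity, data)


# ---------------------------------------------------------------------------
# parameter vector mapping


class _ModelSpec:
    def __init__(self, flags: ModelFlags, covariates: tuple[str, ...]):
        self.flags = flags
        self.covariates = tuple(covariates)
        names = ["sigma2_ab"] if flags.include_a else []
        if flags.include_prs:
            names += ["sigma2_ap", "p", "mu_prs"] if flags.prs_link else ["v_prs", "mu_prs"]
        if flags.include_e4:
            names += ["sigma2_ae4", "q", "mu_e4"] if flags.e4_link else ["v_e4", "mu_e4"]
        if flags.free_c:
            names += ["sigma2_c"]
        if flags.free_covac:
            names += ["cov_ac"]
            if flags.split_covac:
                names += ["sigma_apc"]
        names += ["b0"] + [f"b_{c}" for c in self.covariates]
        self.names = names
        # SEM-convention parameter count includes the derived E component
        self.k = len(names) + 1

    def to_params(self, theta: np.ndarray) -> BiometricParams:
        d = dict(zip(self.names, theta))
        n_mean = 1 + len(self.covariates)
        cov_total = d.get("cov_ac", 0.0)
        if self.flags.split_covac:
            apc = d.get("sigma_apc", 0.0)
        elif self.flags.covac_on == "ap":
            apc = cov_total
        else:
            apc = 0.0
        return BiometricParams(
            sigma2_ap=d.get("sigma2_ap", 0.0),
            sigma2_ab=d.get("sigma2_ab", 0.0),
            sigma2_ae4=d.get("sigma2_ae4", 0.0),
            sigma2_c=d.get("sigma2_c", 0.0),
            sigma_apc=apc,
            sigma_abc=cov_total - apc,
            p=d.get("p", 1.0),
            q=d.get("q", 1.0),
            mu_prs=d.get("mu_prs", 0.0),
            mu_e4=d.get("mu_e4", 0.0),
            v_prs=d.get("v_prs", 0.0),
            v_e4=d.get("v_e4", 0.0),
            mean_coefs=np.asarray(theta[-n_mean:], float),
        )


def _prepare_pairs(
    cohort: pd.DataFrame,
    flags: ModelFlags,
    covariates: tuple[str, ...],
    prs_col: str,
    e4_col: str,
    outcome: str,
):
    df = cohort.copy()
    sizes = df.groupby("pair")["iid"].transform("size")
    df = df[(sizes == 2) & df["complete_pair"]] if "complete_pair" in df else df[sizes == 2]
    df = df.sort_values(["pair", "order"], kind="mergesort")
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = df[df["zygosity"] == zyg]
        n = len(sub) // 2
        data = {
            "y": sub[outcome].to_numpy(float).reshape(n, 2),
            "x": np.column_stack(
                [np.ones(len(sub))] + [sub[c].to_numpy(float) for c in covariates]
            ).reshape(n, 2, -1),
        }
        if flags.include_prs:
            data["prs"] = sub[prs_col].to_numpy(float).reshape(n, 2)
        if flags.include_e4:
            data["e4"] = sub[e4_col].to_numpy(float).reshape(n, 2)
        out[zyg] = data
    return out


@dataclass
class BiometricFit:
    estimates: pd.Series
    se: pd.Series
    shares: dict
    total_a: float
    minus2ll: float
    k: int
    n_pairs: int
    aic: float
    bic: float
    flags: ModelFlags
    covariates: tuple[str, ...]
    converged: bool
    message: str = ""
    ci: dict = field(default_factory=dict)
    spec: "_ModelSpec | None" = None
    _data: dict | None = field(default=None, repr=False)

    @property
    def free_names(self) -> list[str]:
        return list(self.estimates.index)


@dataclass
class ModelComparison:
    delta_chisq: float
    delta_df: int
    p_value: float
    dropped: list[str]


def fit_criteria_sem(minus2ll: float, k: int, n_pairs: int) -> tuple[float, float]:
    """(AIC, BIC) in the SEM reporting convention: -2LL + 2k and
    -2LL + k ln(n pairs)."""
    if k < 0 or n_pairs < 1:
        raise ValueError("need k >= 0 and n_pairs >= 1")
    return minus2ll + 2.0 * k, minus2ll + k * math.log(n_pairs)


def tetrachoric(y1, y2) -> float:
    """Latent correlation of a 2x2 binary table (thresholds from margins)."""
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    # symmetrize: either twin can be "twin 1"
    a = np.concatenate([y1, y2])
    b = np.concatenate([y2, y1])
    t = ndtri(1.0 - a.mean())
    p11 = float(((a == 1) & (b == 1)).mean())

    def f(r):
        return bvn_upper(t, t, r) - p11

    lo, hi = -0.999, 0.999
    if f(lo) * f(hi) > 0:
        return 0.999 if abs(f(hi)) < abs(f(lo)) else -0.999
    return brentq(f, lo, hi, xtol=1e-8)


def measured_genetic_share(shares: dict) -> float:
    """Total measured genetic contribution: A_P plus A_e4 shares."""
    return float(shares.get("A_P", 0.0) + shares.get("A_e4", 0.0))


def _starting_points(spec: _ModelSpec, data, seed: int, n_jitter: int) -> list[np.ndarray]:
    flags = spec.flags
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))

    all_y = np.vstack([data["MZ"]["y"], data["DZ"]["y"]])
    all_x = np.vstack([data["MZ"]["x"].reshape(-1, data["MZ"]["x"].shape[2]),
                       data["DZ"]["x"].reshape(-1, data["DZ"]["x"].shape[2])])
    yy = all_y.reshape(-1)
    # crude probit start for the liability mean: IRLS-free two-step
    base = ndtri(np.clip(yy.mean(), 1e-3, 1 - 1e-3))
    coef = np.zeros(all_x.shape[1])
    coef[0] = base
    try:  # one-shot weighted LS refinement of the probit mean model
        eta = all_x @ coef
        mu = np.clip(ndtr(eta), 1e-6, 1 - 1e-6)
        w = norm.pdf(eta) ** 2 / (mu * (1 - mu))
        z = eta + (yy - mu) / np.maximum(norm.pdf(eta), 1e-6)
        wx = all_x * w[:, None]
        coef = np.linalg.solve(all_x.T @ wx, wx.T @ z)
    except np.linalg.LinAlgError:
        pass

    try:
        r_mz = tetrachoric(data["MZ"]["y"][:, 0], data["MZ"]["y"][:, 1])
        r_dz = tetrachoric(data["DZ"]["y"][:, 0], data["DZ"]["y"][:, 1])
        a0 = float(np.clip(2.0 * (r_mz - r_dz), 0.05, 0.95))
        c0 = float(np.clip(2.0 * r_dz - r_mz, -0.3, 0.6))
    except Exception:
        a0, c0 = 0.5, 0.0

    def build(ap, ae4, extra_a=a0, c=c0):
        d = {"sigma2_ab": max(extra_a - ap - ae4, 0.02)}
        if flags.include_prs:
            prs = np.vstack([data["MZ"]["prs"], data["DZ"]["prs"]]).reshape(-1)
            d["sigma2_ap"] = ap
            d["p"] = float(prs.std() / math.sqrt(ap))
            d["mu_prs"] = float(prs.mean())
            d["v_prs"] = float(prs.var())
        if flags.include_e4:
            e4 = np.vstack([data["MZ"]["e4"], data["DZ"]["e4"]]).reshape(-1)
            d["sigma2_ae4"] = ae4
            d["q"] = float(max(e4.std(), 0.05) / math.sqrt(ae4))
            d["mu_e4"] = float(e4.mean())
            d["v_e4"] = float(max(e4.var(), 0.01))
        if flags.free_c:
            d["sigma2_c"] = c
        if flags.free_covac:
            d["cov_ac"] = 0.0
            if flags.split_covac:
                d["sigma_apc"] = 0.0
        theta = [d.get(nm, 0.0) for nm in spec.names if not nm.startswith("b")]
        return np.concatenate([theta, coef])

    ap_grid = [0.05, 0.15] if flags.include_prs else [0.0]
    ae4_grid = [0.08] if flags.include_e4 else [0.0]
    starts = [build(ap if flags.include_prs else 0.0, ae4) for ap in ap_grid for ae4 in ae4_grid]
    base0 = starts[0]
    for _ in range(n_jitter):
        jit = base0 * (1.0 + 0.15 * rng.standard_normal(len(base0)))
        starts.append(jit)
    return starts


def fit_biometric(
    cohort: pd.DataFrame,
    model: "ModelFlags | str" = "ace",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    prs_col: str = "zprs",
    e4_col: str = "apoe_e4",
    outcome: str = "ad",
    seed: int = 0,
    n_jitter_starts: int = 2,
    compute_se: bool = True,
) -> BiometricFit:
    """Maximum-likelihood fit of the extended ACE model to complete pairs.

    Multi-start Nelder–Mead refined by BFGS on the best start; no sign
    bounds on variance components.
    """
    flags = ModelFlags.from_name(model) if isinstance(model, str) else model
    spec = _ModelSpec(flags, covariates)
    data = _prepare_pairs(cohort, flags, covariates, prs_col, e4_col, outcome)
    n_pairs = data["MZ"]["y"].shape[0] + data["DZ"]["y"].shape[0]
    if data["MZ"]["y"].shape[0] < 2 or data["DZ"]["y"].shape[0] < 2:
        raise ValueError("need complete pairs of both zygosities")

    def nll(theta):
        params = spec.to_params(theta)
        val = _group_loglik(params, flags, "MZ", data["MZ"]) + _group_loglik(
            params, flags, "DZ", data["DZ"]
        )
        return -val

    best = None
    diagnostics = []
    for theta0 in _starting_points(spec, data, seed, n_jitter_starts):
        res = minimize(
            nll, theta0, method="Nelder-Mead",
            options={"maxfev": 6000, "xatol": 1e-7, "fatol": 1e-9},
        )
        diagnostics.append((res.fun, res.message))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all starts failed: {diagnostics}")
    polish = minimize(nll, best.x, method="BFGS", options={"gtol": 1e-8, "maxiter": 400})
    if polish.fun <= best.fun:
        best = polish
    theta = best.x
    params = spec.to_params(theta)

    se = np.full(len(theta), np.nan)
    if compute_se:
        try:
            hess = _numeric_hessian(nll, theta)
            cov = np.linalg.pinv(hess)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except Exception:
            pass

    shares = {
        "A_P": params.sigma2_ap,
        "A_e4": params.sigma2_ae4,
        "A_B": params.sigma2_ab,
        "C": params.sigma2_c,
        "covAC": params.cov_ac,
        "E": params.sigma2_e,
    }
    total_a = params.sigma2_ap + params.sigma2_ae4 + params.sigma2_ab + 2.0 * params.cov_ac
    m2ll = 2.0 * best.fun
    aic, bic = fit_criteria_sem(m2ll, spec.k, n_pairs)
    return BiometricFit(
        estimates=pd.Series(theta, index=spec.names),
        se=pd.Series(se, index=spec.names),
        shares=shares,
        total_a=float(total_a),
        minus2ll=float(m2ll),
        k=spec.k,
        n_pairs=n_pairs,
        aic=aic,
        bic=bic,
        flags=flags,
        covariates=tuple(covariates),
        converged=bool(np.isfinite(best.fun)),
        message=str(best.message),
        spec=spec,
        _data=data,
    )


def compare_minus2ll(
    m2ll_full: float, m2ll_reduced: float, delta_df: int, dropped: list[str] | None = None
) -> ModelComparison:
    """Likelihood-ratio comparison from raw -2LL values."""
    delta = max(float(m2ll_reduced) - float(m2ll_full), 0.0)
    p = float(chi2.sf(delta, delta_df)) if delta_df > 0 else 1.0
    return ModelComparison(delta, int(delta_df), p, dropped or [])


def compare_models(fit_full: BiometricFit, fit_reduced: BiometricFit) -> ModelComparison:
    """Likelihood-ratio comparison of nested biometric fits."""
    full_names = set(fit_full.free_names)
    red_names = set(fit_reduced.free_names)
    # a link-free measured block (v_prs / v_e4) is the nested reparameterized
    # null of the corresponding linked block (sigma2, scaling) with zero loading
    aliases = {"v_prs": {"sigma2_ap", "p"}, "v_e4": {"sigma2_ae4", "q"}}
    resolved = set()
    for nm in red_names:
        if nm in full_names:
            resolved.add(nm)
        elif nm in aliases and aliases[nm] <= full_names:
            resolved |= aliases[nm]
        else:
            raise ValueError("reduced model parameters are not a subset of the full model's")
    dropped = sorted(full_names - resolved)
    return compare_minus2ll(fit_full.minus2ll, fit_reduced.minus2ll, fit_full.k - fit_reduced.k, dropped)


def profile_interval(
    prof_m2ll,
    hat_value: float,
    step: float,
    m2ll_min: float,
    level: float = 0.95,
    max_expand: int = 8,
    xtol: float = 1e-5,
) -> tuple[float | None, float | None]:
    """Bisection bounds where ``prof_m2ll`` rises by the chi-square(1)
    quantile above ``m2ll_min``; a side that never crosses within the search
    box comes back as None."""
    target = m2ll_min + chi2.ppf(level, 1)

    def g(value):
        return prof_m2ll(value) - target

    bounds: list[float | None] = []
    for sign in (-1.0, 1.0):
        s = step
        a, b = hat_value, hat_value + sign * s
        ok = False
        for _ in range(max_expand):
            if g(b) > 0:
                ok = True
                break
            a, b = b, b + sign * s
            s *= 1.8
        if not ok:
            bounds.append(None)
            continue
        lo_, hi_ = sorted((a, b))
        bounds.append(float(brentq(g, lo_, hi_, xtol=xtol)))
    return bounds[0], bounds[1]


def profile_ci(
    fit: BiometricFit, component: str, level: float = 0.95, max_expand: int = 8
) -> tuple[float, float, bool]:
    """Profile-likelihood interval: bounds where the re-optimized -2LL rises
    by the chi-square(1) quantile (3.841 at 95%).  Returns
    (lower, upper, profiled); ``profiled`` is False when a side failed and
    the Wald interval was substituted.
    """
    if component not in fit.free_names:
        raise ValueError(f"{component!r} is not a free parameter of this fit")
    if level <= 0.0:
        est = float(fit.estimates[component])
        return est, est, True
    spec = fit.spec
    data = fit._data
    flags = fit.flags
    i = fit.free_names.index(component)
    hat = fit.estimates.to_numpy().copy()
    sd = fit.se.iloc[i]
    if not np.isfinite(sd) or sd == 0:
        sd = max(abs(hat[i]) * 0.25, 0.05)

    def prof_m2ll(value):
        def nll(theta_red):
            theta = np.insert(theta_red, i, value)
            params = spec.to_params(theta)
            val = _group_loglik(params, flags, "MZ", data["MZ"]) + _group_loglik(
                params, flags, "DZ", data["DZ"]
            )
            return -val

        theta0 = np.delete(hat, i)
        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"maxfev": 4000, "xatol": 1e-6, "fatol": 1e-9})
        return 2.0 * res.fun

    lo, hi = profile_interval(
        prof_m2ll, float(hat[i]), float(sd), fit.minus2ll, level, max_expand,
        xtol=max(sd * 1e-3, 1e-5),
    )
    if lo is None or hi is None:
        z = norm.ppf(0.5 + level / 2.0)
        return float(hat[i] - z * fit.se.iloc[i]), float(hat[i] + z * fit.se.iloc[i]), False
    return lo, hi, True


def power_sim(
    config,
    full_model: "ModelFlags | str",
    reduced_model: "ModelFlags | str",
    alpha: float = 0.05,
    n_reps: int = 100,
    seed: int = 0,
    **fit_kwargs,
) -> dict:
    """Monte-Carlo power of the LRT dropping components from ``full_model``.

    Simulates replicate cohorts from ``config`` (a
    :class:`~twinprs.simdata.CohortSimConfig`), fits both models and counts
    rejections at ``alpha``.
    """
    from .simdata import simulate_liability_cohort

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fit_kwargs.setdefault("compute_se", False)
    ss = np.random.SeedSequence([int(seed), 7])
    rep_seeds = ss.generate_state(n_reps)
    rejections = 0
    for r in range(n_reps):
        cfg = replace(config, seed=int(rep_seeds[r]))
        cohort = simulate_liability_cohort(cfg)
        fit_full = fit_biometric(cohort, full_model, seed=int(rep_seeds[r]), **fit_kwargs)
        fit_red = fit_biometric(cohort, reduced_model, seed=int(rep_seeds[r]), **fit_kwargs)
        comp = compare_models(fit_full, fit_red)
        if comp.p_value < alpha:
            rejections += 1
    power = rejections / n_reps
    mc_se = math.sqrt(power * (1.0 - power) / n_reps)
    return {"power": power, "mc_se": mc_se, "rejections": rejections, "n_reps": n_reps}


def _numeric_hessian(f, x0, eps: float = 1e-4) -> np.ndarray:
    n = len(x0)
    h = np.zeros((n, n))
    steps = np.maximum(np.abs(x0) * eps, eps)
    for i in range(n):
        for j in range(i, n):
            ei, ej = steps[i], steps[j]
            xpp = x0.copy(); xpp[i] += ei; xpp[j] += ej
            xpm = x0.copy(); xpm[i] += ei; xpm[j] -= ej
            xmp = x0.copy(); xmp[i] -= ei; xmp[j] += ej
            xmm = x0.copy(); xmm[i] -= ei; xmm[j] -= ej
            h[i, j] = h[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * ei * ej)
    return h
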