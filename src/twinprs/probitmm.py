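"""Mixed-effects probit/logit regression for clustered twin data.

Pair-level random intercepts with separate MZ and DZ variances, marginal
likelihood by adaptive Gauss–Hermite quadrature, intraclass correlations,
deviance (likelihood-ratio) tests, Nagelkerke pseudo-R², rank-based AUC and
the log-likelihood-minus-k information-criterion convention used for
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, log_ndtr, ndtr
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "PredictorSpec",
    "MixedProbitFit",
    "fit_mixed_probit",
    "icc",
    "lrt",
    "fit_criteria_mixor",
    "nagelkerke",
    "auc",
    "concordance",
]


class DegenerateResponseError(ValueError):
    """Outcome has a single level."""


@dataclass
class PredictorSpec:
    """Fixed-effect design: cohort column names (intercept implicit)."""

    columns: tuple[str, ...] = ("mz", "sex", "age_c", "age_c2", "array_code", "zprs")
    link: str = "probit"
    quad_points: int = 21
    random: str = "zygosity"  # 'zygosity' (v_MZ, v_DZ free) or 'none' (v = 0)

    def __post_init__(self) -> None:
        if self.link not in ("probit", "logit"):
            raise ValueError("link must be 'probit' or 'logit'")


@dataclass
class MixedProbitFit:
    params: pd.DataFrame  # index = names; columns est, se, z, p
    v_mz: float
    v_dz: float
    se_v_mz: float
    se_v_dz: float
    loglik: float
    k: int
    n_individuals: int
    n_pairs: int
    link: str
    converged: bool
    message: str = ""
    spec: PredictorSpec | None = None
    _design: tuple | None = field(default=None, repr=False)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def aic(self) -> float:
        return fit_criteria_mixor(self.loglik, self.k, self.n_pairs)[0]

    @property
    def sbc(self) -> float:
        return fit_criteria_mixor(self.loglik, self.k, self.n_pairs)[1]

    @property
    def icc_mz(self) -> float:
        return icc(self.v_mz, self.link)

    @property
    def icc_dz(self) -> float:
        return icc(self.v_dz, self.link)


def icc(v: float, link: str = "probit") -> float:
    """Residual intraclass correlation v / (v + residual variance)."""
    if v < 0:
        raise ValueError("random-effect variance must be >= 0")
    resid = 1.0 if link == "probit" else np.pi**2 / 3.0
    return v / (v + resid)


def fit_criteria_mixor(loglik: float, k: int, n_clusters: int) -> tuple[float, float]:
    """(AIC, SBC) in the log-likelihood-minus-penalty reporting convention:
    AIC = logLik - k, SBC = logLik - (k/2) ln(n_clusters)."""
    if k < 0 or n_clusters < 1:
        raise ValueError("need k >= 0 and n_clusters >= 1")
    return loglik - k, loglik - 0.5 * k * np.log(n_clusters)


def lrt(fit_small, fit_big, df: int) -> tuple[float, int, float]:
    """Deviance difference of nested fits with a chi-square reference.

    Accepts fit objects (anything with ``.deviance``) or raw deviances.
    """
    dev_s = getattr(fit_small, "deviance", fit_small)
    dev_b = getattr(fit_big, "deviance", fit_big)
    delta = float(dev_s) - float(dev_b)
    if delta < -1e-6:
        raise ValueError("larger model has higher deviance; models not nested?")
    delta = max(delta, 0.0)
    return delta, df, float(chi2.sf(delta, df)) if df > 0 else 1.0


def nagelkerke(
    fit, reference_fit, n: int | None = None
) -> tuple[float, float]:
    """(Cox–Snell R², Nagelkerke R²) of ``fit`` against a nested reference.

    Accepts fits or raw deviances; ``n`` defaults to the number of
    individuals recorded on ``fit``.
    """
    dev_f = getattr(fit, "deviance", fit)
    dev_r = getattr(reference_fit, "deviance", reference_fit)
    if n is None:
        n = getattr(fit, "n_individuals", None)
    if n is None or n <= 0:
        raise ValueError("n must be a positive individual count")
    r2_cs = 1.0 - np.exp((dev_f - dev_r) / n)
    denom = 1.0 - np.exp(-dev_r / n)
    return float(r2_cs), float(r2_cs / denom)


def concordance(y: np.ndarray, score: np.ndarray) -> float:
    """Rank-based AUC with ties counted half."""
    y = np.asarray(y)
    if y.min() == y.max():
        raise DegenerateResponseError("outcome has a single level")
    ranks = rankdata(score)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc(fit: MixedProbitFit, cohort: pd.DataFrame, outcome: str = "ad") -> float:
    """Concordance of marginal (fixed-effects-only) predictions with the
    outcome; random effects are integrated out so ranking follows the
    linear predictor."""
    x, y, _, _ = _design(cohort, fit.spec, outcome)
    eta = x @ fit.params["est"].to_numpy()
    return concordance(y, eta)


# ---------------------------------------------------------------------------
# likelihood machinery


def _design(cohort: pd.DataFrame, spec: PredictorSpec, outcome: str):
    y = cohort[outcome].to_numpy(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    cols = [cohort[c].to_numpy(float) for c in spec.columns]
    x = np.column_stack([np.ones(len(cohort))] + cols)
    names = ["intercept"] + list(spec.columns)
    pair = cohort["pair"].to_numpy()
    is_mz = cohort["zygosity"].to_numpy() == "MZ"
    return x, y, names, (pair, is_mz)


def _cluster_arrays(x, y, pair, is_mz):
    """Pad clusters to two members; returns (eta-index matrix, sign, mask,
    mz flag per cluster)."""
    order = np.argsort(pair, kind="mergesort")
    pair_sorted = pair[order]
    uniq, start = np.unique(pair_sorted, return_index=True)
    n_clusters = len(uniq)
    idx = np.zeros((n_clusters, 2), int)
    mask = np.zeros((n_clusters, 2), bool)
    for j, s in enumerate(start):
        e = start[j + 1] if j + 1 < n_clusters else len(pair_sorted)
        members = order[s:e]
        idx[j, : len(members)] = members[:2]
        mask[j, : len(members)] = True
    mz = is_mz[idx[:, 0]]
    return idx, mask, mz


def _log_cdf(t, link):
    if link == "probit":
        return log_ndtr(t)
    return -np.logaddexp(0.0, -t)


def _dlog_cdf(t, link):
    # first and second derivatives of log F(t)
    if link == "probit":
        lam = np.exp(norm.logpdf(t) - log_ndtr(t))
        return lam, -lam * (t + lam)
    p = expit(-t)  # 1 - F
    return p, -expit(t) * p


class _MixedLikelihood:
    def __init__(self, x, y, idx, mask, mz, link, quad_points):
        self.x = x
        self.s = np.where(y > 0, 1.0, -1.0)
        self.idx = idx
        self.mask = mask.astype(float)
        self.mz = mz
        self.link = link
        nodes, weights = hermgauss(quad_points)
        self.nodes = nodes
        self.logw = np.log(weights)

    def _eta_s(self, beta):
        eta = self.x @ beta
        return eta[self.idx], self.s[self.idx]

    def loglik(self, beta, v_mz, v_dz):
        eta, s = self._eta_s(beta)
        m = self.mask
        v = np.where(self.mz, v_mz, v_dz)
        if np.any(v < 0):
            return -np.inf
        if np.all(v == 0):
            ll = (_log_cdf(s * eta, self.link) * m).sum()
            return float(ll)

        # adaptive GH: Newton for the per-cluster posterior mode
        u = np.zeros(len(v))
        v_safe = np.maximum(v, 1e-12)
        for _ in range(50):
            t = s * (eta + u[:, None])
            d1, d2 = _dlog_cdf(t, self.link)
            g1 = -u / v_safe + (s * d1 * m).sum(axis=1)
            g2 = -1.0 / v_safe + (d2 * m).sum(axis=1)
            step = g1 / g2
            step = np.clip(step, -5.0, 5.0)
            u = u - step
            if np.max(np.abs(step)) < 1e-10:
                break
        sigma = 1.0 / np.sqrt(-g2)
        pts = u[:, None] + np.sqrt(2.0) * sigma[:, None] * self.nodes[None, :]
        t = s[:, :, None] * (eta[:, :, None] + pts[:, None, :])
        g = (
            -(pts**2) / (2.0 * v_safe[:, None])
            + (_log_cdf(t, self.link) * m[:, :, None]).sum(axis=1)
        )
        log_integrand = self.logw[None, :] + self.nodes[None, :] ** 2 + g
        mx = log_integrand.max(axis=1)
        integral = np.exp(log_integrand - mx[:, None]).sum(axis=1)
        ll = (
            mx
            + np.log(integral)
            + np.log(np.sqrt(2.0) * sigma)
            - 0.5 * np.log(2.0 * np.pi * v_safe)
        )
        return float(ll.sum())


def fit_mixed_probit(
    cohort: pd.DataFrame,
    spec: PredictorSpec | None = None,
    outcome: str = "ad",
) -> MixedProbitFit:
    """Maximize the marginal likelihood of the pair-clustered binary model.

    Zygosity-specific random-intercept variances are parameterized on the
    log scale internally and reported as variances; incomplete pairs enter
    as one-member clusters.
    """
    spec = spec or PredictorSpec()
    x, y, names, (pair, is_mz) = _design(cohort, spec, outcome)
    if y.min() == y.max():
        raise DegenerateResponseError("outcome has a single level; nothing to fit")
    idx, mask, mz = _cluster_arrays(x, y, pair, is_mz)
    lik = _MixedLikelihood(x, y, idx, mask, mz, spec.link, spec.quad_points)
    n_clusters = len(mz)
    p = x.shape[1]

    # independent-observation fit for starting values (also the v=0 fit)
    def nll0(beta):
        return -lik.loglik(beta, 0.0, 0.0)

    res0 = minimize(nll0, np.zeros(p), method="BFGS", options={"gtol": 1e-10, "maxiter": 500})

    if spec.random == "none":
        se = np.sqrt(np.diag(res0.hess_inv))
        est = res0.x
        zval = est / se
        tbl = pd.DataFrame(
            {"est": est, "se": se, "z": zval, "p": 2 * norm.sf(np.abs(zval))}, index=names
        )
        return MixedProbitFit(
            params=tbl,
            v_mz=0.0,
            v_dz=0.0,
            se_v_mz=np.nan,
            se_v_dz=np.nan,
            loglik=-res0.fun,
            k=p,
            n_individuals=len(y),
            n_pairs=n_clusters,
            link=spec.link,
            converged=bool(res0.success),
            message=res0.message,
            spec=spec,
            _design=(x, y),
        )

    def nll(theta):
        beta = theta[:p]
        v_mz_, v_dz_ = np.exp(theta[p]), np.exp(theta[p + 1])
        val = lik.loglik(beta, v_mz_, v_dz_)
        return -val if np.isfinite(val) else 1e12

    theta0 = np.concatenate([res0.x, [np.log(0.5), np.log(0.5)]])
    res = minimize(nll, theta0, method="BFGS", options={"gtol": 1e-7, "maxiter": 1000})
    if not res.success:  # one polish pass from the current point
        res = minimize(nll, res.x, method="Nelder-Mead", options={"maxiter": 4000, "fatol": 1e-10})
        res = minimize(nll, res.x, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})

    theta = res.x
    hess = _numeric_hessian(nll, theta)
    cov = _safe_inverse(hess)
    se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))

    est = theta[:p]
    se = se_all[:p]
    zval = np.divide(est, se, out=np.full(p, np.nan), where=se > 0)
    tbl = pd.DataFrame(
        {"est": est, "se": se, "z": zval, "p": 2 * norm.sf(np.abs(zval))}, index=names
    )
    v_mz_, v_dz_ = float(np.exp(theta[p])), float(np.exp(theta[p + 1]))
    return MixedProbitFit(
        params=tbl,
        v_mz=v_mz_,
        v_dz=v_dz_,
        se_v_mz=v_mz_ * se_all[p],  # delta method from log-variance
        se_v_dz=v_dz_ * se_all[p + 1],
        loglik=-res.fun,
        k=p + 2,
        n_individuals=len(y),
        n_pairs=n_clusters,
        link=spec.link,
        converged=bool(np.isfinite(res.fun)),
        message=str(res.message),
        spec=spec,
        _design=(x, y),
    )


def _numeric_hessian(f, x0, eps: float = 1e-4) -> np.ndarray:
    n = len(x0)
    h = np.zeros((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            xpp = x0.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x0.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x0.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x0.copy(); xmm[i] -= eps; xmm[j] -= eps
            h[i, j] = h[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps * eps)
    del f0
    return h


def _safe_inverse(h: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(h)
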