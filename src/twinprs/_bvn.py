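"""Vectorized bivariate normal probabilities.

Implemented through Owen's T function (:func:`scipy.special.owens_t`),
which is accurate to ~1e-14 and broadcasts over arrays.  All helpers accept
scalars or ndarrays and broadcast like ufuncs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "bvn_upper", "rectangle_prob"]

# |rho| beyond this is treated as perfect (anti-)correlation
_RHO_LIMIT = 1.0 - 1e-12
# |h| below this is nudged away from zero so the Owen T arguments stay finite
_H_TINY = 1e-12


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Broadcasts over ``h``, ``k`` and ``rho``.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    out = np.empty(h.shape, float)

    hi = rho >= _RHO_LIMIT
    lo = rho <= -_RHO_LIMIT
    mid = ~(hi | lo)

    if np.any(hi):  # comonotone: P = Phi(min(h, k))
        out[hi] = ndtr(np.minimum(h[hi], k[hi]))
    if np.any(lo):  # antithetic: P = max(0, Phi(h) + Phi(k) - 1)
        out[lo] = np.maximum(0.0, ndtr(h[lo]) + ndtr(k[lo]) - 1.0)
    if np.any(mid):
        out[mid] = _bvn_cdf_owen(h[mid], k[mid], rho[mid])

    if out.ndim == 0:
        return float(out)
    return out


def _bvn_cdf_owen(h, k, rho):
    # Owen (1956): Phi2 = (Phi(h)+Phi(k))/2 - T(h,ah) - T(k,ak) - delta,
    # delta = 1/2 when h and k fall on opposite sides of zero.
    h = np.where(np.abs(h) < _H_TINY, np.where(h < 0, -_H_TINY, _H_TINY), h)
    k = np.where(np.abs(k) < _H_TINY, np.where(k < 0, -_H_TINY, _H_TINY), k)
    root = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * root)
    ak = (h - rho * k) / (k * root)
    delta = np.where(h * k > 0, 0.0, 0.5)
    p = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - delta
    return np.clip(p, 0.0, 1.0)


def bvn_upper(h, k, rho):
    """P(X > h, Y > k) — the upper orthant probability."""
    return np.clip(1.0 - ndtr(h) - ndtr(k) + bvn_cdf(h, k, rho), 0.0, 1.0)


def rectangle_prob(y1, y2, m1, m2, sd1, sd2, rho):
    """Probability of the binary pair outcome under a liability threshold at 0.

    ``y1``/``y2`` are 0/1 indicators of the latent variables exceeding 0;
    the latents are bivariate normal with means ``m1``/``m2``, standard
    deviations ``sd1``/``sd2`` and correlation ``rho``.  Sign-flipping maps
    every outcome onto a single upper-orthant evaluation.
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    q1 = 2.0 * y1 - 1.0
    q2 = 2.0 * y2 - 1.0
    a1 = -np.asarray(m1, float) / np.asarray(sd1, float)
    a2 = -np.asarray(m2, float) / np.asarray(sd2, float)
    return bvn_upper(q1 * a1, q2 * a2, q1 * q2 * np.asarray(rho, float))
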