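"""Bivariate standard-normal probabilities.

Rectangle probabilities of the bivariate normal are the likelihood kernel of
tetrachoric/polychoric estimation, so they are evaluated with Owen's T
function (absolute accuracy ~1e-14) rather than generic numerical
integration.  All functions broadcast over numpy arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "bvn_pdf", "rect_prob", "rect_dprob_drho"]

_TINY = 1e-15


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Infinite limits are handled; |rho| = 1 falls back to the degenerate
    comonotone/antimonotone forms.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    out = np.empty(h.shape, dtype=float)

    neg_inf = np.isneginf(h) | np.isneginf(k)
    h_inf = np.isposinf(h)
    k_inf = np.isposinf(k)
    degenerate = np.abs(rho) >= 1.0 - 1e-14
    general = ~(neg_inf | h_inf | k_inf | degenerate)

    out[neg_inf] = 0.0
    out[h_inf & ~neg_inf] = ndtr(k[h_inf & ~neg_inf])
    out[k_inf & ~h_inf & ~neg_inf] = ndtr(h[k_inf & ~h_inf & ~neg_inf])

    deg = degenerate & ~neg_inf & ~h_inf & ~k_inf
    if np.any(deg):
        hp, kp, rp = h[deg], k[deg], rho[deg]
        pos = np.where(rp > 0, ndtr(np.minimum(hp, kp)),
                       np.maximum(0.0, ndtr(hp) + ndtr(kp) - 1.0))
        out[deg] = pos

    if np.any(general):
        hg = h[general]
        kg = k[general]
        rg = rho[general]
        # nudge exact zeros off the axis; the CDF is continuous there
        hg = np.where(hg == 0.0, _TINY, hg)
        kg = np.where(kg == 0.0, _TINY, kg)
        s = np.sqrt(1.0 - rg * rg)
        ah = (kg - rg * hg) / (hg * s)
        ak = (hg - rg * kg) / (kg * s)
        delta = np.where(hg * kg > 0, 0.0, np.where(hg + kg >= 0, 0.0, 0.5))
        # hk < 0 always carries the 1/2 correction
        delta = np.where(hg * kg < 0, 0.5, delta)
        val = (0.5 * (ndtr(hg) + ndtr(kg))
               - owens_t(hg, ah) - owens_t(kg, ak) - delta)
        out[general] = np.clip(val, 0.0, 1.0)

    return out if out.ndim else float(out)


def bvn_pdf(x, y, rho):
    """Bivariate standard-normal density; zero at infinite arguments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = np.asarray(rho, dtype=float)
    x, y, rho = np.broadcast_arrays(x, y, rho)
    finite = np.isfinite(x) & np.isfinite(y)
    out = np.zeros(x.shape, dtype=float)
    if np.any(finite):
        xf, yf, rf = x[finite], y[finite], rho[finite]
        om = 1.0 - rf * rf
        z = (xf * xf - 2.0 * rf * xf * yf + yf * yf) / om
        out[finite] = np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(om))
    return out if out.ndim else float(out)


def rect_prob(a_lo, a_hi, b_lo, b_hi, rho):
    """P(a_lo < X <= a_hi, b_lo < Y <= b_hi)."""
    p = (bvn_cdf(a_hi, b_hi, rho) - bvn_cdf(a_lo, b_hi, rho)
         - bvn_cdf(a_hi, b_lo, rho) + bvn_cdf(a_lo, b_lo, rho))
    return np.clip(p, 0.0, 1.0)


def rect_dprob_drho(a_lo, a_hi, b_lo, b_hi, rho):
    """d/d rho of the rectangle probability (Plackett's identity)."""
    return (bvn_pdf(a_hi, b_hi, rho) - bvn_pdf(a_lo, b_hi, rho)
            - bvn_pdf(a_hi, b_lo, rho) + bvn_pdf(a_lo, b_lo, rho))
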