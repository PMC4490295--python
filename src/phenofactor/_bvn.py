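"""Bivariate standard-normal CDF and ordinal cell probabilities.

The polychoric/polyserial likelihoods need rectangle probabilities of a
bivariate standard normal at many threshold corners for a single
correlation.  We evaluate the CDF through Owen's T function
(scipy.special.owens_t), which is vectorised over the corners:

    Phi2(h, k; rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - beta

with a_h = (k - rho*h) / (h * sqrt(1 - rho^2)), a_k symmetric, and
beta = 1/2 when h*k < 0 (or when one argument is 0 and the other
negative).  Exact zeros are nudged to +1e-13 — the CDF is continuous so
the error is far below the accuracy of the T evaluation, and the nudge
reproduces the sign rule for the h*k = 0 corner cases.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

# beyond |8.5| the univariate normal mass is < 1e-17; clipping keeps the
# Owen decomposition finite for infinite thresholds
_CLIP = 8.5


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    ``h`` and ``k`` broadcast; ``rho`` is scalar and clipped to
    (-0.9999, 0.9999).
    """
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    h, k = np.broadcast_arrays(h, k)
    rho = float(np.clip(rho, -0.9999, 0.9999))
    if abs(rho) < 1e-14:
        return ndtr(h) * ndtr(k)
    h = np.where(h == 0.0, 1e-13, h)
    k = np.where(k == 0.0, 1e-13, k)
    s = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * s)
    ak = (h - rho * k) / (k * s)
    beta = np.where(h * k < 0.0, 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - beta
    return np.clip(out, 0.0, 1.0)


def cell_probabilities(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Probability of each cell of the two-way ordinal table.

    ``tau_x`` (len Kx-1) and ``tau_y`` (len Ky-1) are strictly increasing
    thresholds on the standard-normal scale; returns a (Kx, Ky) matrix of
    bivariate-normal rectangle probabilities at correlation ``rho``.
    """
    hx = np.concatenate(([-np.inf], np.asarray(tau_x, float), [np.inf]))
    hy = np.concatenate(([-np.inf], np.asarray(tau_y, float), [np.inf]))
    F = bvn_cdf(hx[:, None], hy[None, :], rho)
    P = np.diff(np.diff(F, axis=0), axis=1)
    return np.clip(P, 0.0, 1.0)
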