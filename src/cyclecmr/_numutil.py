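"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np


def expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function at ``x``."""
    x = np.asarray(x, dtype=float)
    k = x.size
    H = np.empty((k, k))
    step = eps * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            hi, hj = step[i], step[j]
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += hi
                xm[i] -= hi
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / hi**2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [hi, hj]
                xpm[i] += hi
                xpm[j] -= hj
                xmp[i] -= hi
                xmp[j] += hj
                xmm[[i, j]] -= [hi, hj]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * hi * hj)
    return H


def safe_vcov(hessian: np.ndarray) -> np.ndarray:
    """Invert a Hessian of a negative log-likelihood, tolerating near-singularity."""
    try:
        return np.linalg.inv(hessian)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(hessian)


def wald_ci_from_link(est_link: float, se_link: float, inv_link) -> tuple[float, float]:
    lo = inv_link(est_link - 1.96 * se_link)
    hi = inv_link(est_link + 1.96 * se_link)
    return float(lo), float(hi)
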