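"""Numba kernels for the latent-variable Gibbs scans.

The spatial probit's latent field must be updated one site at a time
(each conditional depends on the freshly updated neighbours), which is a
tight sequential loop — hence the jit.  Truncated-normal draws use naive
rejection near the bulk and Robert's (1995) shifted-exponential rejection
in the tail; both are exact samplers.

The kernels draw from numba's internal np.random state; call
:func:`seed_kernels` before a sampling run to make draw streams
reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_kernels(seed):
    np.random.seed(seed)


@njit(cache=True)
def _std_truncnorm_lower(a):
    """Draw z ~ N(0,1) conditioned on z > a."""
    if a < 0.45:
        while True:
            z = np.random.normal()
            if z > a:
                return z
    else:
        alpha = 0.5 * (a + np.sqrt(a * a + 4.0))
        while True:
            z = a - np.log(np.random.random()) / alpha
            if np.random.random() <= np.exp(-0.5 * (z - alpha) ** 2):
                return z


@njit(cache=True)
def truncnorm_lower(mu, sigma, lower):
    """Draw from N(mu, sigma^2) truncated to (lower, inf)."""
    return mu + sigma * _std_truncnorm_lower((lower - mu) / sigma)


@njit(cache=True)
def truncnorm_upper(mu, sigma, upper):
    """Draw from N(mu, sigma^2) truncated to (-inf, upper)."""
    return mu - sigma * _std_truncnorm_lower((mu - upper) / sigma)


@njit(cache=True)
def latent_scan(ystar, P, b, y):
    """One systematic single-site Gibbs sweep over the latent field.

    The latent vector is multivariate normal with precision P and
    canonical mean b (i.e. mean P^{-1} b); site i's full conditional is
    normal with mean (b_i - sum_{j != i} P_ij ystar_j) / P_ii and variance
    1 / P_ii, truncated to (0, inf) when y_i = 1 and (-inf, 0] when
    y_i = 0.  Updates ``ystar`` in place, in fixed index order.
    """
    n = ystar.shape[0]
    for i in range(n):
        Pii = P[i, i]
        acc = 0.0
        for j in range(n):
            acc += P[i, j] * ystar[j]
        acc -= Pii * ystar[i]
        m = (b[i] - acc) / Pii
        s = 1.0 / np.sqrt(Pii)
        if y[i] == 1:
            ystar[i] = truncnorm_lower(m, s, 0.0)
        else:
            ystar[i] = truncnorm_upper(m, s, 0.0)
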