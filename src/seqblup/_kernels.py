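"""Numba kernels for the Gibbs samplers.

The marker-effect sweeps are the hot loop of the samplers (markers x
iterations, each touching every training animal), so they are compiled.
Design matrices are expected in Fortran order so column access is
contiguous.  The kernels use numba's own random state; call :func:`seed_rng`
once per chain before the first sweep.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_rng", "sweep_component", "sweep_component_mt"]


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False, fastmath=True)
def sweep_component(Z, zsq, e, beta, u, s2c, s2e):
    """One Gibbs sweep over a single-trait effect component.

    For each marker, samples its effect from the normal full conditional
    given the current residuals, then updates the residual vector ``e`` and
    the component genetic values ``u`` in place.
    """
    n, p = Z.shape
    lam = s2e / s2c
    for m in range(p):
        old = beta[m]
        rhs = zsq[m] * old
        for i in range(n):
            rhs += Z[i, m] * e[i]
        c = zsq[m] + lam
        mean = rhs / c
        sd = np.sqrt(s2e / c)
        new = mean + sd * np.random.standard_normal()
        d = new - old
        beta[m] = new
        for i in range(n):
            e[i] -= Z[i, m] * d
            u[i] += Z[i, m] * d


@njit(cache=False, fastmath=True)
def _chol_small(a, lo):
    """Cholesky of a small SPD matrix into ``lo`` (lower). Returns 0 on failure."""
    b = a.shape[0]
    for i in range(b):
        for j in range(b):
            lo[i, j] = 0.0
    for i in range(b):
        for j in range(i + 1):
            s = a[i, j]
            for k in range(j):
                s -= lo[i, k] * lo[j, k]
            if i == j:
                if s <= 0.0:
                    return 0
                lo[i, i] = np.sqrt(s)
            else:
                lo[i, j] = s / lo[j, j]
    return 1


@njit(cache=False, fastmath=True)
def sweep_component_mt(Z, zsq_b, e, eff, u, sigma_inv, s2e_b, starts):
    """One Gibbs sweep over a multi-trait (per-breed effects) component.

    Animals are sorted by breed with block boundaries in ``starts`` (length
    n_breeds + 1).  ``eff`` is (p, B); for each marker the B effects are
    sampled jointly from their multivariate-normal full conditional given
    the across-breed effect covariance (``sigma_inv`` is its inverse).
    Returns 1, or 0 if a conditional precision matrix was not positive
    definite (caller aborts with diagnostics).
    """
    n, p = Z.shape
    nb = starts.shape[0] - 1
    prec = np.empty((nb, nb))
    lo = np.empty((nb, nb))
    rhs = np.empty(nb)
    tmp = np.empty(nb)
    mean = np.empty(nb)
    dev = np.empty(nb)
    for m in range(p):
        for j in range(nb):
            for k in range(nb):
                prec[j, k] = sigma_inv[j, k]
        for j in range(nb):
            s, t = starts[j], starts[j + 1]
            dot = 0.0
            for i in range(s, t):
                dot += Z[i, m] * e[i]
            rhs[j] = (dot + zsq_b[j, m] * eff[m, j]) / s2e_b[j]
            prec[j, j] += zsq_b[j, m] / s2e_b[j]
        if _chol_small(prec, lo) == 0:
            return 0
        # mean = prec^-1 rhs via forward + back substitution
        for j in range(nb):
            s = rhs[j]
            for k in range(j):
                s -= lo[j, k] * tmp[k]
            tmp[j] = s / lo[j, j]
        for j in range(nb - 1, -1, -1):
            s = tmp[j]
            for k in range(j + 1, nb):
                s -= lo[k, j] * mean[k]
            mean[j] = s / lo[j, j]
        # deviation with covariance prec^-1: solve L' dev = z
        for j in range(nb):
            tmp[j] = np.random.standard_normal()
        for j in range(nb - 1, -1, -1):
            s = tmp[j]
            for k in range(j + 1, nb):
                s -= lo[k, j] * dev[k]
            dev[j] = s / lo[j, j]
        for j in range(nb):
            new = mean[j] + dev[j]
            d = new - eff[m, j]
            eff[m, j] = new
            s, t = starts[j], starts[j + 1]
            for i in range(s, t):
                e[i] -= Z[i, m] * d
                u[i] += Z[i, m] * d
    return 1
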