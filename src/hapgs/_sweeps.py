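"""Single-site Gibbs sweep kernels shared by the whole-genome regressions.

Each kernel sweeps once over the columns of a regressor matrix, updating
the coefficient vector and the running residual in place.  All random
variates are drawn OUTSIDE the kernels from a seeded numpy Generator and
passed in as arrays, so chains are bit-identical for a given seed
regardless of compilation.  ``Z`` should be Fortran-ordered for contiguous
column access.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_normal(Z, zsq, resid, m, prior_prec, sigma2_e, normals):
    """One sweep of normal full-conditional updates.

    prior_prec[j] = sigma2_e / prior_var_j (0 => flat prior).  The full
    conditional of m_j is N(rhs/c, sigma2_e/c) with c = z_j'z_j +
    prior_prec_j and rhs = z_j' (resid + z_j m_j).
    """
    n, p = Z.shape
    for j in range(p):
        c = zsq[j] + prior_prec[j]
        if c <= 0.0:
            continue
        rhs = zsq[j] * m[j]
        for i in range(n):
            rhs += Z[i, j] * resid[i]
        mu = rhs / c
        new = mu + normals[j] * np.sqrt(sigma2_e / c)
        diff = new - m[j]
        if diff != 0.0:
            for i in range(n):
                resid[i] -= Z[i, j] * diff
        m[j] = new


@njit(cache=True)
def sweep_spike_slab(Z, zsq, resid, m, delta, slab_var, sigma2_e,
                     log_prior_odds, normals, uniforms):
    """Joint indicator-and-effect update for the zero-mixture models.

    slab_var[j] is the prior variance of an included effect;
    log_prior_odds = log((1-pi)/pi).  Returns the number of included
    markers after the sweep.
    """
    n, p = Z.shape
    k = 0
    for j in range(p):
        if zsq[j] <= 0.0 or slab_var[j] <= 0.0:
            if m[j] != 0.0:
                for i in range(n):
                    resid[i] += Z[i, j] * m[j]
                m[j] = 0.0
            delta[j] = 0
            continue
        u = zsq[j] * m[j]
        for i in range(n):
            u += Z[i, j] * resid[i]
        v0 = zsq[j] * sigma2_e
        v1 = zsq[j] * zsq[j] * slab_var[j] + v0
        lbf = 0.5 * (np.log(v0) - np.log(v1)) + 0.5 * u * u * (1.0 / v0 - 1.0 / v1)
        lo = log_prior_odds + lbf
        if lo > 35.0:
            p_incl = 1.0
        elif lo < -35.0:
            p_incl = 0.0
        else:
            p_incl = 1.0 / (1.0 + np.exp(-lo))
        if uniforms[j] < p_incl:
            c = zsq[j] + sigma2_e / slab_var[j]
            new = u / c + normals[j] * np.sqrt(sigma2_e / c)
            delta[j] = 1
            k += 1
        else:
            new = 0.0
            delta[j] = 0
        diff = new - m[j]
        if diff != 0.0:
            for i in range(n):
                resid[i] -= Z[i, j] * diff
        m[j] = new
    return k
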