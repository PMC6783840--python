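"""Pedigree relationship machinery and the Bayesian animal model.

The additive (numerator) relationship matrix A holds Wright's coefficients
of relationship; its sparse inverse is assembled directly from the pedigree
by Henderson's rules with inbreeding coefficients from the tabular A.  The
animal model

    y = X beta + Z a + e,   a ~ N(0, A sigma_a^2),   e ~ N(0, I sigma_e^2)

is fitted by Gibbs sampling: after the one-off eigendecomposition
A = U D U', the transformed effects alpha (a = U D^{1/2} alpha) are iid
N(0, sigma_a^2) and are updated with the same single-site normal sweep used
by the ridge regression sampler; variances get scaled-inverse-chi-squared
full conditionals.  Narrow-sense heritability h_a^2 = sigma_a^2 /
(sigma_a^2 + sigma_e^2) is evaluated per retained sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from hapgs._sweeps import sweep_normal
from hapgs.simulate import UNKNOWN

__all__ = [
    "AInverse",
    "McmcConfig",
    "FULL_MCMC",
    "PedigreeFit",
    "relationship_matrix",
    "build_a_inverse",
    "fit_animal_model",
]


@dataclass
class McmcConfig:
    """Gibbs settings.  Desk-scale defaults; FULL_MCMC has the full run."""

    iterations: int = 20_000
    burn_in: int = 2_000
    thin: int = 10

    def __post_init__(self):
        if self.iterations <= self.burn_in or self.thin < 1:
            raise ValueError("need iterations > burn_in and thin >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


FULL_MCMC = McmcConfig(iterations=1_000_000, burn_in=100_000, thin=50)


def _pedigree_indices(pedigree: pd.DataFrame):
    ids = list(pedigree.individual_id)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in pedigree")
    index = {iid: i for i, iid in enumerate(ids)}
    sires, dams = [], []
    for i, row in enumerate(pedigree.itertuples()):
        for pid, out in ((row.sire_id, sires), (row.dam_id, dams)):
            if pid == UNKNOWN:
                out.append(-1)
            else:
                j = index.get(pid)
                if j is None:
                    raise ValueError(f"parent {pid} missing from pedigree")
                if j >= i:
                    raise ValueError(
                        f"parent {pid} does not precede offspring {row.individual_id}"
                    )
                out.append(j)
    return ids, np.array(sires), np.array(dams)


def relationship_matrix(pedigree: pd.DataFrame) -> tuple:
    """Wright's numerator relationship matrix A by the tabular method."""
    ids, s, d = _pedigree_indices(pedigree)
    n = len(ids)
    a = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        a[i, i] = 1.0 + (0.5 * a[si, di] if si >= 0 and di >= 0 else 0.0)
        for j in range(i):
            val = 0.0
            if si >= 0:
                val += 0.5 * a[j, si]
            if di >= 0:
                val += 0.5 * a[j, di]
            a[i, j] = a[j, i] = val
    return ids, a


@dataclass
class AInverse:
    """Sparse inverse of the numerator relationship matrix."""

    ids: list
    matrix: sparse.csr_matrix
    inbreeding: np.ndarray  # F coefficients, pedigree order


def build_a_inverse(pedigree: pd.DataFrame) -> AInverse:
    """Henderson's rules with inbreeding (F from the tabular A diagonal).

    Each individual i with parents s, d contributes alpha_i * w w' with
    w = (1, -1/2, -1/2) on (i, s, d) and alpha_i = 1 / (1/2 - (F_s+F_d)/4)
    when both parents are known, 1 / (3/4 - F_p/4) with one known parent,
    and 1 for founders.
    """
    ids, a = relationship_matrix(pedigree)
    _, s, d = _pedigree_indices(pedigree)
    f = np.diag(a) - 1.0
    n = len(ids)
    rows, cols, vals = [], [], []
    for i in range(n):
        si, di = s[i], d[i]
        known = [p for p in (si, di) if p >= 0]
        b = 0.5 if len(known) == 2 else (0.75 if len(known) == 1 else 1.0)
        b -= 0.25 * sum(f[p] for p in known)
        alpha = 1.0 / b
        entries = [(i, 1.0)] + [(p, -0.5) for p in known]
        for (r, wr) in entries:
            for (c, wc) in entries:
                rows.append(r)
                cols.append(c)
                vals.append(alpha * wr * wc)
    mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return AInverse(ids=ids, matrix=mat, inbreeding=f)


def _scaled_inv_chi2(rng, df: float, total_scale: float) -> float:
    """Draw sigma^2 from scaled-inv-chi2 with nu*S = total_scale."""
    return total_scale / rng.chisquare(df)


@dataclass
class PedigreeFit:
    ids: list  # pedigree order
    ebv_mean: np.ndarray  # posterior-mean EBV per pedigree individual
    samples: dict  # sigma2_a, sigma2_e, h2 (arrays), beta (S x B), ebv (S x n)
    h2_mean: float
    h2_cr90: tuple
    converged: bool = True
    rhat: float = field(default=np.nan)


def fit_animal_model(
    phenotypes: pd.DataFrame,
    trait: str,
    a_inverse: AInverse,
    mcmc: McmcConfig | None = None,
    seed=0,
    prior_df: float = 5.0,
) -> PedigreeFit:
    """Gibbs sampler for the pedigree animal model.

    ``phenotypes`` needs columns individual_id, design_block and ``trait``;
    every phenotyped individual must appear in the pedigree behind
    ``a_inverse``.  Block effects get flat priors; both variances get
    scaled-inverse-chi-squared priors with ``prior_df`` degrees of freedom
    and scale set so the prior mode equals half the phenotypic variance.
    Ordinal traits are fitted on the observed scores as Gaussian.
    """
    mcmc = mcmc or McmcConfig()
    rng = np.random.default_rng(seed)
    ids = a_inverse.ids
    index = {iid: i for i, iid in enumerate(ids)}
    df_ph = phenotypes.dropna(subset=[trait])
    missing = [i for i in df_ph.individual_id if i not in index]
    if missing:
        raise ValueError(f"phenotyped individuals not in pedigree: {missing[:5]}")
    rows = np.array([index[i] for i in df_ph.individual_id])
    y = df_ph[trait].to_numpy(dtype=float)
    blocks = df_ph.design_block.to_numpy()
    block_levels = np.unique(blocks)
    x = (blocks[:, None] == block_levels[None, :]).astype(float)

    n_ind = len(ids)
    a_dense = np.linalg.inv(a_inverse.matrix.toarray())
    evals, u = np.linalg.eigh(a_dense)
    if evals.min() <= 1e-10:
        raise ValueError("relationship matrix not positive definite")
    t = u * np.sqrt(evals)  # a = T alpha with alpha ~ N(0, sigma_a^2 I)
    w = np.asfortranarray(t[rows, :])
    x = np.asfortranarray(x)
    wsq = np.einsum("ij,ij->j", w, w)
    xsq = np.einsum("ij,ij->j", x, x)

    vy = y.var()
    if vy <= 0:
        raise ValueError("zero-variance phenotype")
    nu = prior_df
    s_scale = 0.5 * vy * (nu + 2.0) / nu  # prior mode = vy/2
    nu_s = nu * s_scale

    beta = np.zeros(x.shape[1])
    alpha = np.zeros(n_ind)
    sigma2_a, sigma2_e = vy / 2, vy / 2
    resid = y - x @ beta
    n_keep = mcmc.n_retained
    out = {
        "sigma2_a": np.empty(n_keep),
        "sigma2_e": np.empty(n_keep),
        "h2": np.empty(n_keep),
        "beta": np.empty((n_keep, x.shape[1])),
        "ebv": np.empty((n_keep, n_ind)),
    }
    kept = 0
    flat = np.zeros(x.shape[1])
    for it in range(mcmc.iterations):
        sweep_normal(x, xsq, resid, beta, flat, sigma2_e,
                     rng.standard_normal(x.shape[1]))
        prior_prec = np.full(n_ind, sigma2_e / sigma2_a)
        sweep_normal(w, wsq, resid, alpha, prior_prec, sigma2_e,
                     rng.standard_normal(n_ind))
        sigma2_a = _scaled_inv_chi2(rng, nu + n_ind, nu_s + alpha @ alpha)
        sigma2_e = _scaled_inv_chi2(rng, nu + len(y), nu_s + resid @ resid)
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and kept < n_keep:
            out["sigma2_a"][kept] = sigma2_a
            out["sigma2_e"][kept] = sigma2_e
            out["h2"][kept] = sigma2_a / (sigma2_a + sigma2_e)
            out["beta"][kept] = beta
            out["ebv"][kept] = t @ alpha
            kept += 1
    for k in out:
        out[k] = out[k][:kept]
    h2 = out["h2"]
    rhat = _split_rhat(h2)
    converged = bool(rhat < 1.2) if np.isfinite(rhat) else True
    if not converged:
        warnings.warn(f"animal model h2 split-Rhat {rhat:.2f} > 1.2", stacklevel=2)
    return PedigreeFit(
        ids=ids,
        ebv_mean=out["ebv"].mean(axis=0),
        samples=out,
        h2_mean=float(h2.mean()),
        h2_cr90=(float(np.quantile(h2, 0.05)), float(np.quantile(h2, 0.95))),
        converged=converged,
        rhat=float(rhat),
    )


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction on a single chain."""
    n = len(x) // 2
    if n < 2:
        return np.nan
    a, b = x[:n], x[n:2 * n]
    w_var = (a.var(ddof=1) + b.var(ddof=1)) / 2
    b_var = n * np.var([a.mean(), b.mean()], ddof=1)
    if w_var <= 0:
        return np.nan
    var_plus = (n - 1) / n * w_var + b_var / n
    return float(np.sqrt(var_plus / w_var))
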