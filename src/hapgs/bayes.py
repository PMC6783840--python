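"""Bayesian whole-genome regressions: BRR, Bayes A/B/Cpi, Bayesian LASSO.

All five models share the linear predictor

    y = X beta + Z m + e,   e ~ N(0, I sigma_e^2)

and differ only in the prior on the marker (or haplotype) effects m:

* BRR      m_i ~ N(0, sigma_m^2), common variance with a
           scaled-inverse-chi-squared prior (ridge-type shrinkage).
* Bayes A  m_i ~ N(0, sigma_mi^2) with per-marker scaled-inverse-chi-squared
           variances (marginally a scaled-t density).
* Bayes B  spike-and-slab: m_i = 0 with probability pi, else
           N(0, sigma_mi^2) with per-marker variances.
* Bayes C  spike-and-slab with a single common slab variance sigma_m^2
           (pi sampled from its Beta full conditional unless fixed: "Cpi").
* BL       double-exponential prior via the Park-Casella scale mixture:
           m_i | tau_i^2, sigma_e^2 ~ N(0, tau_i^2 sigma_e^2),
           tau_i^2 ~ Exp(rate lambda^2/2), lambda^2 ~ Gamma(phi1, phi2).

Genomic variance is evaluated per posterior draw from the column
frequencies p_i:

    BRR/BC:  sigma_g^2 = 2 sigma_m^2 sum_i p_i(1-p_i)
    BA/BB:   sigma_g^2 = 2 sum_i p_i(1-p_i) sigma_mi^2   (BB: excluded -> 0)
    BL:      sigma_g^2 = 2 sum_i tau_i^2 sigma_e^2 p_i(1-p_i)

Hyperparameter defaults follow the usual whole-genome-regression
convention: the prior apportions half the phenotypic variance to the
markers (R2 = 0.5) with 5 prior degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from hapgs._sweeps import sweep_normal, sweep_spike_slab
from hapgs.pedigree import McmcConfig, _scaled_inv_chi2

__all__ = [
    "MODELS",
    "ModelSpec",
    "PosteriorSamples",
    "GenomicFit",
    "fit_whole_regression",
    "genomic_variance",
    "heritability_posterior",
    "genetic_gain",
    "fit_genomic_model",
]

MODELS = ("BRR", "BA", "BB", "BC", "BL")


@dataclass
class ModelSpec:
    """Model choice plus hyperparameters and MCMC settings.

    ``nu_m``/``s_m`` are the scaled-inverse-chi-squared df/scale of the
    marker-variance prior (``s_m`` None = set from the data at fit time);
    ``pi`` is the mixture mass at zero for BB/BC (sampled from a Beta(1,1)
    full conditional unless ``pi_fixed``); ``phi1``/``phi2`` are the
    shape/rate of the Gamma prior on lambda^2 for BL (``phi2`` None = set
    from the data).  ``bl_printed_rate`` switches the BL mixing density
    from the Park-Casella Exp(lambda^2/2) to the plain Exp(lambda^2) rate.
    """

    model: str = "BRR"
    nu_m: float = 5.0
    s_m: float | None = None
    nu_e: float = 5.0
    s_e: float | None = None
    pi: float = 0.5
    pi_fixed: bool = False
    phi1: float = 1.1
    phi2: float | None = None
    r2_prior: float = 0.5
    bl_printed_rate: bool = False
    fix_sigma2_m: float | None = None  # hold the common marker variance fixed
    fix_sigma2_e: float | None = None  # hold the residual variance fixed
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie in (0,1)")
        for name in ("nu_m", "nu_e", "phi1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PosteriorSamples:
    model: str
    effects: np.ndarray  # S x p
    beta: np.ndarray  # S x q fixed effects
    sigma2_e: np.ndarray  # S
    sigma2_m: np.ndarray | None = None  # S (BRR/BC)
    sigma2_mi: np.ndarray | None = None  # S x p (BA/BB)
    tau2: np.ndarray | None = None  # S x p (BL)
    lambda2: np.ndarray | None = None  # S (BL)
    inclusion: np.ndarray | None = None  # S x p bool (BB/BC)
    pi: np.ndarray | None = None  # S (BB/BC)


def fit_whole_regression(y: np.ndarray, fixed_design: np.ndarray,
                         marker_design: np.ndarray, spec: ModelSpec,
                         seed=0) -> PosteriorSamples:
    """Gibbs sampler for one whole-genome regression.

    Rows of ``y``, ``fixed_design`` and ``marker_design`` must be aligned;
    missing phenotypes are dropped upstream.  Fixed effects get flat
    priors.  Returns thinned post-burn-in chains.
    """
    y = np.asarray(y, dtype=float)
    if y.var() <= 0:
        raise ValueError("zero-variance phenotype")
    x = np.asfortranarray(np.atleast_2d(fixed_design).astype(float))
    z = np.asfortranarray(np.asarray(marker_design, dtype=float))
    n, p = z.shape
    if x.shape[0] != n or len(y) != n:
        raise ValueError("misaligned y / fixed_design / marker_design")
    rng = np.random.default_rng(seed)
    mcmc = spec.mcmc
    vy = float(y.var())
    sum_var_z = float(z.var(axis=0).sum())
    if sum_var_z <= 0:
        raise ValueError("marker design has no variation")
    r2 = spec.r2_prior
    # prior mode of sigma_m^2 at the per-marker share of R2*Vy
    mode_m = r2 * vy / sum_var_z
    s_m = spec.s_m if spec.s_m is not None else mode_m * (spec.nu_m + 2) / spec.nu_m
    s_e = spec.s_e if spec.s_e is not None else (1 - r2) * vy * (spec.nu_e + 2) / spec.nu_e
    if spec.model in ("BB",):
        s_m = s_m / max(1.0 - spec.pi, 1e-3)

    xsq = np.einsum("ij,ij->j", x, x)
    zsq = np.einsum("ij,ij->j", z, z)
    beta = np.zeros(x.shape[1])
    m = np.zeros(p)
    delta = np.ones(p, dtype=np.int64)
    sigma2_e = spec.fix_sigma2_e if spec.fix_sigma2_e is not None else (1 - r2) * vy
    sigma2_m = spec.fix_sigma2_m if spec.fix_sigma2_m is not None else mode_m
    sigma2_mi = np.full(p, mode_m)
    lam0_sq = 2 * (1 - r2) / r2 * sum_var_z
    phi2 = spec.phi2 if spec.phi2 is not None else spec.phi1 / lam0_sq
    lambda2 = lam0_sq
    tau2 = np.full(p, mode_m / max(sigma2_e, 1e-12))
    pi_val = spec.pi
    resid = y.copy()

    n_keep = mcmc.n_retained
    out = PosteriorSamples(
        model=spec.model,
        effects=np.empty((n_keep, p)),
        beta=np.empty((n_keep, x.shape[1])),
        sigma2_e=np.empty(n_keep),
    )
    if spec.model in ("BRR", "BC"):
        out.sigma2_m = np.empty(n_keep)
    if spec.model in ("BA", "BB"):
        out.sigma2_mi = np.empty((n_keep, p))
    if spec.model in ("BB", "BC"):
        out.inclusion = np.empty((n_keep, p), dtype=bool)
        out.pi = np.empty(n_keep)
    if spec.model == "BL":
        out.tau2 = np.empty((n_keep, p))
        out.lambda2 = np.empty(n_keep)

    nu_e, nu_m = spec.nu_e, spec.nu_m
    kept = 0
    for it in range(mcmc.iterations):
        sweep_normal(x, xsq, resid, beta, np.zeros(x.shape[1]), sigma2_e,
                     rng.standard_normal(x.shape[1]))
        normals = rng.standard_normal(p)
        if spec.model == "BRR":
            sweep_normal(z, zsq, resid, m, np.full(p, sigma2_e / sigma2_m),
                         sigma2_e, normals)
            if spec.fix_sigma2_m is None:
                sigma2_m = _scaled_inv_chi2(rng, nu_m + p, nu_m * s_m + m @ m)
        elif spec.model == "BA":
            sweep_normal(z, zsq, resid, m, sigma2_e / sigma2_mi, sigma2_e, normals)
            sigma2_mi = (nu_m * s_m + m * m) / rng.chisquare(nu_m + 1, size=p)
        elif spec.model == "BL":
            sweep_normal(z, zsq, resid, m, 1.0 / tau2, sigma2_e, normals)
            # tau_i^2 prior Exp(rate = rate_mult * lambda^2):
            # Park-Casella rate_mult=1/2, printed form rate_mult=1
            rate_mult = 1.0 if spec.bl_printed_rate else 0.5
            c = 2.0 * rate_mult * lambda2
            mu_ig = np.sqrt(c * sigma2_e / np.maximum(m * m, 1e-30))
            inv_tau2 = _rinvgauss(rng, mu_ig, c)
            tau2 = 1.0 / np.maximum(inv_tau2, 1e-30)
            lambda2 = rng.gamma(spec.phi1 + p,
                                1.0 / (phi2 + rate_mult * tau2.sum()))
        else:  # BB / BC spike-and-slab
            slab = sigma2_mi if spec.model == "BB" else np.full(p, sigma2_m)
            log_odds = np.log((1 - pi_val) / pi_val)
            sweep_spike_slab(z, zsq, resid, m, delta, slab, sigma2_e, log_odds,
                             normals, rng.random(p))
            k = int(delta.sum())
            if spec.model == "BC":
                ss_incl = float(m @ m)
                sigma2_m = _scaled_inv_chi2(rng, nu_m + k, nu_m * s_m + ss_incl)
            else:
                inc = delta.astype(bool)
                sigma2_mi = np.empty(p)
                chi = rng.chisquare(nu_m + 1, size=p)
                chi0 = rng.chisquare(nu_m, size=p)
                sigma2_mi[inc] = (nu_m * s_m + m[inc] ** 2) / chi[inc]
                sigma2_mi[~inc] = nu_m * s_m / chi0[~inc]
            if not spec.pi_fixed:
                pi_val = rng.beta(1 + p - k, 1 + k)
                pi_val = min(max(pi_val, 1e-6), 1 - 1e-6)
        if spec.fix_sigma2_e is not None:
            sigma2_e = spec.fix_sigma2_e
        elif spec.model == "BL":
            ss = resid @ resid + float((m * m / tau2).sum())
            sigma2_e = _scaled_inv_chi2(rng, nu_e + n + p, nu_e * s_e + ss)
        else:
            sigma2_e = _scaled_inv_chi2(rng, nu_e + n, nu_e * s_e + resid @ resid)
        if not np.isfinite(sigma2_e) or sigma2_e > 1e12 * vy:
            raise FloatingPointError(
                f"divergent residual variance at iteration {it}: {sigma2_e}"
            )
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and kept < n_keep:
            out.effects[kept] = m
            out.beta[kept] = beta
            out.sigma2_e[kept] = sigma2_e
            if out.sigma2_m is not None:
                out.sigma2_m[kept] = sigma2_m
            if out.sigma2_mi is not None:
                out.sigma2_mi[kept] = sigma2_mi
            if out.inclusion is not None:
                out.inclusion[kept] = delta.astype(bool)
                out.pi[kept] = pi_val
            if out.tau2 is not None:
                out.tau2[kept] = tau2
                out.lambda2[kept] = lambda2
            kept += 1
    _truncate(out, kept)
    return out


def _truncate(out: PosteriorSamples, kept: int) -> None:
    for name in ("effects", "beta", "sigma2_e", "sigma2_m", "sigma2_mi",
                 "tau2", "lambda2", "inclusion", "pi"):
        v = getattr(out, name)
        if v is not None:
            setattr(out, name, v[:kept])


def _rinvgauss(rng: np.random.Generator, mu: np.ndarray,
               lam: float | np.ndarray) -> np.ndarray:
    """Inverse-Gaussian draws (Michael-Schucany-Haas)."""
    mu = np.asarray(mu, dtype=float)
    nu = rng.standard_normal(mu.shape)
    y = nu * nu
    x = mu + mu * mu * y / (2 * lam) - mu / (2 * lam) * np.sqrt(
        4 * mu * lam * y + mu * mu * y * y
    )
    u = rng.random(mu.shape)
    return np.where(u <= mu / (mu + x), x, mu * mu / np.maximum(x, 1e-300))


def genomic_variance(samples: PosteriorSamples, column_freqs: np.ndarray,
                     model: str | None = None) -> np.ndarray:
    """Per-draw genomic variance from the model-matched formula.

    ``column_freqs`` are the p_i recorded on the design-matrix columns.
    """
    model = model or samples.model
    if model != samples.model:
        raise ValueError(f"samples are from {samples.model}, not {model}")
    p = np.asarray(column_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("column frequencies must lie strictly in (0,1)")
    w = p * (1.0 - p)
    if model in ("BRR", "BC"):
        return 2.0 * samples.sigma2_m * w.sum()
    if model == "BA":
        return 2.0 * samples.sigma2_mi @ w
    if model == "BB":
        var_incl = samples.sigma2_mi * samples.inclusion
        return 2.0 * var_incl @ w
    if model == "BL":
        return 2.0 * (samples.tau2 * samples.sigma2_e[:, None]) @ w
    raise ValueError(f"unknown model {model}")


def heritability_posterior(sigma2_g: np.ndarray, sigma2_e: np.ndarray):
    """Per-draw h^2 = sigma_g^2/(sigma_g^2+sigma_e^2) with mean and 90% CR."""
    g = np.asarray(sigma2_g, dtype=float)
    e = np.asarray(sigma2_e, dtype=float)
    if g.shape != e.shape:
        raise ValueError("draw vectors must be aligned")
    if np.any(e <= 0) or np.any(g < 0):
        raise ValueError("variance draws must be positive")
    h2 = g / (g + e)
    return h2, {
        "mean": float(h2.mean()),
        "cr90": (float(np.quantile(h2, 0.05)), float(np.quantile(h2, 0.95))),
    }


def genetic_gain(breeding_value_means: np.ndarray, selection_fraction: float,
                 phenotypic_mean: float) -> float:
    """Percent genetic gain of truncation selection.

    GG = (mean BV of the selected top fraction - population mean BV) /
    phenotypic mean x 100, with n_sel = round(fraction x n).
    """
    if phenotypic_mean == 0:
        raise ValueError("phenotypic mean must be nonzero")
    if not 0.0 < selection_fraction <= 1.0:
        raise ValueError("selection_fraction must be in (0,1]")
    bv = np.asarray(breeding_value_means, dtype=float)
    n_sel = max(1, int(round(selection_fraction * len(bv))))
    sel = np.sort(bv)[::-1][:n_sel]
    return float((sel.mean() - bv.mean()) / phenotypic_mean * 100.0)


@dataclass
class GenomicFit:
    """Summaries of one whole-genome regression fit."""

    model: str
    gebv: np.ndarray  # posterior-mean marker part per individual
    samples: PosteriorSamples
    sigma2_g: np.ndarray  # per-draw genomic variance
    h2_draws: np.ndarray
    h2_mean: float
    h2_cr90: tuple
    gg: float | None


def fit_genomic_model(y, fixed_design, design, spec: ModelSpec, seed=0,
                      selection_fraction: float = 0.1006,
                      phenotypic_mean: float | None = None) -> GenomicFit:
    """Fit + genomic variance + heritability + genetic gain in one call.

    ``design`` is a DesignMatrix from :mod:`hapgs.encoding` (or any object
    with ``values`` and ``freqs``).  GEBV = Z times the posterior-mean
    effects.  GG uses the observed phenotypic mean unless given.
    """
    z = design.values
    freqs = design.freqs
    keep = (freqs > 0) & (freqs < 1)
    samples = fit_whole_regression(y, fixed_design, z, spec, seed=seed)
    gebv = z @ samples.effects.mean(axis=0)
    sub = _subset_samples(samples, keep)
    sigma2_g = genomic_variance(sub, freqs[keep])
    h2_draws, summ = heritability_posterior(sigma2_g, samples.sigma2_e)
    ybar = float(np.mean(y)) if phenotypic_mean is None else phenotypic_mean
    gg = genetic_gain(gebv, selection_fraction, ybar) if ybar != 0 else None
    return GenomicFit(
        model=spec.model, gebv=gebv, samples=samples, sigma2_g=sigma2_g,
        h2_draws=h2_draws, h2_mean=summ["mean"], h2_cr90=summ["cr90"], gg=gg,
    )


def _subset_samples(s: PosteriorSamples, keep: np.ndarray) -> PosteriorSamples:
    """Column-subset of per-marker chains (monomorphic columns contribute 0)."""
    if keep.all():
        return s
    return PosteriorSamples(
        model=s.model,
        effects=s.effects[:, keep],
        beta=s.beta,
        sigma2_e=s.sigma2_e,
        sigma2_m=s.sigma2_m,
        sigma2_mi=None if s.sigma2_mi is None else s.sigma2_mi[:, keep],
        tau2=None if s.tau2 is None else s.tau2[:, keep],
        lambda2=s.lambda2,
        inclusion=None if s.inclusion is None else s.inclusion[:, keep],
        pi=s.pi,
    )
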