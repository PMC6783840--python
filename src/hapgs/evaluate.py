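"""Model-comparison machinery: cross-validated predictive ability,
Tukey-Kramer letter groupings, credible-set significance and EBV-GEBV
regression.

Predictive ability (PA) is the Pearson correlation between the GEBVs of a
whole-data fit and the GEBVs predicted for held-out individuals by a model
trained on the remaining 90%, averaged over random-split cycles (100 in a
full run).  An alternative reference — phenotypes adjusted for fixed
effects — is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from hapgs.bayes import ModelSpec, fit_whole_regression

logger = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "ComparisonReport",
    "cross_validate",
    "compare_tukey_kramer",
    "credible_set_compare",
    "ebv_gebv_regression",
]


@dataclass
class CVResult:
    model: str
    marker_mode: str
    pa_cycles: np.ndarray
    n_cycles: int
    skipped: int

    @property
    def mean_pa(self) -> float:
        return float(self.pa_cycles.mean())

    @property
    def se_pa(self) -> float:
        return float(self.pa_cycles.std(ddof=1) / np.sqrt(len(self.pa_cycles)))


def cross_validate(y: np.ndarray, fixed_design: np.ndarray,
                   marker_design: np.ndarray, spec: ModelSpec,
                   marker_mode: str = "SNP", holdout_fraction: float = 0.1,
                   n_cycles: int = 100, seed=0,
                   reference: str = "gebv") -> CVResult:
    """Random-split cross-validated predictive ability.

    Each cycle holds out ``holdout_fraction`` of the individuals, fits the
    model on the rest, predicts held-out GEBVs as Z_val @ m_hat, and
    correlates them against the whole-data-fit GEBVs of the same
    individuals (``reference="gebv"``) or against their phenotypes adjusted
    for fixed effects (``reference="adjusted"``).  Per-cycle splits and
    sampler seeds derive from (seed, cycle), so any cycle is reproducible
    in isolation.  Cycles with zero variance in either vector are skipped
    and logged, never averaged in.
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0,1)")
    if reference not in ("gebv", "adjusted"):
        raise ValueError("reference must be 'gebv' or 'adjusted'")
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_val = max(1, int(round(holdout_fraction * n)))
    whole = fit_whole_regression(
        y, fixed_design, marker_design, spec,
        seed=np.random.SeedSequence([int(seed), 2**20]).generate_state(1)[0] % 2**31,
    )
    gebv_whole = marker_design @ whole.effects.mean(axis=0)
    adj = y - fixed_design @ whole.beta.mean(axis=0)

    pas = []
    skipped = 0
    for cycle in range(n_cycles):
        ss = np.random.SeedSequence([int(seed), cycle])
        rng = np.random.default_rng(ss)
        val = rng.choice(n, size=n_val, replace=False)
        train = np.setdiff1d(np.arange(n), val)
        fit_seed = int(ss.generate_state(2)[1] % 2**31)
        try:
            fit = fit_whole_regression(
                y[train], fixed_design[train], marker_design[train], spec,
                seed=fit_seed,
            )
        except (ValueError, FloatingPointError) as exc:
            logger.warning("cycle %d skipped: %s", cycle, exc)
            skipped += 1
            continue
        pred = marker_design[val] @ fit.effects.mean(axis=0)
        ref = gebv_whole[val] if reference == "gebv" else adj[val]
        if pred.std() == 0 or ref.std() == 0:
            logger.warning("cycle %d skipped: zero-variance fold", cycle)
            skipped += 1
            continue
        pas.append(float(np.corrcoef(ref, pred)[0, 1]))
    return CVResult(model=spec.model, marker_mode=marker_mode,
                    pa_cycles=np.array(pas), n_cycles=n_cycles, skipped=skipped)


@lru_cache(maxsize=256)
def _q_critical(p: float, k: int, df: int) -> float:
    """Studentized-range quantile (cached: the ppf is expensive)."""
    return float(stats.studentized_range.ppf(p, k, df))


@dataclass
class ComparisonReport:
    groups: list
    means: np.ndarray
    letters: list  # compact letter display, aligned with groups
    significant: np.ndarray  # pairwise boolean matrix
    q_critical: float
    alpha: float


def compare_tukey_kramer(pa_matrix, alpha: float = 0.01,
                         groups=None) -> ComparisonReport:
    """All-pairs Tukey-Kramer comparison with a compact letter display.

    ``pa_matrix`` is (cycles x groups) or a list of per-group sample
    arrays (unequal sizes allowed).  Group means are compared with
    studentized-range critical values on the pooled within-group variance;
    groups sharing a letter are not significantly different at ``alpha``.
    Letters are assigned greedily from the best (largest) mean.
    """
    if isinstance(pa_matrix, np.ndarray) and pa_matrix.ndim == 2:
        samples = [pa_matrix[:, j] for j in range(pa_matrix.shape[1])]
    else:
        samples = [np.asarray(s, dtype=float) for s in pa_matrix]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([len(s) for s in samples])
    if np.any(ns < 2):
        raise ValueError("need at least 2 observations per group")
    means = np.array([s.mean() for s in samples])
    df = int(ns.sum() - k)
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df
    qcrit = _q_critical(round(1.0 - alpha, 10), k, df)
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            sig[i, j] = sig[j, i] = abs(means[i] - means[j]) > qcrit * se
    order = np.argsort(-means)
    letter_sets: list[set] = []  # groups covered by each letter
    assigned = [set() for _ in range(k)]
    for g in order:
        placed = False
        for li, members in enumerate(letter_sets):
            if all(not sig[g, m] for m in members):
                members.add(g)
                assigned[g].add(li)
                placed = True
        if not placed:
            letter_sets.append({g})
            assigned[g].add(len(letter_sets) - 1)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["".join(sorted(alphabet[li] for li in assigned[g])) for g in range(k)]
    names = list(groups) if groups is not None else [f"g{j}" for j in range(k)]
    return ComparisonReport(groups=names, means=means, letters=letters,
                            significant=sig, q_critical=float(qcrit), alpha=alpha)


def credible_set_compare(genomic, pedigree, level: float = 0.90,
                         rule: str = "nonoverlap") -> bool:
    """Star flag: are two posterior summaries different at the given level?

    Inputs are either draw arrays or (low, high) interval bounds at
    ``level``.  Default rule flags significance when the two central
    credible intervals do not overlap; ``rule="exclusion"`` instead checks
    that each interval excludes the other's posterior median/midpoint.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0,1)")

    def interval(x):
        x = np.asarray(x, dtype=float).ravel()
        if len(x) == 2:  # already (low, high) bounds
            return float(x[0]), float(x[1]), float(x.mean())
        tail = (1.0 - level) / 2.0
        return (float(np.quantile(x, tail)), float(np.quantile(x, 1 - tail)),
                float(np.median(x)))

    lo_a, hi_a, mid_a = interval(genomic)
    lo_b, hi_b, mid_b = interval(pedigree)
    if rule == "nonoverlap":
        return bool(hi_a < lo_b or hi_b < lo_a)
    if rule == "exclusion":
        return bool((mid_b < lo_a or mid_b > hi_a) and (mid_a < lo_b or mid_a > hi_b))
    raise ValueError("rule must be 'nonoverlap' or 'exclusion'")


def ebv_gebv_regression(ebv: np.ndarray, gebv: np.ndarray) -> dict:
    """OLS regression of GEBV on EBV; returns slope, intercept and R^2."""
    ebv = np.asarray(ebv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if len(ebv) != len(gebv):
        raise ValueError("vectors must have equal length")
    if ebv.std() == 0 or gebv.std() == 0:
        raise ValueError("zero-variance input")
    res = stats.linregress(ebv, gebv)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2)}
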