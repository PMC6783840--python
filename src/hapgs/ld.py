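"""Pairwise linkage disequilibrium and Gabriel haplotype-block discovery.

Input genotypes are unphased 0/1/2 dosages, so two-locus haplotype
frequencies are estimated by EM over the 3x3 genotype table (only double
heterozygotes are phase-ambiguous).  From the fitted table the module
computes Lewontin's D' (|D| normalised by its maximum attainable magnitude
given the allele frequencies) and the squared allele-frequency correlation
r^2, bounds D' by one-sided likelihood-profile confidence limits, and
partitions chromosomes into haplotype blocks with the Gabriel
confidence-interval rules: a marker pair is in "strong LD" when the upper
D' bound reaches 0.98 and the lower bound at least 0.70, shows "strong
recombination" when the upper bound stays below 0.90, and a block is a
contiguous run whose informative pairs are overwhelmingly strong-LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LDUndefinedError",
    "TwoLocusTable",
    "LDStats",
    "HaploBlock",
    "LDExtent",
    "GabrielParams",
    "genotype_counts",
    "two_locus_loglik",
    "em_two_locus",
    "ld_stats",
    "dprime_confidence_bounds",
    "gabriel_blocks",
    "critical_r2",
    "critical_r2_from_values",
    "ld_decay_profile",
]


class LDUndefinedError(ValueError):
    """LD is undefined (monomorphic locus or zero marginal frequency)."""


@dataclass(frozen=True)
class TwoLocusTable:
    """Two-locus haplotype frequencies; allele 1 = reference (dosage 0)."""

    p_a1b1: float
    p_a1b2: float
    p_a2b1: float
    p_a2b2: float
    n_informative: int

    @property
    def p_a1(self) -> float:
        return self.p_a1b1 + self.p_a1b2

    @property
    def p_a2(self) -> float:
        return self.p_a2b1 + self.p_a2b2

    @property
    def p_b1(self) -> float:
        return self.p_a1b1 + self.p_a2b1

    @property
    def p_b2(self) -> float:
        return self.p_a1b2 + self.p_a2b2

    def freqs(self) -> np.ndarray:
        return np.array([self.p_a1b1, self.p_a1b2, self.p_a2b1, self.p_a2b2])


@dataclass(frozen=True)
class LDStats:
    D: float
    DMAX: float  # magnitude of the attainable extreme for the sign of D
    Dprime: float
    r2: float
    ci_low: float | None = None
    ci_high: float | None = None


def genotype_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """3x3 genotype-class counts over pairwise-complete individuals.

    Rows index dosage at locus A (count of allele 2), columns at locus B.
    Missing dosages are any values outside {0,1,2}.
    """
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    ok = np.isin(ga, (0, 1, 2)) & np.isin(gb, (0, 1, 2))
    n = np.zeros((3, 3), dtype=np.int64)
    np.add.at(n, (ga[ok].astype(int), gb[ok].astype(int)), 1)
    return n


# ordered haplotypes: 0=A1B1 1=A1B2 2=A2B1 3=A2B2; allele 2 is the dosage-counted one
_HAP_A2 = np.array([0, 0, 1, 1])
_HAP_B2 = np.array([0, 1, 0, 1])


def _genotype_probs(f: np.ndarray) -> np.ndarray:
    """P(3x3 genotype class) from haplotype freqs f[..., 4] under random union."""
    f = np.asarray(f, dtype=float)
    out_shape = f.shape[:-1] + (3, 3)
    p = np.zeros(out_shape)
    for h in range(4):
        for k in range(4):
            ia, ib = _HAP_A2[h] + _HAP_A2[k], _HAP_B2[h] + _HAP_B2[k]
            p[..., ia, ib] += f[..., h] * f[..., k]
    return p


def _loglik(counts: np.ndarray, f: np.ndarray) -> np.ndarray:
    p = _genotype_probs(f)
    lp = np.log(np.maximum(p, 1e-300))  # impossible classes get a huge penalty
    return (counts * lp).sum(axis=(-2, -1))


def two_locus_loglik(counts: np.ndarray, freqs: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table given haplotype
    frequencies (A1B1, A1B2, A2B1, A2B2) under random union of gametes."""
    return float(_loglik(np.asarray(counts, dtype=float),
                         np.asarray(freqs, dtype=float)))


def em_two_locus(ga, gb, tol: float = 1e-10, max_iter: int = 2000) -> TwoLocusTable:
    """EM estimate of the four two-locus haplotype frequencies.

    Maximises the multinomial likelihood of the observed 3x3 genotype table;
    only the double-heterozygote class has ambiguous phase, so the E step
    splits its haplotypes between the coupling pair (A1B1, A2B2) and the
    repulsion pair (A1B2, A2B1) in proportion to their current frequency
    products.  Initialised at linkage equilibrium; an all-double-het sample
    therefore stays at the D = 0 fixed point.
    """
    n = genotype_counts(ga, gb)
    ntot = n.sum()
    if ntot < 1:
        raise LDUndefinedError("no pairwise-complete individuals")
    # marginal allele-2 frequencies
    da = (n.sum(axis=1) * np.array([0, 1, 2])).sum() / (2 * ntot)
    db = (n.sum(axis=0) * np.array([0, 1, 2])).sum() / (2 * ntot)
    if da in (0.0, 1.0) or db in (0.0, 1.0):
        raise LDUndefinedError("monomorphic locus: LD undefined")
    f = np.array([(1 - da) * (1 - db), (1 - da) * db, da * (1 - db), da * db])
    # fixed haplotype counts from unambiguous classes
    base = np.zeros(4)
    base[0] = 2 * n[0, 0] + n[0, 1] + n[1, 0]
    base[1] = 2 * n[0, 2] + n[0, 1] + n[1, 2]
    base[2] = 2 * n[2, 0] + n[1, 0] + n[2, 1]
    base[3] = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    ndh = n[1, 1]
    for _ in range(max_iter):
        coup = f[0] * f[3]
        rep = f[1] * f[2]
        w = coup / (coup + rep) if coup + rep > 0 else 0.5
        e = base.copy()
        e[0] += ndh * w
        e[3] += ndh * w
        e[1] += ndh * (1 - w)
        e[2] += ndh * (1 - w)
        f_new = e / (2 * ntot)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return TwoLocusTable(*f, n_informative=int(ntot))


def ld_stats(t: TwoLocusTable) -> LDStats:
    """Lewontin's D, D' and the squared allele-frequency correlation r^2.

    D = pA1B1*pA2B2 - pA1B2*pA2B1; DMAX is min{pA1*pB1, pA2*pB2} when D < 0
    and min{pA1*pB2, pA2*pB1} when D >= 0 (its magnitude), so that
    D' = |D| / DMAX lies in [0, 1].  r^2 = D^2 / (pA1 pA2 pB1 pB2).
    """
    pa1, pa2, pb1, pb2 = t.p_a1, t.p_a2, t.p_b1, t.p_b2
    if min(pa1, pa2, pb1, pb2) <= 0:
        raise LDUndefinedError("zero marginal allele frequency")
    d = t.p_a1b1 * t.p_a2b2 - t.p_a1b2 * t.p_a2b1
    if d < 0:
        dmax = min(pa1 * pb1, pa2 * pb2)
    else:
        dmax = min(pa1 * pb2, pa2 * pb1)
    dprime = 0.0 if dmax == 0 else min(abs(d) / dmax, 1.0)
    r2 = min(d * d / (pa1 * pa2 * pb1 * pb2), 1.0)
    return LDStats(D=float(d), DMAX=float(dmax), Dprime=float(dprime), r2=float(r2))


def _freqs_at_dprime(dprime_grid: np.ndarray, pa1: float, pb1: float,
                     sign: int) -> np.ndarray:
    """Haplotype freqs f[g, 4] along a D' grid with marginals fixed."""
    pa2, pb2 = 1 - pa1, 1 - pb1
    dmax = min(pa1 * pb2, pa2 * pb1) if sign >= 0 else min(pa1 * pb1, pa2 * pb2)
    d = np.sign(sign if sign != 0 else 1) * dprime_grid * dmax
    f = np.empty((len(dprime_grid), 4))
    f[:, 0] = pa1 * pb1 + d
    f[:, 1] = pa1 * pb2 - d
    f[:, 2] = pa2 * pb1 - d
    f[:, 3] = pa2 * pb2 + d
    return np.clip(f, 0.0, 1.0)


def dprime_confidence_bounds(ga, gb, grid_step: float = 0.01,
                             alpha_tail: float = 0.05) -> tuple:
    """One-sided likelihood-support bounds on D' (Gabriel/Haploview scheme).

    The multinomial likelihood of the observed 3x3 genotype table is
    profiled over D' in [0,1] on a grid, with allele frequencies plugged in
    at their MLEs and D taking the sign of the EM estimate.  The normalised
    likelihood is treated as a unit mass; ci_low is the smallest grid value
    with cumulative mass >= alpha_tail, ci_high the smallest with cumulative
    mass >= 1 - alpha_tail.
    """
    t = em_two_locus(ga, gb)
    stats = ld_stats(t)
    sign = 1 if stats.D >= 0 else -1
    counts = genotype_counts(ga, gb)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    f = _freqs_at_dprime(grid, t.p_a1, t.p_b1, sign)
    ll = _loglik(np.broadcast_to(counts, (len(grid), 3, 3)), f)
    mass = np.exp(ll - ll.max())
    mass /= mass.sum()
    cum = np.cumsum(mass)
    ci_low = float(grid[np.searchsorted(cum, alpha_tail)])
    ci_high = float(grid[np.searchsorted(cum, 1.0 - alpha_tail)])
    return ci_low, ci_high


@dataclass
class HaploBlock:
    """Contiguous marker run in strong LD, with its haplotype variants."""

    chromosome: int
    first: int  # marker index into the map (inclusive)
    last: int
    marker_ids: list
    span_bp: int
    n_snps: int
    variants: list = field(default_factory=list)  # (allele string, freq)


@dataclass
class GabrielParams:
    strong_ci_high: float = 0.98
    strong_ci_low: float = 0.70
    recomb_ci_high: float = 0.90
    informative_fraction: float = 0.95
    max_span_bp: int = 500_000
    min_informative_n: int = 20
    grid_step: float = 0.01


def _pair_class(ci_low, ci_high, p: GabrielParams) -> int:
    """2 = strong LD, 1 = strong recombination, 0 = uninformative."""
    if ci_high >= p.strong_ci_high and ci_low >= p.strong_ci_low:
        return 2
    if ci_high < p.recomb_ci_high:
        return 1
    return 0


def gabriel_blocks(genotypes: np.ndarray, marker_map: pd.DataFrame,
                   params: GabrielParams | None = None,
                   compute_variants: bool = True) -> list:
    """Partition each chromosome into Gabriel confidence-interval blocks.

    ``genotypes`` is (individuals x markers) 0/1/2 dosage (anything else =
    missing), columns aligned to ``marker_map``.  A candidate block [i..j]
    requires the endpoint pair to be strong-LD and >= the informative
    fraction (default 95%) of informative pairs inside to be strong-LD, with
    span <= max_span_bp.  The final set is chosen greedily, longest span
    first (leftmost on ties), without overlap.
    """
    p = params or GabrielParams()
    if genotypes.shape[1] == 0:
        return []
    chrom = marker_map.chromosome.to_numpy()
    pos = marker_map.position_bp.to_numpy()
    blocks: list[HaploBlock] = []
    for ch in np.unique(chrom):
        idx = np.flatnonzero(chrom == ch)
        m = len(idx)
        if m < 2:
            continue
        cls = np.zeros((m, m), dtype=np.int8)
        for a in range(m):
            for b in range(a + 1, m):
                if pos[idx[b]] - pos[idx[a]] > p.max_span_bp:
                    break
                ga, gb = genotypes[:, idx[a]], genotypes[:, idx[b]]
                ok = (np.isin(ga, (0, 1, 2)) & np.isin(gb, (0, 1, 2))).sum()
                if ok < p.min_informative_n:
                    continue
                try:
                    lo, hi = dprime_confidence_bounds(ga, gb, p.grid_step)
                except LDUndefinedError:
                    continue
                cls[a, b] = _pair_class(lo, hi, p)
        strong = (cls == 2).astype(np.int32)
        informative = (cls > 0).astype(np.int32)
        cs = strong.cumsum(0).cumsum(1)
        ci = informative.cumsum(0).cumsum(1)

        def boxsum(c, a, b):  # sum over rows a..b, cols a..b (upper triangle stored)
            tot = c[b, b]
            if a > 0:
                tot -= c[a - 1, b] + c[b, a - 1] - c[a - 1, a - 1]
            return tot

        cands = []
        for a in range(m):
            for b in range(a + 1, m):
                span = int(pos[idx[b]] - pos[idx[a]])
                if span > p.max_span_bp:
                    break
                if cls[a, b] != 2:
                    continue
                n_inf = boxsum(ci, a, b)
                if n_inf == 0:
                    continue
                if boxsum(cs, a, b) / n_inf >= p.informative_fraction:
                    cands.append((span, a, b))
        cands.sort(key=lambda t: (-t[0], t[1]))
        taken = np.zeros(m, bool)
        for span, a, b in cands:
            if taken[a:b + 1].any():
                continue
            taken[a:b + 1] = True
            blocks.append(HaploBlock(
                chromosome=int(ch), first=int(idx[a]), last=int(idx[b]),
                marker_ids=list(marker_map.marker_id.iloc[idx[a]:idx[b] + 1]),
                span_bp=span, n_snps=b - a + 1,
            ))
    blocks.sort(key=lambda blk: (blk.chromosome, blk.first))
    if compute_variants:
        from hapgs.encoding import em_block_haplotypes
        for blk in blocks:
            hs = em_block_haplotypes(genotypes[:, blk.first:blk.last + 1])
            blk.variants = [("".join(map(str, h)), f) for h, f in hs.variants]
    return blocks


def _pair_r2(genotypes: np.ndarray, i: int, j: int) -> float | None:
    try:
        return ld_stats(em_two_locus(genotypes[:, i], genotypes[:, j])).r2
    except LDUndefinedError:
        return None


def critical_r2_from_values(r2_values) -> float:
    """Critical r^2 from a sample of unlinked-pair r^2 values:
    the square of the empirical 95th percentile of sqrt(r^2)."""
    root = np.sqrt(np.asarray(r2_values, dtype=float))
    if root.size == 0:
        raise LDUndefinedError("no informative unlinked pairs")
    return float(np.quantile(root, 0.95) ** 2)


def critical_r2(genotypes: np.ndarray, marker_map: pd.DataFrame, seed=0,
                max_pairs: int = 10_000) -> float:
    """Breseghello-Sorrells critical r^2 from unlinked marker pairs.

    Takes inter-chromosomal (unlinked) pairs — all of them, or a seeded
    subsample of ``max_pairs`` when more exist — and returns the square of
    the 95th percentile of sqrt(r^2).  Intra-chromosomal mean r^2 above this
    value is taken to reflect genuine linkage.
    """
    chrom = marker_map.chromosome.to_numpy()
    if len(np.unique(chrom)) < 2:
        raise ValueError("critical r^2 needs markers on at least 2 chromosomes")
    m = len(chrom)
    rng = np.random.default_rng(seed)
    n_cross = sum(
        int(np.sum(chrom[i + 1:] != chrom[i])) for i in range(m - 1)
    )
    vals = []
    if n_cross <= max_pairs:
        for i in range(m - 1):
            for j in range(i + 1, m):
                if chrom[i] != chrom[j]:
                    r2 = _pair_r2(genotypes, i, j)
                    if r2 is not None:
                        vals.append(r2)
    else:
        seen = 0
        while seen < max_pairs:
            i, j = rng.integers(0, m, 2)
            if i == j or chrom[i] == chrom[j]:
                continue
            r2 = _pair_r2(genotypes, int(i), int(j))
            if r2 is not None:
                vals.append(r2)
            seen += 1
    return critical_r2_from_values(vals)


@dataclass
class LDExtent:
    critical_r2: float
    decay_table: list  # (bin midpoint bp, mean r2, n pairs)
    crossing_distance_bp: float | None


def ld_decay_profile(genotypes: np.ndarray, marker_map: pd.DataFrame,
                     bin_width_bp: int, max_dist_bp: int,
                     critical: float) -> LDExtent:
    """Mean intra-chromosomal r^2 per distance bin and the critical crossing.

    The crossing distance is the midpoint of the first bin whose 3-bin
    moving-average mean r^2 falls below ``critical`` (None when no bin
    crosses).
    """
    if bin_width_bp <= 0:
        raise ValueError("bin_width_bp must be positive")
    chrom = marker_map.chromosome.to_numpy()
    pos = marker_map.position_bp.to_numpy()
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for ch in np.unique(chrom):
        idx = np.flatnonzero(chrom == ch)
        for a in range(len(idx) - 1):
            for b in range(a + 1, len(idx)):
                d = pos[idx[b]] - pos[idx[a]]
                if d > max_dist_bp:
                    break
                r2 = _pair_r2(genotypes, int(idx[a]), int(idx[b]))
                if r2 is None:
                    continue
                k = min(int(d // bin_width_bp), n_bins - 1)
                sums[k] += r2
                counts[k] += 1
    if counts.sum() == 0:
        raise LDUndefinedError("no intra-chromosomal pairs within max_dist_bp")
    mids = (np.arange(n_bins) + 0.5) * bin_width_bp
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    crossing = None
    for k in range(n_bins):
        window = means[max(0, k - 1):k + 2]
        window = window[~np.isnan(window)]
        if len(window) and window.mean() < critical:
            crossing = float(mids[k])
            break
    table = [(float(mids[k]), float(means[k]) if counts[k] else None, int(counts[k]))
             for k in range(n_bins)]
    return LDExtent(critical_r2=float(critical), decay_table=table,
                    crossing_distance_bp=crossing)
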