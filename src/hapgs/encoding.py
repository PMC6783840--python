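"""Within-block phasing by multi-locus EM and SNP/HAP/HAP-SNP design matrices.

Each haplotype block (2-12 SNPs in the populations targeted here; hard cap
15 for enumeration safety) is phased by an EM over all haplotypes compatible
with the observed unphased genotypes.  Individuals are then assigned their
maximum-posterior diplotype and each haplotype variant becomes a 0/1/2
copy-count regressor: 0 for individuals carrying no copy of the variant, 1
for one copy, 2 for two copies.  Three regressor sets are built: SNP (all
SNP dosage columns, 2 = common-allele homozygote), HAP (one column per
retained haplotype variant across all blocks), and HAP-SNP (HAP columns
plus the dosage columns of every SNP not assigned to a block).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from hapgs.ld import HaploBlock

__all__ = [
    "BlockHaplotypeSet",
    "DesignColumn",
    "DesignMatrix",
    "em_block_haplotypes",
    "assign_diplotypes",
    "build_design",
]

MAX_BLOCK_SNPS = 15


@dataclass
class BlockHaplotypeSet:
    """EM haplotype variants and per-individual diplotypes for one block."""

    n_snps: int
    variants: list  # (tuple alleles, freq), sorted by descending frequency
    diplotypes: list  # per individual: (variant_idx, variant_idx) or None
    loglik: float


def _compatible_pairs(geno_row) -> list:
    """All unordered haplotype pairs consistent with one individual's dosages.

    Missing sites (dosage outside {0,1,2}) are marginalised: both alleles
    free on both haplotypes.  Haplotypes are tuples of 0/1 alleles.
    """
    k = len(geno_row)
    site_options = []
    for g in geno_row:
        if g == 0:
            site_options.append(((0, 0),))
        elif g == 2:
            site_options.append(((1, 1),))
        elif g == 1:
            site_options.append(((0, 1), (1, 0)))
        else:  # missing
            site_options.append(((0, 0), (0, 1), (1, 0), (1, 1)))
    pairs = set()
    for combo in product(*site_options):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(pairs)


def em_block_haplotypes(block_genotypes: np.ndarray, tol: float = 1e-8,
                        max_iter: int = 500) -> BlockHaplotypeSet:
    """Multi-locus EM haplotype frequencies for a single block.

    ``block_genotypes`` is (individuals x block SNPs) dosage.  The E step
    weights each individual's compatible diplotypes by the product of the
    current haplotype frequencies (doubled for heterodiplotypes); the M step
    renormalises expected haplotype counts.  Converges when the largest
    frequency change is below ``tol``.
    """
    g = np.asarray(block_genotypes)
    n, k = g.shape
    if k > MAX_BLOCK_SNPS:
        raise ValueError(
            f"block has {k} SNPs (> {MAX_BLOCK_SNPS}); split it before phasing"
        )
    per_ind = [_compatible_pairs(row) for row in g]
    haps = sorted({h for pairs in per_ind for pr in pairs for h in pr})
    hidx = {h: i for i, h in enumerate(haps)}
    nh = len(haps)
    freq = np.full(nh, 1.0 / nh)
    pair_idx = [
        np.array([(hidx[a], hidx[b]) for a, b in pairs], dtype=int)
        for pairs in per_ind
    ]
    loglik = -np.inf
    for _ in range(max_iter):
        counts = np.zeros(nh)
        ll = 0.0
        for pi in pair_idx:
            w = freq[pi[:, 0]] * freq[pi[:, 1]]
            w = np.where(pi[:, 0] != pi[:, 1], 2.0 * w, w)
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(w), 1.0 / len(w))
                tot = 1.0
            else:
                ll += np.log(tot)
                w = w / tot
            np.add.at(counts, pi[:, 0], w)
            np.add.at(counts, pi[:, 1], w)
        new = counts / (2 * n)
        delta = np.max(np.abs(new - freq))
        freq = new
        loglik = ll
        if delta < tol:
            break
    order = sorted(range(nh), key=lambda i: (-freq[i], haps[i]))
    remap = {old: new for new, old in enumerate(order)}
    variants = [(haps[i], float(freq[i])) for i in order]
    fr = freq.copy()
    diplos = []
    for pi in pair_idx:
        w = fr[pi[:, 0]] * fr[pi[:, 1]]
        w = np.where(pi[:, 0] != pi[:, 1], 2.0 * w, w)
        if w.sum() <= 0:
            best = 0  # all candidate haplotypes at zero frequency: first pair
        else:
            best = int(np.argmax(w))  # argmax: lexicographically smallest on ties
        a, b = remap[pi[best, 0]], remap[pi[best, 1]]
        diplos.append((min(a, b), max(a, b)))
    return BlockHaplotypeSet(n_snps=k, variants=variants, diplotypes=diplos,
                             loglik=float(loglik))


def assign_diplotypes(hs: BlockHaplotypeSet) -> np.ndarray:
    """Copy counts per haplotype variant from maximum-posterior diplotypes.

    Returns (individuals x variants) integer matrix: 0 = no copy of the
    variant, 1 = one copy, 2 = two copies.
    """
    nv = len(hs.variants)
    out = np.zeros((len(hs.diplotypes), nv), dtype=np.int8)
    for i, d in enumerate(hs.diplotypes):
        if d is None:
            continue
        a, b = d
        out[i, a] += 1
        out[i, b] += 1
    return out


@dataclass(frozen=True)
class DesignColumn:
    kind: str  # "snp" or "hap"
    source: object  # marker_id, or (block index, variant index)
    freq: float  # p_i, column mean / 2 — feeds the genomic-variance formulas


@dataclass
class DesignMatrix:
    ids: list
    values: np.ndarray  # individuals x columns, float
    columns: list  # DesignColumn

    @property
    def freqs(self) -> np.ndarray:
        return np.array([c.freq for c in self.columns])


def _orient_snp(dosage: np.ndarray) -> np.ndarray:
    """Recode so 2 = homozygote of the more frequent allele (NaN = missing)."""
    d = np.asarray(dosage, dtype=float)
    d = np.where(np.isin(d, (0, 1, 2)), d, np.nan)
    mean = np.nanmean(d)
    if mean < 1.0:  # allele 2 is the minor allele: flip
        d = 2.0 - d
    return d


def build_design(genotypes: np.ndarray, blocks: list, assignments: list,
                 mode: str, ids=None, variant_freq_min: float = 0.01,
                 impute: bool = True, marker_ids=None) -> DesignMatrix:
    """Assemble the SNP / HAP / HAP-SNP regressor matrix.

    ``blocks`` and ``assignments`` (copy-count matrices from
    :func:`assign_diplotypes`, one per block, aligned with
    ``BlockHaplotypeSet.variants``) may be empty for SNP mode.  Haplotype
    variants with EM frequency below ``variant_freq_min`` are dropped, so a
    block's retained copy codes sum to <= 2 per individual.  Missing values
    are mean-imputed per column when ``impute`` is on.  Every column records
    its frequency p_i = column mean / 2.
    """
    mode = mode.upper().replace("-", "_")
    if mode not in ("SNP", "HAP", "HAP_SNP"):
        raise ValueError(f"unknown design mode {mode!r}")
    n, m = genotypes.shape
    if ids is None:
        ids = list(range(n))
    if marker_ids is None:
        marker_ids = [f"snp{j}" for j in range(m)]
    in_block = np.zeros(m, bool)
    for blk in blocks:
        in_block[blk.first:blk.last + 1] = True

    cols, mats = [], []
    if mode in ("HAP", "HAP_SNP"):
        for bi, (blk, hs_counts) in enumerate(zip(blocks, assignments)):
            counts, variants = hs_counts
            for vi, (_, fr) in enumerate(variants):
                if fr < variant_freq_min:
                    continue
                cols.append(("hap", (bi, vi)))
                mats.append(counts[:, vi].astype(float))
    if mode == "SNP":
        snp_cols = range(m)
    elif mode == "HAP_SNP":
        snp_cols = np.flatnonzero(~in_block)
    else:
        snp_cols = []
    for j in snp_cols:
        cols.append(("snp", marker_ids[j]))
        mats.append(_orient_snp(genotypes[:, j]))
    if not mats:
        raise ValueError("design matrix has no columns")
    x = np.column_stack(mats)
    col_means = np.nanmean(x, axis=0)
    if impute:
        nan_r, nan_c = np.where(np.isnan(x))
        x[nan_r, nan_c] = col_means[nan_c]
    freqs = np.nanmean(x, axis=0) / 2.0
    columns = [DesignColumn(kind, src, float(f))
               for (kind, src), f in zip(cols, freqs)]
    return DesignMatrix(ids=list(ids), values=x, columns=columns)


def phase_blocks(genotypes: np.ndarray, blocks: list, tol: float = 1e-8):
    """Phase every block; returns the ``assignments`` input of build_design."""
    out = []
    for blk in blocks:
        hs = em_block_haplotypes(genotypes[:, blk.first:blk.last + 1], tol=tol)
        out.append((assign_diplotypes(hs), hs.variants))
    return out
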