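"""Synthetic breeding populations with block-structured LD and RCBD phenotypes.

The generator emulates a forest-tree progeny trial: a mix of half- and
full-sib families (~10 progeny each), unphased biallelic SNPs on several
chromosomes, discrete strong-LD haplotype blocks planted among otherwise
independent markers, and phenotypes laid out in a randomized complete block
design with single-tree plots.  Every stage keeps its simulation truth
(phase, QTL effects, breeding values, planted block boundaries) so
downstream estimators can be tested for parameter recovery.

Founder linkage disequilibrium is modelled as perfectly correlated marker
segments: each founder haplotype draws one variant per segment from a small
pool, and markers outside segments are independent Bernoulli draws.  Gametes
recombine by a Poisson crossover process at a fixed per-bp rate with no
interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = "UNKNOWN"

__all__ = [
    "UNKNOWN",
    "LDSegment",
    "FounderHaplotypeSpec",
    "PhasedGenotypes",
    "TraitTruth",
    "SimTruth",
    "make_marker_map",
    "simulate_pedigree",
    "make_founder_spec",
    "drop_genotypes",
    "simulate_phenotypes",
    "simulate_study",
    "STUDY_TRAITS",
]


def make_marker_map(
    n_chromosomes: int,
    n_markers: int,
    chromosome_length_bp: int,
    seed,
    weights=None,
) -> pd.DataFrame:
    """Scatter ``n_markers`` uniformly over chromosomes of equal length.

    Returns a marker map: DataFrame with columns ``marker_id``,
    ``chromosome`` (1-based), ``position_bp`` (1-based, strictly increasing
    within chromosome), sorted by (chromosome, position).  Markers are split
    evenly across chromosomes (counts differ by at most one) unless
    ``weights`` supplies per-chromosome proportions.
    """
    if n_chromosomes < 1 or n_markers < n_chromosomes:
        raise ValueError("need n_markers >= n_chromosomes >= 1")
    if chromosome_length_bp < n_markers:
        raise ValueError("chromosome_length_bp must be >= n_markers")
    rng = np.random.default_rng(seed)
    if weights is None:
        base, rem = divmod(n_markers, n_chromosomes)
        counts = np.full(n_chromosomes, base, dtype=int)
        counts[:rem] += 1
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != n_chromosomes or np.any(w <= 0):
            raise ValueError("weights must be positive, one per chromosome")
        counts = np.maximum(1, np.round(w / w.sum() * n_markers).astype(int))
        # adjust rounding drift onto the largest chromosome
        counts[np.argmax(counts)] += n_markers - counts.sum()
    rows = []
    for ch in range(1, n_chromosomes + 1):
        k = counts[ch - 1]
        pos = np.sort(rng.choice(chromosome_length_bp, size=k, replace=False) + 1)
        for p in pos:
            rows.append((ch, int(p)))
    df = pd.DataFrame(rows, columns=["chromosome", "position_bp"])
    df = df.sort_values(["chromosome", "position_bp"], kind="stable").reset_index(drop=True)
    df.insert(0, "marker_id", [f"chr{c}_{p}" for c, p in zip(df.chromosome, df.position_bp)])
    if df.marker_id.duplicated().any():  # ties in position: disambiguate
        df["marker_id"] = [f"m{i:06d}_{mid}" for i, mid in enumerate(df.marker_id)]
    return df


def simulate_pedigree(
    n_families: int,
    progeny_per_family: int,
    half_sib_fraction: float,
    n_founders: int,
    seed,
) -> pd.DataFrame:
    """Founder + progeny pedigree with full-sib and open-pollinated families.

    Each family has one dam; full-sib families additionally have one known
    sire, half-sib (open-pollinated) families record the sire as UNKNOWN.
    Columns: individual_id, sire_id, dam_id, family_id, generation.
    """
    if n_families < 1 or progeny_per_family < 1:
        raise ValueError("family counts must be positive")
    if not 0.0 <= half_sib_fraction <= 1.0:
        raise ValueError("half_sib_fraction must be in [0,1]")
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    founders = [f"F{i + 1:04d}" for i in range(n_founders)]
    n_dams = max(1, n_founders // 2)
    dams, sires = founders[:n_dams], founders[n_dams:] or founders[:1]
    is_half = rng.random(n_families) < half_sib_fraction
    rows = [(f, UNKNOWN, UNKNOWN, "FOUNDER", 0) for f in founders]
    k = 0
    for fam in range(n_families):
        dam = dams[fam % len(dams)]
        sire = UNKNOWN if is_half[fam] else sires[fam % len(sires)]
        for _ in range(progeny_per_family):
            k += 1
            rows.append((f"P{k:05d}", sire, dam, f"FAM{fam + 1:03d}", 1))
    return pd.DataFrame(
        rows, columns=["individual_id", "sire_id", "dam_id", "family_id", "generation"]
    )


@dataclass(frozen=True)
class LDSegment:
    """A run of contiguous markers whose founder alleles are drawn jointly.

    ``marker_indices`` are row indices into the marker map (contiguous,
    single chromosome).  ``variants`` lists (allele-vector, frequency) pairs
    over the segment's markers; frequencies sum to 1.  With the default two
    complementary variants every marker pair inside the segment has founder
    D' = r^2 = 1.
    """

    chromosome: int
    marker_indices: np.ndarray
    variants: tuple  # ((np.ndarray alleles, float freq), ...)

    def __post_init__(self):
        freqs = np.array([f for _, f in self.variants])
        if not np.isclose(freqs.sum(), 1.0):
            raise ValueError("segment variant frequencies must sum to 1")


@dataclass
class FounderHaplotypeSpec:
    """Founder haplotype distribution: planted LD segments + background freqs."""

    segments: list
    background_freq: np.ndarray  # allele-1 frequency per marker
    marker_map: pd.DataFrame

    def __post_init__(self):
        f = self.background_freq
        seg_idx = np.concatenate(
            [s.marker_indices for s in self.segments]
        ) if self.segments else np.array([], dtype=int)
        mask = np.ones(len(f), bool)
        mask[seg_idx] = False
        if np.any((f[mask] < 0.05) | (f[mask] > 0.95)):
            raise ValueError("background allele frequencies must lie in [0.05, 0.95]")
        for s in self.segments:
            for _, fr in s.variants:
                if not 0.05 <= fr <= 0.95:
                    raise ValueError("segment variant frequencies must lie in [0.05, 0.95]")

    def draw_haplotype(self, rng: np.random.Generator) -> np.ndarray:
        h = (rng.random(len(self.background_freq)) < self.background_freq).astype(np.uint8)
        for seg in self.segments:
            freqs = np.array([f for _, f in seg.variants])
            j = rng.choice(len(freqs), p=freqs)
            h[seg.marker_indices] = seg.variants[j][0]
        return h


def make_founder_spec(
    marker_map: pd.DataFrame,
    segment_bounds,
    seed,
    freq_range=(0.2, 0.8),
    segment_variants=None,
) -> FounderHaplotypeSpec:
    """Build a founder spec with planted perfect-LD segments.

    ``segment_bounds`` is a list of (first_idx, last_idx) inclusive marker
    index pairs (each within one chromosome).  By default each segment gets
    two complementary variants (all-1 with a drawn frequency, all-0 with the
    complement); ``segment_variants[k]`` may instead supply a list of
    (allele tuple, freq) pairs for multi-haplotype segments.
    """
    rng = np.random.default_rng(seed)
    chrom = marker_map.chromosome.to_numpy()
    segments = []
    for k, (i0, i1) in enumerate(segment_bounds):
        if chrom[i0] != chrom[i1]:
            raise ValueError("segment crosses a chromosome boundary")
        idx = np.arange(i0, i1 + 1)
        if segment_variants is not None and segment_variants[k] is not None:
            variants = tuple(
                (np.asarray(a, dtype=np.uint8), float(f)) for a, f in segment_variants[k]
            )
        else:
            f = float(rng.uniform(*freq_range))
            variants = (
                (np.ones(len(idx), np.uint8), f),
                (np.zeros(len(idx), np.uint8), 1.0 - f),
            )
        segments.append(LDSegment(int(chrom[i0]), idx, variants))
    bg = rng.uniform(*freq_range, size=len(marker_map))
    return FounderHaplotypeSpec(segments, bg, marker_map)


@dataclass
class PhasedGenotypes:
    """Phased haplotypes for a set of individuals, aligned to a marker map.

    ``haplotypes`` has shape (n_individuals, 2, n_markers) with alleles in
    {0,1}; summing the two haplotypes gives the 0/1/2 dosage.
    """

    ids: list
    haplotypes: np.ndarray
    marker_map: pd.DataFrame
    planted_segments: list = field(default_factory=list)

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(np.int8)

    def index_of(self, individual_id: str) -> int:
        return self.ids.index(individual_id)


def _gamete(hap_pair: np.ndarray, marker_map: pd.DataFrame, rate: float,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a (2, M) parental haplotype pair."""
    out = np.empty(hap_pair.shape[1], np.uint8)
    chrom = marker_map.chromosome.to_numpy()
    pos = marker_map.position_bp.to_numpy()
    for ch in np.unique(chrom):
        sel = chrom == ch
        p = pos[sel]
        length = p.max()
        n_x = rng.poisson(rate * length) if rate > 0 else 0
        start = rng.integers(2)
        if n_x == 0:
            out[sel] = hap_pair[start, sel]
            continue
        breaks = np.sort(rng.integers(1, length + 1, size=n_x))
        which = (start + np.searchsorted(breaks, p, side="left")) % 2
        idx = np.flatnonzero(sel)
        out[idx] = hap_pair[which, idx]
    return out


def drop_genotypes(
    pedigree: pd.DataFrame,
    marker_map: pd.DataFrame,
    founder_spec: FounderHaplotypeSpec,
    recomb_rate_per_bp: float = 1e-8,
    seed=0,
) -> PhasedGenotypes:
    """Gene-drop through the pedigree: founders from the spec, offspring by
    Poisson recombination of parental gametes.

    Unknown parents (open pollination) are modelled as unrecorded phantom
    founders drawn fresh from the founder spec for each offspring.  Mendelian
    consistency between recorded parents and offspring holds by construction.
    """
    rng = np.random.default_rng(seed)
    n_mark = len(marker_map)
    ids = list(pedigree.individual_id)
    index = {iid: i for i, iid in enumerate(ids)}
    haps = np.zeros((len(ids), 2, n_mark), np.uint8)

    def parent_gamete(pid: str) -> np.ndarray:
        if pid == UNKNOWN:
            phantom = np.stack(
                [founder_spec.draw_haplotype(rng), founder_spec.draw_haplotype(rng)]
            )
            return _gamete(phantom, marker_map, recomb_rate_per_bp, rng)
        if pid not in index:
            raise ValueError(f"parent {pid} not in pedigree")
        return _gamete(haps[index[pid]], marker_map, recomb_rate_per_bp, rng)

    for _, row in pedigree.iterrows():
        i = index[row.individual_id]
        if row.sire_id == UNKNOWN and row.dam_id == UNKNOWN and row.generation == 0:
            haps[i, 0] = founder_spec.draw_haplotype(rng)
            haps[i, 1] = founder_spec.draw_haplotype(rng)
        else:
            haps[i, 0] = parent_gamete(row.sire_id)
            haps[i, 1] = parent_gamete(row.dam_id)
    planted = [(int(s.marker_indices[0]), int(s.marker_indices[-1])) for s in founder_spec.segments]
    return PhasedGenotypes(ids, haps, marker_map, planted)


@dataclass
class TraitTruth:
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray  # aligned to phenotyped individuals
    target_h2: float
    realized_h2: float
    ordinal_levels: int | None
    ordinal_thresholds: np.ndarray | None


@dataclass
class SimTruth:
    """Ground truth of one simulated trial (parameter-recovery oracle)."""

    traits: dict
    phenotyped_ids: list
    block_effects: np.ndarray
    true_block_boundaries: list
    seed: object


# Study conditions: five traits with the trial's narrow-sense heritabilities;
# ST and BQ are ordinal scores (7- and 6-level scales).
STUDY_TRAITS = {
    "HT": (0.15, None),
    "DBH": (0.04, None),
    "ST": (0.06, 7),
    "BQ": (0.05, 6),
    "WD": (0.46, None),
}


def simulate_phenotypes(
    phased: PhasedGenotypes,
    pedigree: pd.DataFrame,
    n_qtl: int,
    target_h2,
    n_design_blocks: int = 30,
    block_sd: float = 1.0,
    ordinal_spec: dict | None = None,
    seed=0,
    trait_mean: float = 10.0,
):
    """RCBD phenotypes with additive QTL genetics at a target heritability.

    ``target_h2`` is a float (single trait named "trait") or a mapping
    trait-name -> h2.  ``ordinal_spec`` maps trait names to the number of
    ordinal levels; ordinal scores are produced by thresholding the latent
    continuous value at equal-probability empirical quantiles.

    The residual variance is solved from the realized breeding-value
    variance so that var(BV)/(var(BV)+var(resid)) hits the target exactly in
    expectation.  Heritability here excludes the design-block variance,
    matching the usual RCBD narrow-sense definition sigma_a^2 /
    (sigma_a^2 + sigma_e^2).

    Returns (PhenotypeTable DataFrame, SimTruth).  Only generation >= 1
    individuals (the trial progeny) are phenotyped; each family appears at
    most once per design block (single-tree plots).
    """
    if isinstance(target_h2, dict):
        h2map = dict(target_h2)
    else:
        h2map = {"trait": float(target_h2)}
    for name, h2 in h2map.items():
        if not 0.0 < h2 < 1.0:
            raise ValueError(f"target_h2 for {name} must be in (0,1)")
    ordinal_spec = ordinal_spec or {}
    n_mark = phased.haplotypes.shape[2]
    if n_qtl > n_mark:
        raise ValueError("n_qtl cannot exceed the number of markers")
    rng = np.random.default_rng(seed)

    prog = pedigree[pedigree.generation >= 1]
    ids = list(prog.individual_id)
    rows_idx = [phased.index_of(i) for i in ids]
    dos = phased.dosage()[rows_idx].astype(float)

    # RCBD: each family's trees land in distinct blocks
    blocks = np.empty(len(ids), int)
    for fam, grp in prog.groupby("family_id", sort=False):
        k = len(grp)
        if k > n_design_blocks:
            raise ValueError(f"family {fam} larger than the number of design blocks")
        chosen = rng.choice(n_design_blocks, size=k, replace=False) + 1
        blocks[[ids.index(i) for i in grp.individual_id]] = chosen
    block_eff = rng.normal(0.0, block_sd, size=n_design_blocks)

    table = pd.DataFrame({"individual_id": ids, "design_block": blocks})
    truths = {}
    for name, h2 in h2map.items():
        qtl = np.sort(rng.choice(n_mark, size=n_qtl, replace=False))
        eff = rng.normal(0.0, 1.0, size=n_qtl)
        bv = (dos[:, qtl] - dos[:, qtl].mean(axis=0)) @ eff
        var_bv = bv.var()
        if var_bv <= 0:
            raise ValueError("degenerate breeding values (all QTL monomorphic)")
        resid_sd = np.sqrt(var_bv * (1.0 - h2) / h2)
        resid = rng.normal(0.0, resid_sd, size=len(ids))
        latent = trait_mean + block_eff[blocks - 1] + bv + resid
        realized = var_bv / (var_bv + resid.var())
        levels = ordinal_spec.get(name)
        thresholds = None
        if levels is not None:
            qs = np.quantile(latent, np.linspace(0, 1, levels + 1)[1:-1])
            table[name] = np.searchsorted(qs, latent, side="right").astype(int)
            thresholds = qs
        else:
            table[name] = latent
        truths[name] = TraitTruth(qtl, eff, bv, h2, float(realized), levels, thresholds)

    truth = SimTruth(truths, ids, block_eff, list(phased.planted_segments), seed)
    return table, truth


def simulate_study(
    n_families: int = 65,
    progeny_per_family: int = 10,
    half_sib_fraction: float = 0.5,
    n_chromosomes: int = 11,
    n_markers: int = 14422,
    chromosome_length_bp: int = 40_000_000,
    n_segments: int = 110,
    segment_size_range=(2, 12),
    n_qtl: int = 100,
    traits=None,
    n_design_blocks: int = 30,
    recomb_rate_per_bp: float = 1e-8,
    seed=0,
):
    """One-call standard scenario mirroring the trial design.

    Defaults follow the study conditions: 65 families x 10 progeny (half of
    them open-pollinated), 11 chromosomes, 30 design blocks, planted LD
    segments of 2-12 SNPs, and the five traits in :data:`STUDY_TRAITS`.
    Returns a dict with marker_map, pedigree, phased, phenotypes, truth and
    the founder spec.
    """
    ss = np.random.SeedSequence(seed)
    s_map, s_ped, s_spec, s_drop, s_phen = [int(c.generate_state(1)[0] % 2**31)
                                            for c in ss.spawn(5)]
    traits = traits if traits is not None else STUDY_TRAITS
    mmap = make_marker_map(n_chromosomes, n_markers, chromosome_length_bp, s_map)
    ped = simulate_pedigree(
        n_families, progeny_per_family, half_sib_fraction, 2 * n_families, s_ped
    )
    rng = np.random.default_rng(s_spec)
    chrom = mmap.chromosome.to_numpy()
    bounds, used = [], np.zeros(len(mmap), bool)
    per_chr = {c: np.flatnonzero(chrom == c) for c in np.unique(chrom)}
    for _ in range(n_segments):
        c = rng.choice(list(per_chr))
        idx = per_chr[c]
        size = int(rng.integers(segment_size_range[0], segment_size_range[1] + 1))
        if len(idx) < size + 2:
            continue
        start = int(rng.integers(0, len(idx) - size))
        sel = idx[start:start + size]
        if used[max(0, sel[0] - 1):sel[-1] + 2].any():  # keep segments separated
            continue
        used[sel] = True
        bounds.append((int(sel[0]), int(sel[-1])))
    spec = make_founder_spec(mmap, bounds, s_spec)
    phased = drop_genotypes(ped, mmap, spec, recomb_rate_per_bp, s_drop)
    h2map = {k: v[0] for k, v in traits.items()}
    ordspec = {k: v[1] for k, v in traits.items() if v[1] is not None}
    phen, truth = simulate_phenotypes(
        phased, ped, n_qtl, h2map, n_design_blocks, 1.0, ordspec, s_phen
    )
    return {
        "marker_map": mmap,
        "pedigree": ped,
        "phased": phased,
        "phenotypes": phen,
        "truth": truth,
        "founder_spec": spec,
    }
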