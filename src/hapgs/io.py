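"""Readers/writers for the standard formats, QC filters and run configuration.

Genotypes move as VCF (GT field, phased "|" separators when phase is
known), PLINK-style .ped/.map text, or a plain dosage TSV (individuals x
markers, 0/1/2, NA for missing).  Pedigree and phenotype tables are CSV.
All genomic coordinates are 1-based inclusive.

QC mirrors the usual array workflow and its order matters: markers with
call rate below the threshold are dropped first, then markers with minor
allele frequency below the floor.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING = -1  # internal missing dosage code

__all__ = [
    "RunConfig",
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "read_plink",
    "qc_filter",
    "join_tables",
    "load_dataset",
]


def write_vcf(path, dosage_or_phased, marker_map: pd.DataFrame, ids=None) -> None:
    """Write genotypes as uncompressed VCF.

    Accepts a PhasedGenotypes (writes phased ``a|b`` GT) or an
    (individuals x markers) dosage array (writes unphased ``a/b``).
    Allele 0 is REF=A, allele 1 is ALT=G (synthetic placeholders).
    """
    from hapgs.simulate import PhasedGenotypes

    phased = isinstance(dosage_or_phased, PhasedGenotypes)
    if phased:
        ids = dosage_or_phased.ids
        haps = dosage_or_phased.haplotypes
        n = len(ids)
    else:
        dos = np.asarray(dosage_or_phased)
        n = dos.shape[0]
        if ids is None:
            ids = [f"ind{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for ch in sorted(marker_map.chromosome.unique()):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, ids)) + "\n")
        for j, row in enumerate(marker_map.itertuples()):
            gts = []
            for i in range(n):
                if phased:
                    a, b = haps[i, 0, j], haps[i, 1, j]
                    gts.append(f"{a}|{b}")
                else:
                    d = dos[i, j]
                    if d not in (0, 1, 2):
                        gts.append("./.")
                    elif d == 0:
                        gts.append("0/0")
                    elif d == 1:
                        gts.append("0/1")
                    else:
                        gts.append("1/1")
            fh.write(f"{row.chromosome}\t{row.position_bp}\t{row.marker_id}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path):
    """Read a VCF into (dosage array with -1 missing, marker_map, ids)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"marker {var.ID} is not biallelic")
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", int(var.CHROM), var.POS))
        gt = np.asarray(var.genotype.array())[:, :2]
        d = gt.sum(axis=1).astype(np.int16)
        d[(gt < 0).any(axis=1)] = MISSING
        dosages.append(d)
    mmap = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])
    return np.array(dosages, dtype=np.int16).T, mmap, ids


def write_dosage_tsv(path, dosage, marker_map: pd.DataFrame, ids) -> None:
    df = pd.DataFrame(np.asarray(dosage, dtype=float),
                      index=pd.Index(ids, name="individual_id"),
                      columns=marker_map.marker_id)
    df = df.where(df.isin([0, 1, 2]))
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path, marker_map: pd.DataFrame | None = None):
    df = pd.read_csv(path, sep="\t", index_col=0)
    dos = df.to_numpy(dtype=float)
    out = np.where(np.isin(dos, (0, 1, 2)), dos, MISSING).astype(np.int16)
    if marker_map is None:
        marker_map = pd.DataFrame({
            "marker_id": df.columns,
            "chromosome": 1,
            "position_bp": np.arange(1, df.shape[1] + 1),
        })
    else:
        marker_map = marker_map.set_index("marker_id").loc[df.columns].reset_index()
    return out, marker_map, list(df.index)


def read_plink(ped_path, map_path):
    """PLINK-style text .ped/.map: dosage counts the second-listed allele."""
    mrows = []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        ch, mid, _, pos = line.split()[:4]
        mrows.append((mid, int(ch), int(pos)))
    mmap = pd.DataFrame(mrows, columns=["marker_id", "chromosome", "position_bp"])
    ids, rows = [], []
    alleles: list[dict] = [{} for _ in range(len(mmap))]
    raw = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        ids.append(parts[1])
        geno = parts[6:]
        if len(geno) != 2 * len(mmap):
            raise ValueError(f"ped row for {parts[1]} has wrong allele count")
        raw.append(geno)
        for j in range(len(mmap)):
            for a in geno[2 * j:2 * j + 2]:
                if a != "0":
                    alleles[j][a] = alleles[j].get(a, 0) + 1
    coding = []
    for j, cnt in enumerate(alleles):
        if len(cnt) > 2:
            raise ValueError(f"marker {mmap.marker_id[j]} has >2 alleles")
        order = sorted(cnt, key=lambda a: (cnt[a], a))
        coding.append(order[-1] if order else None)  # most frequent = counted allele
    dos = np.full((len(ids), len(mmap)), MISSING, dtype=np.int16)
    for i, geno in enumerate(raw):
        for j in range(len(mmap)):
            a1, a2 = geno[2 * j], geno[2 * j + 1]
            if a1 == "0" or a2 == "0" or coding[j] is None:
                continue
            dos[i, j] = (a1 == coding[j]) + (a2 == coding[j])
    return dos, mmap, ids


def qc_filter(dosage: np.ndarray, marker_map: pd.DataFrame,
              call_rate_min: float = 0.90, maf_min: float = 0.05):
    """Marker QC: drop low call rate first, then low MAF; log counts.

    Monomorphic markers fall under the MAF filter.  Returns (dosage,
    marker_map, report dict).
    """
    dos = np.asarray(dosage)
    valid = np.isin(dos, (0, 1, 2))
    call_rate = valid.mean(axis=0)
    keep_cr = call_rate >= call_rate_min
    n_cr = int((~keep_cr).sum())
    dos1 = dos[:, keep_cr]
    valid1 = valid[:, keep_cr]
    with np.errstate(invalid="ignore"):
        freq = np.where(valid1, dos1, 0).sum(axis=0) / np.maximum(
            2 * valid1.sum(axis=0), 1)
    maf = np.minimum(freq, 1 - freq)
    keep_maf = maf >= maf_min
    n_maf = int((~keep_maf).sum())
    keep_idx = np.flatnonzero(keep_cr)[keep_maf]
    report = {
        "n_input": dos.shape[1],
        "removed_call_rate": n_cr,
        "removed_maf": n_maf,
        "n_retained": len(keep_idx),
    }
    logger.info("QC: %(n_input)d markers in, %(removed_call_rate)d removed by "
                "call rate, %(removed_maf)d by MAF, %(n_retained)d retained",
                report)
    mmap = marker_map.iloc[keep_idx].reset_index(drop=True)
    return dos[:, keep_idx], mmap, report


def join_tables(genotype_ids, pedigree: pd.DataFrame, phenotypes: pd.DataFrame):
    """Intersect ids across tables; report drops explicitly by name."""
    gset = set(genotype_ids)
    pset = set(pedigree.individual_id)
    fset = set(phenotypes.individual_id)
    if len(gset) != len(list(genotype_ids)):
        raise ValueError("duplicated genotype ids")
    usable = sorted(gset & pset & fset, key=list(genotype_ids).index)
    report = {
        "n_usable": len(usable),
        "genotyped_not_phenotyped": sorted(gset - fset),
        "phenotyped_not_genotyped": sorted(fset - gset),
        "not_in_pedigree": sorted((gset | fset) - pset),
    }
    for key in ("genotyped_not_phenotyped", "phenotyped_not_genotyped",
                "not_in_pedigree"):
        if report[key]:
            logger.info("%s: %s", key, report[key])
    return usable, report


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through YAML losslessly."""

    genotypes: str = ""
    genotype_format: str = "vcf"  # vcf | plink | dosage
    plink_map: str = ""
    pedigree: str = ""
    phenotypes: str = ""
    output_dir: str = "hapgs_out"
    traits: list = field(default_factory=list)  # empty = all non-id columns
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    block_strong_ci_high: float = 0.98
    block_strong_ci_low: float = 0.70
    block_recomb_ci_high: float = 0.90
    block_informative_fraction: float = 0.95
    block_max_span_bp: int = 500_000
    models: list = field(default_factory=lambda: ["BRR", "BA", "BB", "BC", "BL"])
    marker_modes: list = field(default_factory=lambda: ["SNP", "HAP", "HAP_SNP"])
    mcmc_iterations: int = 20_000
    mcmc_burn_in: int = 2_000
    mcmc_thin: int = 10
    cv_cycles: int = 20
    cv_holdout: float = 0.10
    cv_reference: str = "adjusted"  # "adjusted" or "gebv" (literal definition)
    selection_fraction: float = 0.1006
    seed: int = 1

    def __post_init__(self):
        for name in ("call_rate_min", "maf_min", "block_strong_ci_high",
                     "block_strong_ci_low", "block_recomb_ci_high",
                     "block_informative_fraction", "cv_holdout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if not self.models:
            raise ValueError("model list must not be empty")
        bad = [m for m in self.models if m not in ("BRR", "BA", "BB", "BC", "BL")]
        if bad:
            raise ValueError(f"unknown models {bad}")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_dataset(config: RunConfig):
    """Load genotypes + map + pedigree + phenotypes and apply QC.

    Returns (dosage, marker_map, pedigree, phenotypes, ids, report): dosage
    rows are restricted and ordered to the usable id intersection, QC is
    applied in the stated order, and the report names every dropped or
    unmatched id.
    """
    fmt = config.genotype_format
    if fmt == "vcf":
        dos, mmap, gids = read_vcf(config.genotypes)
    elif fmt == "plink":
        dos, mmap, gids = read_plink(config.genotypes, config.plink_map)
    elif fmt == "dosage":
        dos, mmap, gids = read_dosage_tsv(config.genotypes)
    else:
        raise ValueError(f"unknown genotype_format {fmt!r}")
    ped = pd.read_csv(config.pedigree)
    phen = pd.read_csv(config.phenotypes)
    dos, mmap, qc_report = qc_filter(dos, mmap, config.call_rate_min, config.maf_min)
    usable, join_report = join_tables(gids, ped, phen)
    row = {iid: i for i, iid in enumerate(gids)}
    dos = dos[[row[i] for i in usable]]
    phen = phen.set_index("individual_id").loc[usable].reset_index()
    return dos, mmap, ped, phen, usable, {"qc": qc_report, "join": join_report}
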