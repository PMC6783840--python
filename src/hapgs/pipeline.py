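"""End-to-end orchestration: QC -> blocks -> encoding -> pedigree fit ->
genomic fits (model x marker set) -> cross-validation -> comparisons.

Every output directory gets a ``run.json`` sidecar with the config hash,
master seed and stage summaries, so a run is reproducible and individual
stage outputs are re-usable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from hapgs import bayes, encoding, evaluate, io, ld, pedigree as pedmod

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "block_summary"]


def block_summary(blocks: list, marker_map: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome block summary (SNPs, blocks, haplotypes, span range)."""
    chrom = marker_map.chromosome.to_numpy()
    rows = []
    for ch in sorted(np.unique(chrom)):
        bl = [b for b in blocks if b.chromosome == ch]
        rows.append({
            "chromosome": int(ch),
            "n_snps": int((chrom == ch).sum()),
            "n_blocks": len(bl),
            "n_haplotypes": int(sum(len(b.variants) for b in bl)),
            "max_span_bp": max((b.span_bp for b in bl), default=0),
            "min_span_bp": min((b.span_bp for b in bl), default=0),
            "max_snps": max((b.n_snps for b in bl), default=0),
            "min_snps": min((b.n_snps for b in bl), default=0),
        })
    df = pd.DataFrame(rows)
    total = {
        "chromosome": "total",
        "n_snps": int(df.n_snps.sum()),
        "n_blocks": int(df.n_blocks.sum()),
        "n_haplotypes": int(df.n_haplotypes.sum()),
        "max_span_bp": int(df.max_span_bp.max()) if len(df) else 0,
        "min_span_bp": int(df.min_span_bp.min()) if len(df) else 0,
        "max_snps": int(df.max_snps.max()) if len(df) else 0,
        "min_snps": int(df.min_snps.min()) if len(df) else 0,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def _mcmc(config: io.RunConfig) -> pedmod.McmcConfig:
    return pedmod.McmcConfig(config.mcmc_iterations, config.mcmc_burn_in,
                             config.mcmc_thin)


def run_pipeline(config: io.RunConfig) -> dict:
    """Run the whole analysis; returns the in-memory report bundle.

    Writes blocks.tsv, block_summary.tsv, pedigree_fit.json, a
    heritability/genetic-gain table (Table-2 style), a predictive-ability
    table with Tukey-Kramer letters (Table-3 style), per-cycle PA dumps and
    EBV-GEBV scatter data under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % 2**31) for name, s in
             zip(["blocks", "pedigree", "genomic", "cv"], master.spawn(4))}

    dos, mmap, ped, phen, ids, report = io.load_dataset(config)
    traits = config.traits or [c for c in phen.columns
                               if c not in ("individual_id", "design_block")]

    params = ld.GabrielParams(
        strong_ci_high=config.block_strong_ci_high,
        strong_ci_low=config.block_strong_ci_low,
        recomb_ci_high=config.block_recomb_ci_high,
        informative_fraction=config.block_informative_fraction,
        max_span_bp=config.block_max_span_bp,
    )
    blocks = ld.gabriel_blocks(dos, mmap, params)
    pd.DataFrame([{
        "chromosome": b.chromosome,
        "start_bp": int(mmap.position_bp.iloc[b.first]),
        "end_bp": int(mmap.position_bp.iloc[b.last]),
        "n_snps": b.n_snps,
        "marker_ids": ",".join(b.marker_ids),
        "haplotypes": ";".join(f"{a}:{f:.4f}" for a, f in b.variants),
    } for b in blocks]).to_csv(out / "blocks.tsv", sep="\t", index=False)
    summary = block_summary(blocks, mmap)
    summary.to_csv(out / "block_summary.tsv", sep="\t", index=False)

    assignments = encoding.phase_blocks(dos, blocks)
    designs = {}
    for mode in config.marker_modes:
        try:
            designs[mode] = encoding.build_design(
                dos, blocks, assignments, mode, ids=ids,
                marker_ids=list(mmap.marker_id))
        except ValueError as exc:
            logger.warning("marker mode %s skipped: %s", mode, exc)

    a_inv = pedmod.build_a_inverse(ped)
    mcmc = _mcmc(config)
    x_blocks = pd.get_dummies(phen.design_block).to_numpy(dtype=float)
    ped_fits, table2_rows, table3_rows = {}, [], []
    cv_dumps = {}
    for ti, trait in enumerate(traits):
        fit = pedmod.fit_animal_model(phen, trait, a_inv, mcmc,
                                      seed=seeds["pedigree"] + ti)
        ped_fits[trait] = fit
        ybar = float(phen[trait].mean())
        row_idx = [fit.ids.index(i) for i in ids]
        gg_ped = bayes.genetic_gain(fit.ebv_mean[row_idx],
                                    config.selection_fraction, ybar)
        table2_rows.append({
            "trait": trait, "model": "PBP", "marker_mode": "pedigree",
            "h2": fit.h2_mean, "h2_cr90_low": fit.h2_cr90[0],
            "h2_cr90_high": fit.h2_cr90[1], "gg": gg_ped, "star": "",
        })
        y = phen[trait].to_numpy(dtype=float)
        pa_groups = {}
        for di, (mode, design) in enumerate(designs.items()):
            for mi, model in enumerate(config.models):
                spec = bayes.ModelSpec(model=model, mcmc=mcmc)
                gseed = seeds["genomic"] + 1000 * ti + 10 * mi + di
                gfit = bayes.fit_genomic_model(
                    y, x_blocks, design, spec, seed=gseed,
                    selection_fraction=config.selection_fraction,
                    phenotypic_mean=ybar)
                star = evaluate.credible_set_compare(
                    gfit.h2_draws, fit.samples["h2"])
                table2_rows.append({
                    "trait": trait, "model": model, "marker_mode": mode,
                    "h2": gfit.h2_mean, "h2_cr90_low": gfit.h2_cr90[0],
                    "h2_cr90_high": gfit.h2_cr90[1], "gg": gfit.gg,
                    "star": "*" if star else "",
                })
                cv = evaluate.cross_validate(
                    y, x_blocks, design.values, spec, marker_mode=mode,
                    holdout_fraction=config.cv_holdout,
                    n_cycles=config.cv_cycles,
                    reference=config.cv_reference,
                    seed=seeds["cv"] + 1000 * ti + 10 * mi + di)
                pa_groups[(mode, model)] = cv
                cv_dumps[(trait, mode, model)] = cv.pa_cycles
        if pa_groups:
            upper = {}
            models_present = sorted({m for (_, m) in pa_groups})
            modes_present = sorted({md for (md, _) in pa_groups})
            if len(modes_present) >= 2:
                for m in models_present:
                    rep = evaluate.compare_tukey_kramer(
                        [pa_groups[(md, m)].pa_cycles for md in modes_present],
                        groups=modes_present)
                    for md, letter in zip(modes_present, rep.letters):
                        upper[(md, m)] = letter.upper()
            for mode in modes_present:
                models = [m for (md, m) in pa_groups if md == mode]
                if len(models) >= 2:
                    rep = evaluate.compare_tukey_kramer(
                        [pa_groups[(mode, m)].pa_cycles for m in models],
                        groups=models)
                    lowers = rep.letters
                else:
                    lowers = ["a"] * len(models)
                for m, letter in zip(models, lowers):
                    table3_rows.append({
                        "trait": trait, "marker_mode": mode, "model": m,
                        "mean_pa": pa_groups[(mode, m)].mean_pa,
                        "letters_models": letter,
                        "letters_modes": upper.get((mode, m), ""),
                    })

    table2 = pd.DataFrame(table2_rows)
    table2.to_csv(out / "heritability_gain.tsv", sep="\t", index=False)
    table3 = pd.DataFrame(table3_rows)
    table3.to_csv(out / "predictive_ability.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"trait": t, "marker_mode": md, "model": m, "cycle": c, "pa": pa}
        for (t, md, m), cycles in cv_dumps.items()
        for c, pa in enumerate(cycles)
    ]).to_csv(out / "pa_cycles.tsv", sep="\t", index=False)

    meta = {
        "config_hash": config.hash(),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "report": {k: v for k, v in report.items()},
        "n_blocks": len(blocks),
        "traits": traits,
    }
    with open(out / "run.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    config.save(out / "config.yaml")
    return {
        "blocks": blocks,
        "block_summary": summary,
        "designs": designs,
        "pedigree_fits": ped_fits,
        "table2": table2,
        "table3": table3,
        "meta": meta,
    }
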