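# hapgs

SNP- and haplotype-based genomic selection for pedigreed breeding
populations, built for forest-tree progeny trials but applicable to any
diploid population with unphased biallelic SNP genotypes, a pedigree, and
replicated field phenotypes.

Genomic selection (GS) predicts breeding values from genome-wide markers
instead of pedigree alone. Because nearby SNPs in strong linkage
disequilibrium (LD) are inherited together, grouping them into haplotype
blocks and regressing on haplotype *copy counts* can capture QTL that no
single SNP tags — often helping most for low-heritability traits. `hapgs`
implements that whole analysis chain:

* **LD and haplotype blocks** — two-locus haplotype frequencies by EM from
  unphased genotypes; Lewontin's D′ = |D|/D<sub>max</sub> and
  r² = D²/(p<sub>A1</sub>p<sub>A2</sub>p<sub>B1</sub>p<sub>B2</sub>);
  one-sided likelihood-profile confidence bounds on D′; Gabriel
  confidence-interval blocks (strong LD: CI upper ≥ 0.98 and lower ≥ 0.70;
  strong recombination: upper < 0.90; blocks need ≥ 95% strong-LD
  informative pairs); Breseghello–Sorrells critical r² from unlinked pairs
  and the genome-wide LD-decay profile.
* **Haplotype encoding** — within-block phasing by multi-locus EM,
  maximum-posterior diplotypes, and the three regressor sets **SNP**
  (0/1/2 dosage, 2 = common homozygote), **HAP** (0/1/2 copies of each
  haplotype variant) and **HAP-SNP** (variants plus SNPs outside blocks).
* **Pedigree animal model** — y = Xβ + Za + ε with a ~ N(0, Aσ²ₐ), A the
  numerator relationship matrix (Henderson's rules with inbreeding for
  A⁻¹); Gibbs sampling; narrow-sense heritability
  h²ₐ = σ²ₐ/(σ²ₐ+σ²ₑ) per posterior draw.
* **Bayesian alphabet** — y = Xβ + Zm + ε with Gibbs samplers for BRR,
  Bayes A, Bayes B, Bayes Cπ and the Bayesian LASSO; model-specific
  genomic variance, e.g. σ²_g = 2σ²_m Σᵢ pᵢ(1−pᵢ) for BRR/BC, the
  per-marker analogue for BA/BB, and 2Σᵢ τᵢ²σ²ₑ pᵢ(1−pᵢ) for BL; genomic
  heritability and percent genetic gain
  GG = (ȳ_sel − ȳ_pop)/ȳ_phe × 100 at a chosen selection intensity.
* **Evaluation** — 90/10 cross-validated predictive ability averaged over
  random-split cycles, Tukey–Kramer compact-letter comparisons across
  models and marker sets, 90% credible-set significance against the
  pedigree estimates, and EBV–GEBV regression.
* **Synthetic data** — a gene-drop simulator (half-/full-sib families,
  planted perfect-LD founder segments, Poisson recombination, RCBD
  phenotypes with continuous and ordinal traits at target heritabilities)
  that gives every stage a no-download test surface with full truth.

## Worked example

```python
import pandas as pd
from hapgs import simulate as sm, ld, encoding as enc, bayes, pedigree as pm, evaluate as ev

sim = sm.simulate_study(n_families=40, progeny_per_family=10, n_chromosomes=3,
                        n_markers=300, n_segments=12, n_qtl=60,
                        traits={"WD": (0.46, None)}, seed=42)
phen, ph = sim["phenotypes"], sim["phased"]
dos = ph.dosage()[[ph.index_of(i) for i in phen.individual_id]]

blocks = ld.gabriel_blocks(dos, sim["marker_map"])
design = enc.build_design(dos, blocks, enc.phase_blocks(dos, blocks), "HAP_SNP",
                          marker_ids=list(sim["marker_map"].marker_id))
x = pd.get_dummies(phen.design_block).to_numpy(float)
y = phen["WD"].to_numpy(float)
fit = bayes.fit_genomic_model(y, x, design,
                              bayes.ModelSpec("BRR", mcmc=pm.McmcConfig(4000, 1000, 5)),
                              seed=42)
pfit = pm.fit_animal_model(phen, "WD", pm.build_a_inverse(sim["pedigree"]),
                           pm.McmcConfig(4000, 1000, 5), seed=42)
```

Output of the full script (see the docstrings for the remaining calls):

```
found 26 haplotype blocks (2-5 SNPs, spans 18662-499599 bp)
HAP-SNP design: 280 columns (52 haplotype variants + 228 unassigned SNPs)
BRR genomic heritability: 0.53 [0.42-0.63]  genetic gain: 79.6%
pedigree heritability:    0.43 [0.27-0.61]
EBV-GEBV regression: slope 1.11, R^2 0.74
predictive ability (20 CV cycles): 0.54 +/- 0.02
```

Reading it: 12 perfect-LD segments were planted, and family disequilibrium
in the 400-tree pedigree creates further block-like stretches, so 26
blocks pass the Gabriel criteria. The wood-density trait was simulated at
h² = 0.46; both the genomic (0.53) and pedigree (0.43) posteriors cover
the truth, the EBV–GEBV regression slope is near 1, and cross-validated
predictive ability is 0.54. The genetic-gain percentage is large only
because the synthetic trait's additive variance is large relative to its
mean of 10.

A `hapgs` command-line interface wraps the same stages
(`hapgs simulate`, `qc`, `blocks`, `encode`, `fit-pedigree`,
`fit-genomic`, `cv`, `report`, `run`) around a YAML run configuration.

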