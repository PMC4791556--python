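# creole-core

Diversity analysis and **mixed-variable core reference set selection** for large
SNP-genotyped germplasm collections, motivated by genebank panels of Mexican
("Creole") wheat landraces characterized by genotyping-by-sequencing (GBS).

A genebank holding thousands of landrace accessions needs two things from its
genotype data: an honest description of how diversity — especially *rare allele*
diversity — is distributed across geographic and genetic groups, and a manageable
core subset that a breeder can actually phenotype without throwing that diversity
away. `creole-core` implements both halves as a tested, reusable library with a
thin CLI, plus a synthetic-panel generator so every stage is verifiable without
access to any particular collection.

## What it computes

**Diversity statistics** over a biallelic dosage matrix (0/1/2 with missing
calls): per-marker allele frequencies and the MAF spectrum; Nei's gene diversity
`H = 1 − (p² + q²)` and the Shannon index `I = −(p ln p + q ln q)`, averaged over
markers per group; Nei's differentiation `G_ST = (H_T − H_S)/H_T` with gene flow
`N_m = (1 − G_ST)/(4 G_ST)`; multilocus pairwise F_ST (Weir & Cockerham 1984
variance components, or a pairwise G_ST variant); simple-matching distance
`d(x,y) = 1 − M/N` with complete-linkage clustering; and an equally-spaced marker
subsetting routine for map-balanced index estimation.

**Rare-allele characterization**: alleles with population frequency strictly in
(0, 0.05) per reference population; per-group counts (`nra`), rates per accession
(`napa = nra/nac`), *unique* rare alleles (`nura`, rare in one group and carried
nowhere else — a group-size-invariant measure) and their percentage (`pura`);
geographic k-means on (latitude, longitude, altitude) with cross-classification
against genetic groups; and a scan for alleles fixed within a geographic cluster
while segregating in the complete set.

**Core selection** blends genotype and phenotype. The marker matrix is reduced by
PCA; the PC block and the 23-trait phenotype block enter a two-block multiple
factor analysis in which the phenotype block is rescaled by a weight `w` (found by
bisection) so that the cumulative genotype:phenotype contributions over the first
six axes hit a target ratio (default 75:25). Accessions are grouped on the axis
scores by two-stage **Ward-MLM** (Ward agglomeration initializing a Gaussian
mixture EM with shared covariance; groups chosen by BIC or a log-likelihood
plateau). Quotas per group follow the **D-method** — proportional to mean
within-group Gower distance — and many stratified random candidates are scored by
mean pairwise **Gower distance**, keeping the maximum. A Monte-Carlo subsampling
curve (`f_ST = var(p)/(p̄ q̄)` across replicate subsamples at 5–100% levels)
supports the choice of core size, and an evaluation module reports rare-allele
recovery, diversity indices, phenotype mean/variance ratios and classical MDS
coordinates for the core against the complete set.

## Worked example

```python
import numpy as np
from creole_core import SimulationConfig, simulate_population
from creole_core.core_selection import select_core
from creole_core.diversity import gst_and_nm, nei_index, pairwise_fst, shannon_index
from creole_core.evaluation import compare_core_complete

cfg = SimulationConfig(n_accessions=500, n_markers=2000, n_groups=5,
                       target_fst=0.15, seed=42)
geno, pheno, sites, truth = simulate_population(cfg)

print(f"Nei diversity H = {nei_index(geno):.3f}, Shannon I = {shannon_index(geno):.3f}")
flow = gst_and_nm(geno, truth)
print(f"G_ST = {flow.g_st:.3f}, N_m = {flow.n_m:.2f}")

result = select_core(geno, pheno, core_fraction=0.15, n_geno_components=30,
                     g_range=range(3, 9), n_candidates=200, seed=1)
rep = compare_core_complete(geno, result.core)
print(f"core: {len(result.core.accession_ids)} accessions, "
      f"mean Gower {result.core.mean_gower:.4f} "
      f"vs complete {result.distance.mean_offdiagonal():.4f}")
print(f"rare-allele recovery: {rep.recovery_pct:.2f}%")
```

prints

```
Nei diversity H = 0.229, Shannon I = 0.353
G_ST = 0.123, N_m = 1.79
core: 75 accessions, mean Gower 0.2420 vs complete 0.2145
rare-allele recovery: 68.94%
```

i.e. on a 500-accession panel with five drift-differentiated groups (planted
F_ST = 0.15) the pipeline recovers the group structure, selects a 15% core whose
mean Gower distance exceeds the complete set's (a diversity gain of ~13% here),
and retains ~69% of the 557 complete-set rare alleles — far above what a random
subset of 75 accessions would keep.

The same steps are available from the shell:

```bash
creole-core simulate --config cfg.yaml --out-prefix panel --seed 7
creole-core diversity --genotypes panel_genotypes.csv --groups panel_groups.csv --out div.csv
creole-core rare-alleles --genotypes panel_genotypes.csv --groups panel_groups.csv \
    --geo panel_metadata.csv --k 6 --out rare.csv
creole-core core-select --genotypes panel_genotypes.csv --phenotypes panel_phenotypes.csv \
    --schema schema.yaml --core-frac 0.15 --candidates 1000 --seed 3 --out core.txt
creole-core evaluate --genotypes panel_genotypes.csv --core core.txt \
    --meta panel_metadata.csv --out report/
```

## Layout

- `creole_core.io_core` — containers (`GenotypeMatrix`, `PhenotypeTable`,
  `AccessionInfo`, `GroupAssignment`) and CSV/HapMap/VCF readers and writers.
- `creole_core.synthetic_data` — the population generator and rare-allele
  injector.
- `creole_core.diversity` — frequencies, indices, F_ST/G_ST/N_m, distances,
  clustering, spaced-marker selection.
- `creole_core.rare_alleles` — rare/unique/fixed allele reports, geographic
  k-means, cross-classification.
- `creole_core.core_selection` — PCA, two-block MFA, Ward-MLM, Gower, D-method,
  stratified search, core-size simulation.
- `creole_core.evaluation` — core-vs-complete reports, phenotype ratios, MDS.

See `docs/methods.md` for the statistical details, parameter choices and known
limitations.
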