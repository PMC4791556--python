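# Methods

This note documents the statistical models behind `creole-core`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic panels do
and do not establish about real collections.

## Genotype model and conventions

Genotypes are biallelic SNP calls stored as alternate-allele dosage: 0
(homozygous reference), 1 (heterozygous), 2 (homozygous alternate), with a
distinct missing sentinel that is never conflated with dosage 0. Allele
frequencies are computed over non-missing calls only, `p = Σ dosage / (2·n_calls)`
per marker; markers with zero calls in a given accession set are flagged and
excluded from marker averages. Marker filtering retains markers whose missing
fraction is *strictly below* the threshold (default 0.5), the convention under
which a marker with exactly half its scores missing is removed.

## Diversity and differentiation

Nei's gene diversity per marker is the biallelic expected heterozygosity
`1 − (p² + q²)`; the Shannon index is `−(p ln p + q ln q)` with `0·ln 0 ≡ 0`.
Both are reported as mean ± SD across markers, matching how such group tables are
usually presented. Although the index is sometimes written in terms of the major
allele frequency only, `1 − P_major²` is not a diversity index; the standard
two-allele form is used and this choice is deliberate.

`G_ST = (H_T − H_S)/H_T` uses the accession-count-weighted mean of within-group
diversities for `H_S` and the diversity at pooled (weighted-mean) frequencies for
`H_T`; Jensen's inequality guarantees `H_S ≤ H_T`, so `G_ST ∈ [0, 1]`. Gene flow
is the island-model transform `N_m = (1 − G_ST)/(4·G_ST)`, flagged infinite when
`G_ST = 0` rather than silently dividing by zero.

Pairwise F_ST defaults to the Weir–Cockerham (1984) estimator: per-locus variance
components a (among populations), b (among individuals) and c (within
individuals) computed from per-locus non-missing sample sizes, sample frequencies
and *observed* heterozygosity — which makes the estimator robust to the strong
inbreeding of selfing crops — combined multilocus as `Σa / Σ(a+b+c)`
(ratio of averages). Slightly negative estimates on undifferentiated pairs are
expected; the reported matrix is clamped at 0 with the raw values retained in
`df.attrs["raw"]`. A pairwise Nei `G_ST` variant is available. On
Balding–Nichols simulations the multilocus estimator recovers the planted F
within ±0.03 at 200 accessions × 1,000 markers (verified in the acceptance
suite at F ∈ {0.05, 0.15, 0.25}).

Simple-matching distance is `d(x, y) = 1 − M/N` over markers where both calls are
present, with genotype-call equality as the matching rule (a heterozygote matches
only a heterozygote); this is the plain reading of "simple matching" on genotype
data, and nothing in the downstream clustering depends on the alternative
allele-sharing rule. The squared-Euclidean transform `D² = 2·N·d` is exposed as a
view, never silently applied. Pairs with no shared markers are flagged missing.

Spaced-marker selection allocates per-chromosome quotas proportional to marker
share (largest-remainder rounding so the total is hit exactly), lays a grid of
`quota` points starting at the first mapped position with step `span/quota`, and
takes the nearest unused marker to each point, ties toward the lower position.
The grid convention (`first_anchored` vs an endpoints-inclusive `endpoint` grid)
is configurable because endpoint inclusion is genuinely ambiguous for this kind
of procedure; the default anchors at the first marker.

## Rare alleles

A rare allele has reference-population frequency strictly in (0, 0.05): zero is a
*lost* allele, and exactly 0.05 is not rare. At a biallelic marker at most one
allele can be rare. Group reports support two reference scopes: each group as its
own population (the default for per-group tables) or the complete set with
group-restricted presence. A **unique** rare allele of group k is rare in k's
population *and* carried by no accession outside k; the carried-nowhere-else
clause is what makes `nura`/`pura` invariant to group size (duplicating a group's
accessions changes none of its unique-allele counts, a property the tests
enforce). `raf` is reported as the mean reference-population frequency of the
group's rare alleles; note that per-group frequency spectra in drift-structured
collections can place this mean well above the 0.05 cutoff only when computed on
a different allele set, so the column is defined here explicitly as stated.

The fixed-allele scan gates candidate markers at a ≥60% call rate within the
cluster (the only reading of a per-marker "data points" requirement that is
well-defined), then flags markers monomorphic in the cluster (within-cluster
MAF ≤ `fixed_maf_max`, default 0) while segregating in the complete set. Both the
gate and the fixation cutoff are parameters. Geographic clusters come from
k-means on z-scored (latitude °, longitude °, altitude m), 10 restarts, best
inertia, seeded.

## Core selection

**PCA.** Missing dosages are mean-imputed per marker before the centered
decomposition — imputation to the column mean preserves frequencies and is the
field default for genotype PCA. An integer component count or a cumulative
variance target may be given.

**Two-block MFA with contribution targeting.** The genotype-PC block and the
phenotype block (ordinal traits coded as numeric levels; all columns z-scored)
are each divided by the square root of their first principal eigenvalue — the
MFA normalization that stops either block from dominating the first axis — after
which the phenotype block is multiplied by a scalar weight `w`. The contribution
of a block to an axis is the summed squared loadings of its columns; the
cumulative contribution over the first `n_axes` axes (eigenvalue-weighted) is a
monotone function of `w`, so `w` is found by bisection on `log w ∈ [−6, 6]` to
hit the target ratio (default 75:25 over 6 axes, tolerance 1%). Contributions can
*step* at weights where the axis ordering swaps, so the search is validated
against a brute-force grid by comparing achieved contributions, not weights. An
unattainable target raises an error reporting the achievable range. Deeper block
hierarchies are out of scope: with exactly two data types the two-block form is
the whole structure.

**Ward-MLM.** Stage 1 cuts a Ward dendrogram of the axis scores at each
candidate G; stage 2 refines each partition by Gaussian-mixture EM with a shared
full covariance (the modified-location-model convention for mostly continuous
scores; per-group diagonal is available), initialized from the Ward partition
and ridge-regularized (1e-6) against degeneracy. Model selection defaults to BIC
because the raw likelihood is non-decreasing in G; a `loglik` criterion
implements the maximum-likelihood wording with a plateau rule (smallest G whose
relative gain falls below 1%). EM is run one iteration at a time so the
log-likelihood trace is exposed and its monotonicity testable.

**Gower distance.** For mixed variables: categorical (marker calls) contribute
an exact-match similarity, continuous and ordinal variables contribute
`1 − |xᵢ − xⱼ|/range`; the distance is one minus the weighted mean similarity
over variables observed in both records, hence in [0, 1]. On large panels the
selection-stage distance is computed on the factor-analysis axes (continuous
Gower, each axis weighted by its variance share) because a marker-level Gower
matrix per candidate over ~10⁴ markers × ~10⁴ accessions is intractable; the raw
mixed-variable form is retained for small problems and for evaluation. Which
representation feeds the candidate scoring is therefore an explicit design
choice, not a claim about any particular historical analysis.

**D-method allocation.** Group quotas are proportional to mean within-group
Gower distance (singletons contribute 0 and fall under the minimum-quota rule),
rounded by largest remainder, clamped at group sizes with iterative
redistribution, and guaranteed to sum to the core size; every non-empty group
keeps at least one slot when the core is large enough.

**Stratified search.** Each of `n_candidates` (default 1000) candidates samples
its quota uniformly without replacement within each group; the score is the mean
pairwise distance within the candidate and the argmax wins, ties to the lowest
index. All randomness flows from one seeded generator, so the full pipeline is
reproducible from its inputs and one integer.

**Core-size curve.** At each sampling level (5–100%, step 5) the routine draws
`n_reps` subsamples without replacement and computes per-marker `var(p)` across
replicates, aggregated over markers (`var_p`, the default) or standardized as
`f_ST = var(p)/(p̄·q̄)`. Under without-replacement sampling
`var(p̂) = pq(2N − 2n)/(2n(2N − 1))`, strictly decreasing in the subsample size
and exactly 0 at the 100% level — so under these definitions the curve has its
maximum at the smallest level and cannot peak at an interior size. Any interior
"optimum" must come from a different statistic; the module exposes the
alternatives it implements and makes no claim beyond them. The default core
fraction of 0.15 is carried as a conventional choice for collections of this
kind.

## The synthetic generator

`SimulationConfig` defaults encode the regime of a large GBS landrace panel:
7,986 accessions × 20,526 markers in 15 groups with sizes proportional to a
published 15-group panel; Balding–Nichols group frequencies around ancestral
frequencies (scalar F, default 0.15, inside the 0.04–0.28 range typical of such
collections); 40.4% of markers seeded with ancestral frequency below 0.05;
per-marker missingness uniform on (0, 0.5); heterozygote calls resampled to
homozygotes so per-marker heterozygosity never exceeds 30.5% in expectation
(selfing crop); 23 traits (4 ordinal scores, 19 continuous measurements) with
means and variances from a large wheat landrace evaluation, shifted per group by
0.5 trait-SD; collection sites jittered (σ = 0.35°, 150 m) around one
state-level centre per group. Tests and the acceptance script run scaled-down
panels (200–2,000 accessions × 1,000–5,000 markers) — sizes chosen so the whole
suite completes in minutes while keeping every estimator in its working regime.

What the generator does **not** emulate: linkage disequilibrium and physical
clustering of markers, coalescent ancestry, admixture gradients between groups,
genotyping error, non-random missingness (e.g. presence/absence variation), or
genotype–phenotype covariance beyond a shared group shift. Passing tests
therefore demonstrate the correctness and calibration of the statistics under a
drift-plus-noise model, not robustness to those real-data features.

`inject_rare_alleles` plants group-private minor alleles for planted-truth
testing: designated markers are rewritten so carriers (dosage 1) occur only in
the designated group, at whole-population frequency in (0, 0.05), and also below
the rarity cutoff within the group's own population whenever the group is large
enough for that to be possible (in a group with fewer than ~10 called members a
single carrier already exceeds a 5% within-group frequency, a real property of
tiny populations, not an artifact).

## Numerical choices and degenerate inputs

- Ties everywhere break toward the lower index/position; all stochastic stages
  take explicit seeds.
- Largest-remainder rounding is the single integer-apportionment primitive,
  shared by marker quotas, allocation quotas and group-size resolution.
- Weir–Cockerham per-locus components are skipped for loci without calls in both
  samples; `nan` never propagates into multilocus sums.
- Classical MDS truncates negative eigenvalues at zero (non-Euclidean input) and
  reports a normalized stress; it is cross-checked in the tests against an
  independent principal-coordinates implementation.
- Zero-variance phenotype blocks, single-group differentiation, empty accession
  subsets, infeasible allocation and infeasible injection all raise explicit
  errors rather than returning silent defaults; an empty marker filter result
  only warns.

## Known limitations

- The VCF dialect is minimal: GT-only, biallelic records, uncompressed files.
- Per-candidate scoring in the stratified search is exact (no incremental
  update), so very large `n_candidates` × core sizes cost
  O(`n_candidates` · k²).
- The mixture stage assumes elliptical groups in axis space; strongly
  non-Gaussian structure (e.g. admixture clines) will be over-split by BIC.
- `pura`/`nura` depend on the completeness of genotyping: a unique allele can be
  an artifact of missing calls outside the group at heavily missing markers.
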