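# Methods

This note documents the models and procedures implemented in `landgen`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic test bed does and does not establish about real data.

## The synthetic study design

`landgen.synth` generates data with the structure of a range-wide RAD-seq
landscape-genomics study. Its defaults define the study conditions used
throughout the test suite and the acceptance script:

* **Landscape.** Cells are placed uniformly in a 98–120°E × 24–36°N box
  (a subtropical montane belt). Each environmental variable is an
  independent stationary Gaussian random field, synthesized spectrally
  with random Fourier features of a Gaussian kernel with length scale
  4° (configurable); only the autocorrelation contract matters and is
  tested (Moran's I ≈ 0 as the range → 0, strongly positive at long
  range). Variables carry WorldClim-like names and scales (BIO02, BIO03,
  BIO04, BIO07, BIO08, BIO13, BIO15, elevation). Future scenarios are
  additive shifts; the defaults define a low-emission (SSP126-like) and a
  high-emission (SSP585-like) 2081–2100 horizon whose deltas are nested
  (the high-emission shift dominates per variable), with elevation static.
* **Populations.** 28 populations of 4–8 individuals each (≈ 160
  individuals) in 3 lineages. Lineage labels are assigned by
  farthest-point centroids over the sampled cells, so lineages are
  spatially contiguous blocks, as in real phylogeographic structure.
  All individuals of a population share its coordinates.
* **Genotypes.** Neutral allele frequencies follow a two-level
  Balding–Nichols hierarchy: ancestral frequency ~ U(0.1, 0.9), lineage
  frequencies ~ Beta(p(1−F_L)/F_L, (1−p)(1−F_L)/F_L) with F_L = 0.18 by
  default, population frequencies drawn the same way around their lineage
  frequency with F_P = 0.05. This calibration puts pairwise lineage-level
  multilocus F_ST in the 0.1–0.3 range typical of strongly structured
  montane relict trees, and the realized Weir–Cockerham estimate converges
  to the Balding–Nichols target as the locus count grows (verified at
  2 000 and 20 000 loci with halving tolerance).
* **Adaptive loci.** A configurable minority of loci (default ≈ 5 %)
  receive a logit-linear cline: logit(p_pop) += β·z, where z is the
  driver variable standardized across the sampled populations and β
  defaults to |β| ∈ [1.5, 3] with random sign, drivers cycling through
  BIO04/BIO13/BIO15 (temperature seasonality and the two precipitation
  variables). The cline acts on population frequencies, not individual
  genotypes, because every downstream association method operates on
  population frequencies.
* **Missingness** is uniform at random, default rate 0.05. Real RAD
  missingness is depth- and locus-structured; uniform missingness is an
  explicit simplification. The rate matters through the 70 % per-population
  call-rate filter: with 4–8 individuals per population, a single missing
  call can fail a small population, so at a 10 % uniform rate that filter
  alone would remove the large majority of loci — unlike any post-calling
  VCF. A 5 % rate yields realistic retention (~60 %).

What passing tests on this bed do **not** show about real data: linkage
(loci are exchangeable and unlinked), demographic history (no coalescent
process), depth-structured missingness, genotyping error, and
reference-bias effects are all absent. Power and calibration results below
are statements about this generative model.

## Filtering

Rules are applied in a fixed order — observed heterozygosity > 0.70 →
non-biallelic (enforced at VCF read time) → not the first SNP on its locus
group → pooled MAF < 0.05 → any population calling < 70 % of its
individuals → overall missingness ≥ 20 % (inclusive) — and each removed
locus is attributed to the first rule that rejects it, so the report
reconciles exactly with input/output counts. The order is a convention
(the rules are near-independent; order changes attribution, not the
retained set). MAF is computed on the pooled sample; a per-population MAF
is not implemented. The contig stands in for the RAD read in the
one-SNP-per-locus rule.

## Imputation

Missing genotypes are imputed from inferred genetic structure by
alternating least squares on the individuals × (loci·3) genotype-indicator
matrix: Q (individuals × K) is simplex-projected (rows are ancestry
proportions), F (K × loci·3) is non-negative with each locus triple
normalized to sum to one, and missing triples are re-estimated from QF
between sweeps. Initialization is deterministic (farthest-point seeding on
the filled dosage matrix); the solver is seeded only through that choice,
so results are reproducible. Missing entries are finally replaced by the
modal expected genotype (ties broken to the lower dosage, matching a
counts-based mode); observed entries are never altered. At K = 1 the
least-squares solution is the column mean, so imputation reduces exactly
to the per-locus modal genotype. A mask-and-recover experiment on
two-cluster data must reach ≥ 90 % exact recovery versus ≤ 70 % for a
global-mode baseline.

## Diversity statistics

* **Weir–Cockerham (1984)**: per-locus variance components with the
  ratio-of-sums multilocus combination (the VCFtools convention); negative
  per-locus estimates are retained before summing; loci monomorphic
  across all groups are excluded. Verified against an independently coded
  scalar-formula oracle to 1e-12.
* **π** uses the invariant-sites-aware estimator: per window,
  Σ differing allele pairs / Σ compared pairs, with monomorphic callable
  sites contributing comparisons but no differences. Because invariant
  sites are absent from a VCF, callable-site totals per window must be
  supplied; the synthetic fixture writes one window per RAD locus group
  with 120 callable sites (a RAD-locus-sized window standing in for the
  10-kb windows a reference-aligned analysis would use).
* **Allelic richness** is rarefied per locus to g = 2 × the smallest
  number of called genotypes across groups (overridable), using the exact
  hypergeometric absence probability.
* Private alleles are counted per allele (REF and ALT separately); a
  locus is polymorphic within a group iff both alleles are observed there.

## Outlier scans

All four scans are deterministic. Two design substitutions (stated in
their docstrings) stand in for MCMC-based tools while preserving their
decision rules:

* **PCA Mahalanobis scan**: per-SNP regression z-scores on the first K
  PCs, robust covariance by minimum covariance determinant (rows
  canonically sorted so the fit is invariant to locus order; median/MAD
  diagonal fallback), genomic-inflation rescaling of D², χ²_K p-values,
  Bonferroni at 0.05.
* **Trimmed-FST test**: per-locus FST without sample-size correction
  (infinite-sample WC ratio s²/(p̄q̄ + s²/r)); loci with pooled expected
  heterozygosity ≤ 0.1 excluded; a scaled χ² (free df and mean) fitted by
  truncated maximum likelihood to the 5–95 % body; right-tail p-values,
  BH q-values, flag at q < 0.05.
* **Latent-factor GEA**: per variable, K latent factors are the SVD of
  the genotype matrix residualized on the variable (the ridge-limit
  solution; the factors are orthogonal to the variable, so the
  environmental effect keeps its marginal estimate and structure
  correction is supplied by the factors' variance reduction plus genomic
  control). z² is calibrated by the median genomic inflation factor and
  referred to χ²₁. The flag applies the dual rule per variable:
  calibrated p < 0.001 AND BH q < 0.05.
* **Structure-corrected association**: on population allele frequencies,
  generalized least squares whitened by Ω^{-1/2}, where Ω is the
  covariance of populations across standardized neutral (non-FST-outlier)
  frequencies, ridge-regularized (centering makes Ω structurally
  rank-deficient). The evidence threshold is the χ²₁ 0.99 quantile scaled
  by the neutral scores' inflation factor — a calibrated-tail analogue of
  a "strong evidence" Bayes-factor cut — and a SNP is flagged for a
  variable only if it is also in the top 5 % of |Spearman ρ| for that
  variable.

**Calibration and its limits.** Error control is verified under nulls
satisfying each scan's model assumptions: mild drift fully captured by
K = 3 components for the PCA and latent-factor scans, and a single-level
island model for the trimmed-FST test (whose χ² null assumes
non-hierarchical structure). Under strong two-level drift, per-locus
effects are a heavy-tailed scale mixture and *all* scans of this family —
including the published tools they model — are anti-conservative in the
extreme tail; median-based genomic control cannot repair tail heaviness.
Users of real, strongly structured data should treat the far-tail
p-values of the FST-based scans as rankings rather than calibrated
probabilities.

**Power.** Under the full study conditions (spatially autocorrelated
environments over contiguous lineages), the detectable signal of the
latent-factor scan is bounded by β²/τ², where τ² is the population-drift
variance in the direction of the environmental variable — no choice of
factor count changes this, because factors orthogonal to the variable
cannot absorb drift along it. The GLS scan, which whitens by the neutral
covariance, sits closer to the information bound and shows correspondingly
higher power on planted clines. This ordering is a real property of the
methods, not an implementation artifact.

Consensus sets combine the two FST scans and the two GEA scans by union
(default; intersection available) and the all-outlier set is always
FST ∪ GEA, with Venn counts emitted.

## IBD, IBE and variance partitioning

Geographic distance is great-circle (haversine, R = 6371.0088 km; a flat
Euclidean option exists for sensitivity). Environmental distance is
Bray–Curtis on standardized variables shifted per variable to a minimum of
zero (Bray–Curtis requires non-negative inputs; the shift is the
documented convention for centered data). Genetic distance is
FST/(1−FST) with negative estimates clipped at zero.

Mantel tests correlate upper-triangle entries; the null permutes rows and
columns of the second matrix jointly; p = (1 + #{r* ≥ r})/(n_perm + 1),
one-sided for positive association (the IBD/IBE hypotheses). The partial
test correlates entrywise OLS residuals and permutes the residualized
matrix (raw-matrix permutation is not provided, residual permutation being
the stated convention here). Type-I error is verified at 0.05 ± 0.02 over
500 null replicates, and p-values are checked for uniformity.

PCNM: distances are truncated at the longest minimum-spanning-tree edge t
(entries > t replaced by 4t), −½D² is double-centered and
eigendecomposed; positive-eigenvalue eigenvectors scaled by √λ form the
basis and the first half of positive axes is retained by default, to be
narrowed by forward selection. Forward selection adds the candidate with
the largest adjusted-R² gain if its conditional permutation p < α = 0.05,
and stops once the cumulative adjusted R² exceeds the all-candidates
adjusted R² (the cap is checked after adding: checking before
systematically rejects the last true predictor whenever the clean model's
adjusted R² exceeds the junk-penalized full-model value).

RDA is multivariate least squares on standardized predictors with the
response centred (both residualized on the condition matrix first for
partial models); constrained axes are the PCA of the fitted values,
R² = SS_fit/SS_total, adjusted by Ezekiel's formula, and the global
permutation test permutes rows of the (residualized) predictors. The
two-block partition uses differences of adjusted R²
(geog|env = adjR²(both) − adjR²(env), etc.), which makes the ledger close
exactly: explained + unexplained = 1 and confounded = explained − the two
individual fractions. Orthogonal blocks can give slightly negative
confounded fractions (order −p/n, a known property of adjusted-R²
partitioning). Planted variance shares are recovered within ±0.03.

## Gradient forest and genetic offset

One random-forest regression per SNP (bootstrap rows, ⌈p/3⌉ predictors
per split — `max_features` overridable — minimum leaf 2, no depth cap;
2000 trees by default, 100–200 in tests for speed). Out-of-bag R² is the
SNP's importance weight; SNPs with R² ≤ 0 are excluded from aggregation.
Every split's impurity reduction is binned along its predictor at the
split threshold (201 bin edges per predictor over the observed range),
normalized by a smoothed data-density histogram, accumulated into a
monotone cumulative function and scaled so the SNP's total allocation
equals its out-of-bag R², allocated across predictors by raw improvement
share. The aggregate I_v is the R²-weighted mean of the per-SNP functions;
its endpoint equals the predictor's (R²-weighted impurity) importance —
impurity importance is used for ranking rather than out-of-bag permutation
importance, which the split-record approach does not require. Predictor
pruning keeps the top-3 ranked variables unconditionally and admits others
in rank order only when |Pearson r| < 0.7 against everything kept.

Grid cells are transformed by monotone linear interpolation of the
aggregate I_v between bin edges; values outside the training range clamp
to the endpoints (offsets beyond the training envelope are unreliable and
are deliberately not extrapolated). The genetic offset of a cell is the
Euclidean distance between its transformed current and future coordinates;
the vulnerable fraction is the share of cells strictly above a threshold
of 50 % of the maximum offset across the scenarios considered. Nested
future deltas therefore order the scenarios' vulnerable fractions, which
is tested.

## RONA

For each SNP and variable, ordinary least squares of population allele
frequency on the variable across populations; predicted future frequency
clamp₀₁(a + b·x_future); RONA is the mean |change| over SNPs passing the
per-regression significance pre-filter (p < 0.05 by default; switchable
off), with an R²-weighted variant and SE = SD/√n. "Current" frequency is
the observed value by default; a fitted-current option makes RONA vanish
identically at zero displacement and isolates projected displacement from
lack of fit — the GEA-versus-all-SNP vulnerability contrast is evaluated
under that option, because the observed-current convention adds a
lack-of-fit term that inflates the all-SNP baseline. The R²-weighted mean
weights SNPs within a population; variables are ranked by the mean
weighted RONA across populations with lexicographic tie-breaks.

## Problem sizes and seeds

The test suite and the acceptance script run the design at 2 000 SNPs,
28 populations / ~160 individuals, 300 landscape cells, 100–200 trees per
SNP, and 199–999 permutations — sizes chosen so the full pipeline
(simulation through vulnerability maps) completes in minutes on one CPU
while leaving every statistical contract measurable. All randomness flows
from explicit integer seeds; every pipeline stage is a pure function of
its inputs and seed, and the end-to-end smoke test asserts bit-identical
repetition.

## Known limitations

* Uniform missingness and unlinked loci (see above).
* The latent-factor and trimmed-FST scans are far-tail anti-conservative
  under strong hierarchical drift (shared with the tools they model).
* The latent-factor scan's power on drift-confounded clines is bounded
  well below the GLS scan's; both are reported, and the consensus GEA set
  is their union by default.
* π requires user-supplied callable-site totals on real data; there is no
  window engine for reference-aligned coordinates beyond per-contig
  windows.
* Bray–Curtis on min-shifted standardized variables is a convention; rank
  orderings are stable under it but absolute distances depend on the
  shift.
* The gradient-forest turnover functions use impurity (not permutation)
  importance for ranking; rankings agree on planted structure but can
  differ on strongly correlated predictors.
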