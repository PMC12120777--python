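# Methods

This note states the model behind every computation, the parameter
defaults and why they were chosen, the numerical choices, and the known
limits of the synthetic generator. Nothing here is an empirical claim
about real soil communities; empirical statements are limited to what the
bundled simulations actually compute.

## Niche breadth

Inputs: a binary taxa × samples occurrence matrix and an environmental
table (samples × variables, with an ecosystem label per sample).

1. Each variable is min-max standardized to [0, 1]. The default scope is
   `per_ecosystem` (min and max taken within each ecosystem) so that a
   taxon's range is measured against the variation available in its own
   habitat; `scope="global"` standardizes across the whole survey. A
   variable constant within its scope has no defined scale and raises an
   error naming the variable.
2. For one taxon and one variable, the environmental range is
   `max − min` of the standardized values over the occupied samples.
   Missing values are excluded per variable; fewer than two usable values
   leave that variable's range undefined (NaN) rather than zero.
3. Breadth is the mean of the defined per-variable ranges. Taxa occupying
   fewer than `min_occupancy = 2` samples are excluded entirely: a single
   occurrence carries no range information.

The index is a range statistic, so it grows monotonically with occupancy
and is sensitive to single extreme samples; an optional `quantile_trim`
replaces the span with an interquantile distance for robustness (off by
default, because the plain span is the primary definition).

`breadth_by_group` is a classical one-way ANOVA (scipy `f_oneway`) across
arbitrary taxon groupings, dropping groups below `min_group_size = 2`
with a warning.

## Synthetic generator

The generator is the package's study system; its defaults are the study
conditions and are never tuned to test outcomes.

* **Environment**: `n_vars = 8` variables, uniform on (0, 1) per sample,
  3 ecosystems × 150 samples. An optional equicorrelated Gaussian copula
  (`rho`) induces realistic cross-variable correlation; off by default so
  the axes are interpretable independently.
* **Niches**: each taxon draws a target breadth b ~ U(0.02, 1); its
  half-window on each variable is b/2 plus jitter (SD-like half-range
  0.05), so tolerances correlate across axes within a taxon — wide taxa
  are wide on every axis, as a one-dimensional generalism latent trait
  implies. Window centers are drawn inside [w, 1 − w] so the true breadth
  (mean clipped window width 2w) is realized, not censored. A taxon is
  present in a sample iff every variable falls inside its window, thinned
  by a Bernoulli detection probability `detection = 0.9`.
* **Module catalog**: 5 strategies × 11 modules = 55 modules, 4 steps per
  module, `kos_per_step = 1` (one enzyme per step, the most common shape
  in curated catalogs; AND-complexes and alternatives are still exercised
  by unit fixtures and the parser supports them fully). KO universes are
  disjoint across modules so planted effects do not leak between modules.
* **Genomes**: each KO of each module is carried with probability
  `logistic(alpha + beta_m · b)`, with `gene_alpha = −3.0` (baseline
  prevalence ≈ 5%, matching the sparsity of single-genome KO annotation)
  and planted slopes `beta_m = +2` on 60% of modules, of which 20% are
  flipped to −2; the remaining 40% have no effect. Genome size is
  2 Mb + 1 kb per gene copy; GC ~ N(0.55, 0.05) clipped; CDS =
  size / 1000.
* **Phylogeny**: a Yule (pure-birth) tree over the taxa, with an optional
  Brownian trait (rate `sigma2`) for signal calibration.

Randomness: every generator consumes an independent stream derived as
`SeedSequence([seed & 0x7FFFFFFF, stream_label])`, so consuming one
stream never perturbs another and all derived seeds stay below 2^31.

**Realism limits.** Presence is a hard tolerance window (no abundance, no
dispersal limitation, no species interactions); detection error is
homogeneous; environmental axes are uniform and, by default,
uncorrelated; module KO universes are disjoint (real pathways share
enzymes); the genome model ties gene content to breadth directly rather
than through the phylogeny, so the tree carries signal only for the
Brownian trait, not for gene content. These choices make ground truth
exact and recovery attributable, at the cost of ecological texture.

## Genome-derived traits

A module definition is parsed from `steps ; separated`, `alternatives |
separated`, `AND-complex subunits + separated`. Completeness is the
fraction of steps satisfied, where a step is satisfied when the genome
carries every KO of at least one alternative. Binary presence is the
any-module-gene indicator (used by the GLM screen, which models presence
rather than completeness). Copy numbers do not affect either statistic.

## Trait screen

Per ecosystem, presence of each trait across taxa is regressed on niche
breadth with a binomial GLM (logit link; statsmodels IRLS, max 50
iterations) and a two-sided Wald test of the slope. Degenerate designs
are flagged, never silently fit: constant predictor → error; single-class
response → not-converged with NaN statistics; complete separation
(statsmodels separation error/warning, non-convergence, or |slope| > 15
on the unit-breadth scale) → a `separation` flag that excludes the fit
downstream. Monomorphic traits are skipped with a recorded reason.
Benjamini–Hochberg adjusted p-values are reported per ecosystem.

The consensus filter retains a trait when at least `min_ecosystems = 2`
ecosystems show p < 0.05 with the same slope sign; separation-flagged or
non-converged fits never count toward the quorum.

PERMANOVA treats breadth as a continuous covariate: the squared Jaccard
(binary profiles) or Bray–Curtis (counts) distance matrix is
Gower-centered to G, the hat matrix H comes from the intercept+covariate
design, R² = tr(HGH)/tr(G), pseudo-F = tr(HGH)/(tr((I−H)G(I−H))/(n−2)),
and p is by permutation of taxon labels with `p = (1 + #{F ≥ F_obs}) /
(1 + n_perm)`. For n ≤ 8 an exhaustive mode enumerates all n!
permutations and the identity counts in both numerator and denominator.
Numerically, tr(HGH) = tr(GH) is computed as the trace of
`(X'X)⁻¹X'GX` (2×2), so each permutation costs one small solve instead of
an n×n product.

## Life-history statistics (mLHS)

* `average_mlhs` is the mean completeness over **all** strategy-mapped
  modules — a module-level mean, deliberately distinct from the mean of
  strategy means (both are emitted, for comparison).
* `evenness_mlhs` is the Pielou evenness J = −Σ pₖ ln pₖ / ln K of the
  strategy-level mean completenesses, with pₖ the normalized means and K
  the number of mapped strategies — including strategies whose mean is
  zero, since an absent strategy is information about unevenness. J is
  undefined (NaN) when the means sum to zero; downstream correlations
  exclude such taxa pairwise and error when fewer than three usable taxa
  remain.
* Trait-space PCA operates on the standardized (correlation) matrix by
  default — completeness values share a scale but not a variance — via
  SVD of the centered/scaled matrix. Each PC is oriented so its
  largest-magnitude coefficient is positive; PC1 loadings are reported as
  the Pearson correlation of each module with the PC1 score.
* Module clustering uses 1 − pairwise Spearman ρ as distance, Ward
  linkage, and chooses K in 2..k_max by maximal mean silhouette width
  (ties toward smaller K). A `low_confidence` flag marks best silhouettes
  below 0.25. Constant modules are dropped with a warning before
  clustering (constancy is detected by zero range, robust to float
  round-off).

## Phylogenetic signal

Blomberg's K is computed from the Brownian covariance matrix V of shared
root-to-MRCA path lengths:

K = (MSE₀/MSE) / [(tr V − n/(1'V⁻¹1)) / (n − 1)],

with MSE₀ the variance of tip values about the GLS mean and MSE the
V-weighted residual mean square. The implementation was validated exactly
against an independent R implementation (phytools `phylosig`) on a fixed
instance.

Significance permutes tip labels and compares the variance of
phylogenetically independent contrasts, `p = (1 + #{var_perm ≤ var_obs})
/ (1 + n_perm)`. Contrasts are linear in tip values with tree-only
weights, so a precomputed (n−1)×n contrast matrix reduces each
permutation to one matrix–vector product.

Numerical choices: polytomies are resolved to bifurcations; zero-length
branches (which Yule simulators and real trees both produce, and which
make V singular) are perturbed by 1e-8 × tree height with a warning
rather than rejected; trees are cloned before modification. K is
invariant to affine trait transforms and branch-length rescaling, and the
test suite asserts both.

The Mantel-style diagnostic correlates upper-triangle patristic distance
with |Δ breadth|, with significance from label permutations on the
two-sided |r|; an exhaustive mode enumerates all n! permutations.

## Pipeline

`RunConfig` is a flat declarative dataclass (YAML-loadable; unknown keys
rejected by name). `run_pipeline` executes simulate/load → breadth →
genome traits → screen + consensus → PERMANOVA → mLHS/trait space →
phylogenetic signal, writing one TSV per result with 12 significant
digits (`%.12g`, `NA` for missing, `\n` line endings) so reruns are
byte-identical. The manifest records the config, its SHA-256, the seed,
the package version and per-output row counts. Stage failures are wrapped
in `PipelineError` naming the stage and the offending input.

## Parameter defaults, in one place

| parameter | default | rationale |
|---|---|---|
| `min_occupancy` | 2 | a single occurrence has no range |
| standardization scope | per_ecosystem | ranges measured against habitat-local variation |
| detection | 0.9 | high but imperfect detection |
| `gene_alpha` | −3.0 | ≈5% baseline KO prevalence, matching annotation sparsity |
| `beta_positive` | 2.0 | moderate, recoverable effect on the logit scale |
| effect modules | 60% (20% negative) | majority positive with a planted minority of negatives |
| `kos_per_step` | 1 | single-enzyme steps dominate curated catalogs |
| screen alpha | 0.05 | conventional; BH column provided for FDR control |
| `min_ecosystems` | 2 | cross-habitat consensus with three ecosystems |
| separation slope | 15 | |slope| > 15 on a [0,1] predictor is numerically divergent |
| `n_perm` | 999 | p resolution 0.001 at acceptable cost |
| `k_max` | 10 | silhouette search bound |
| low-confidence silhouette | 0.25 | conventional "weak structure" boundary |
| zero-branch epsilon | 1e-8 × height | smallest perturbation that keeps V invertible |

## Limitations

* The breadth index conflates occupancy with breadth: rare-but-scattered
  taxa and common taxa both score high; it is a descriptive range, not a
  niche model.
* The GLM screen tests marginal associations; correlated modules (shared
  latent breadth effect) are all detected, with no conditional analysis.
* PERMANOVA R² on binary Jaccard profiles is small by construction when
  most profile variance is noise; interpret relative to its permutation
  null, not as variance explained in the ANOVA sense.
* Blomberg's K assumes an ultrametric-ish Brownian null; heavily
  non-clocklike trees shift its calibration.
* The silhouette criterion prefers compact spherical clusters in
  Spearman-distance space; gradually varying module sets yield
  `low_confidence` selections, which the flag reports rather than hides.
* Synthetic defaults are desk-scale; power figures measured on them do
  not transfer to survey-scale data.
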