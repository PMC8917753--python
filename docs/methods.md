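# Methods

This note documents the models, numerical choices and known limitations of
`omicpred`, in the spirit of the methods documentation of mature
statistical-genetics packages.

## Mixed models and heritability

Replicated phenotypes follow the two-way model

    y_ijk = mu + E_j + G_i + (GxE)_ij + e_ijk

with environments, interactions and residuals random.  Adjusted entry
means treat genotype as fixed and are the GLS estimates at the REML
variance components, with their full variance-covariance matrix `C`.
Single-environment data (greenhouse metabolites) reduce to
`y_ik = mu + G_i + e_ik`.  Genetic variance is estimated from the same
model with genotype random, and entry-mean heritability is

    H^2 = sigma2_G / (sigma2_G + nu_bar / 2),

where `nu_bar` averages `C_ii + C_jj - 2 C_ij` over all unordered genotype
pairs — the literal "mean variance of a difference between two adjusted
entry means".  A design-based approximation would be an alternative
reading; the all-pairs average is exact for any design and coincides with
the familiar closed forms in balanced data (e.g. `nu_bar = 2 sigma2_e / r`
for r replicates in one environment).

**REML implementation.**  The restricted log-likelihood is assembled from
explicit design matrices.  With `H = I + Z diag(s2_k/s2_e) Z'`, all
crossproducts (`Z'Z`, `Z'X`, `Z'y`, ...) are precomputed once, so each
likelihood evaluation costs one q x q Cholesky factorization (q = total
random-effect levels, ~180 for 22 genotypes x 7 environments) via the
Woodbury identity.  The optimizer is L-BFGS-B over `log sigma2_e` and the
component variances bounded at zero (constrained REML — negative estimates
are truncated at the boundary, so some metabolites legitimately get
H^2 = 0), with a small multi-start grid to avoid local optima.  The
implementation agrees with `lme4::lmer` to five significant digits on
crossed-design test data.  Exact-fit data (noiseless simulations) make the
restricted likelihood unbounded in `sigma2_e`; this case is detected by a
saturated least-squares fit and handled by sequential least-squares
attribution of the realized effects, which reproduces the noiseless-limit
estimates.

**Estimator behaviour at n = 22.**  `H^2` is a ratio of noisy estimates;
at 22 genotypes the per-replicate spread is substantial (sd ~0.1-0.2 for
mid-range targets) with a small negative Jensen-type bias.  Averaged over
100 simulated panels the estimator stays within +/-0.02 of targets across
0.3-0.9, which is what the recovery tests assert (tolerance +/-0.05).

## Kernels

`G = W* W*^T / m`, columns of `W` centered and scaled to unit *population*
variance (divisor n).  The divisor is a convention choice (the source
material for this analysis style leaves it unstated); population variance
makes `trace(G) = n` exactly and the mean diagonal 1, the common GBLUP
normalization, and any affine recoding of a feature leaves `G` unchanged —
hence the `{0,1}` homozygous genotype coding is without loss of
generality.  QC precedes kernel construction: features with missing rate
strictly above 0.2 and features monomorphic among observed entries are
dropped; surviving gaps are mean-imputed.

ePAV calls per gene-tissue: expression exactly 0 is absent; values in the
open interval `(0, 0.1 * max)` get no call; `0.1 * max` itself is present
(the ambiguity condition is a strict inequality on both sides).  The
across-tissue combination rule is this package's own: present if present
in any tissue, absent if every available call is absent, otherwise NA;
genes observed in a single tissue keep that tissue's call.  The precise
rule used in the literature this emulates is described only in cited prior
work, so this is flagged as an interpretation; it preserves the observed
behaviour that the combined gene set is larger than either tissue's but
smaller than their disjoint union.

SIFT partitioning is exact at the threshold: score <= 0.05 deleterious,
> 0.05 tolerant; unscored variants are excluded from both subsets and
reported.

## GBLUP and cross-validation

Single-kernel GBLUP is fitted by spectral REML: after eigendecomposition
of the training kernel, the restricted likelihood of the variance ratio
`lambda = sigma2_e / sigma2_u` is a cheap one-dimensional function,
minimized on a 61-point log grid followed by bounded Brent refinement over
`log lambda` in [-12, 12].  The strictly positive lower bound on `lambda`
is what regularizes the rank-deficient centered kernels at n <= 22; no
diagonal jitter is added, which keeps hold-out predictions identical (to
< 1e-8) to the equivalent ridge regression on the standardized features
with penalty `m * lambda` — an identity the test suite checks on random
instances.  Hold-out samples are predicted by the BLUP conditional mean
`mu + G_test,train (G_train,train + lambda I)^-1 (y - mu)`.

Cross-validation uses random partitions into five folds with sizes
differing by at most one; `lambda` is re-estimated inside every training
fold, so no information leaks from hold-out samples.  Replicate r draws
its partition from seed `base_seed + r`, and the same partitions are
reused for every kernel and weight vector evaluated under the same
settings.  This pairing is a design choice (the emulated protocol is
silent on it): it makes vertex weight vectors reproduce single-kernel CV
bit-for-bit and sharply reduces Monte-Carlo noise in comparisons.
Constant prediction vectors (infinite-shrinkage fits) get ability 0 with
a warning rather than an undefined correlation.

The weight grid enumerates all compositions of 1 on the step lattice in
exact rational arithmetic (286 vectors for four kernels at step 0.1).
Ties at the grid optimum are broken toward the fewest nonzero weights,
then lexicographically — the emulated analysis reports unique optima, so
the tie-break matters only in degenerate symmetric cases.

## Dataset similarity

Each layer's configuration is its top-k PCA scores (k = min(n-1, 10); the
retained dimension is unstated in the emulated analysis) of the
column-standardized matrix, with a deterministic sign convention.  GPA
iteratively centers, rotates (reflections permitted) and isotropically
scales the configurations to their consensus under the constraint that the
total sum of squares is preserved, until the consensus residual changes by
< 1e-10 (max 100 sweeps).  Pairwise similarity is the Procrustes
correlation `1 - m^2`; dissimilarity `1 - similarity = m^2` lies in [0, 1]
and matches `scipy.spatial.procrustes` on pairs.  PCoA is classical
scaling of `-1/2 J D^2 J`; negative eigenvalues (the GPA and
correlation-based dissimilarities are not guaranteed Euclidean) are
dropped with a warning and percent variance is reported over the positive
spectrum — no Cailliez correction, the simplest defensible choice, and the
output states what was dropped.

Predicted-value distance: per CV replicate, hold-out predictions of all
folds are concatenated into one vector per predictor; the distance is
`1 - r` (in [0, 2]) and the element-wise median over replicates is
embedded by PCoA.

## 3'end emulation

Windows are the last `N` bp of the unspliced gene span, strand-aware,
clamped for genes shorter than `N` (windows are nested in `N` by
construction, and so are the variant subsets).  The emulated protocol
gives no mechanism for "measuring" expression on the truncated genes; this
package models it openly as Poisson read thinning: full-length read count
~ Poisson(depth * GE * L / 1000), uniform read placement, binomial
thinning into the window, then re-normalization by window length — which
makes the re-quantified value unbiased for the original (checked by Monte
Carlo against the `min(N, L)/L` closed form).  Sequencing error, PCR
duplication and real 3' coverage-bias profiles are out of scope.  At low
read depth the thinning noise is material and windowed kernels can drift
from the baseline; the default depth (50 reads per kb per FPKM unit)
deliberately keeps this visible.  `N = inf` (or None) is a sentinel that
bypasses truncation entirely and reproduces baseline abilities exactly
under shared seeds.

## Synthetic panel

The generator emulates the study design it is meant to exercise: 23
inbreds by default (22 in the analysis drivers), seven environments with
ten replicates, metabolite quadruplicates, trait heritability targets
{LA: 0.91, PH: 0.83, HT: 0.90}, metabolite targets uniform on [0, 0.98],
and ~12% deleterious variants.  Feature counts (hundreds of variants and
genes) are scaled down from the 10^4-10^5-scale real layers; the kernel
estimators are insensitive to m beyond a few hundred, and every analysis
then runs in seconds.  Specifics:

- Genotypes are `{0,1}` homozygous, in within-gene linkage blocks
  (variants copy a shared gene haplotype with probability 0.9).
  Deleterious variants get SIFT-like scores <= 0.05 and effect sizes with
  sd 1.0 versus 0.2 for tolerant ones, so the deleterious kernel carries
  more signal — by construction, which the CV results reflect.
- Expression is `softplus(cis effects + sparse trans effects + tissue
  shift + Gaussian noise)`; transcripts are a Dirichlet split of the gene
  value, so gene expression equals the sum of its transcripts exactly.
  A fraction of (inbred, gene) pairs is zeroed with probability decreasing
  in the gene's genetic value, giving the ePAV layer predictive signal.
- Metabolites are sparse linear combinations of leaf expression,
  standardized so that with r replicates the entry-mean heritability
  equals the drawn target exactly in expectation (genetic variance h,
  residual variance r(1-h)); a target of exactly 1 raises an error, being
  unreachable with finite replicates.
- Phenotypes are balanced (all genotypes in all environments, equal
  replication) rather than an augmented field design: the estimators under
  test are design-agnostic, and balance makes closed-form oracles exact.
  The noise calibration sets `nu_bar/2 = sigma2_G (1 - h)/h`, split evenly
  between the interaction term and the residual; the even split is a
  modeling choice, and sigma2_E is set equal to sigma2_G (it cancels from
  both entry means and H^2).
- One global seed fans out to fixed per-stage offsets, so identical
  configurations give bit-identical output and stages are individually
  reproducible.

What the generator does *not* emulate: the joint distribution of real omic
layers (unknowable from the emulated study), epistasis and dominance (only
additive effects), field spatial trends, sequencing artifacts, and
metabolite annotation structure.  Passing recovery tests therefore
demonstrate correctness of the estimators under the stated generative
model, not performance claims about any real panel.

One interaction deserves emphasis: because ePAV, gene- and
transcript-level expression all derive from the same latent expression,
their kernels are strongly coupled — as in real data, where the analogous
layers cluster together.  The grid-search recovery experiment is designed
around this: its ePAV and metabolite kernels come from the leaf tissue
while the causal phenotype lives in the seedling transcript space, the
presence/absence zero-rate is lowered to 0.03 so the zero pattern (which
every derived layer shares through the genetic values) does not dominate
the transcript kernel, and the phenotype is drawn in the transcript
kernel's column space (`y = G_TE alpha`, i.e. an exact combination of the
standardized transcript features concentrated on the kernel's leading
directions).  With fully coupled layers and a diffuse phenotype the
optimizer can legitimately prefer a derived layer's cleaner kernel; that
is a property of the data, not a defect of the search.

## Problem sizes

Analysis drivers default to a 22 x 400-variant, 80-gene, 40-metabolite
panel with 50 CV replicates, and the acceptance script to 20-30 CV
replicates and 20 heritability replicates per trait; these sizes keep each
script in the minutes range while leaving all qualitative conclusions
unchanged relative to larger runs.
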