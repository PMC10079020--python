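# Methods

This note documents the models, numerical choices and limitations of the
`cranioforge` pipeline in enough detail to audit or extend it.

## Bite force

The incisor strength index `Zi = ap² · ml / 6` (mm³) treats the incisor
cross-section as a rectangular beam of antero-posterior depth `ap` and
medio-lateral width `ml`; it is a section modulus, i.e. a structural proxy
for the maximal load the tooth can bear, not an in-vivo force. Calibration
to log₁₀ Newtons uses the fixed cross-Rodentia line
`log₁₀ F = 0.566 · log₁₀ Zi + 1.432` (`CalibrationParams`; both constants
overridable).

The bite force quotient is the residual of an OLS fit of `log₁₀ F` on
`log₁₀ body mass` **refit on each analyzed sample** — the published
coefficients (0.3849, 0.6970, R² = 0.419) are kept only as the reference
constant `REFERENCE_BFQ_REGRESSION`, because the residual definition is
sample-specific. Consequences worth knowing:

* BFQ sums to zero and is exactly orthogonal to log₁₀ mass (OLS normal
  equations), and is invariant to adding a constant to every log force.
* Because the calibration is affine in log₁₀ Zi, BFQ equals
  `0.566 ×` (residuals of log₁₀ Zi on log₁₀ mass) — a useful identity for
  testing.
* If group membership correlates with body mass, the pooled regression
  absorbs part of the group effect into its slope and the group contrasts of
  BFQ are attenuated or reordered. This is a property of the residual
  method itself; the synthetic generator therefore uses mass distributions
  that are identical across groups, so that generator truth is identifiable
  (see below).
* Specimens missing mass are excluded from the BFQ step with a logged count;
  there is no imputation.

## Suture length ratio

`LR = Σ segment lengths / ‖last − first‖` on the traced polyline. LR is
invariant under rigid motion and uniform scaling and under polyline
refinement (inserting collinear midpoints), so tracing units are arbitrary.
Closed (loop) traces are rejected — the chord is degenerate. Curved SVG
path commands (`C`, `Q`, `A`, relative forms) are rejected rather than
approximated so that no hidden arc-length error enters the statistic; curves
must be polyline-sampled upstream. Side bookkeeping (right side preferred,
left when damaged) is carried as metadata and does not enter the statistic.

## Superimposition

Partial generalized Procrustes: each configuration is centred, scaled to
unit centroid size, and rotated to the iteratively re-estimated consensus by
SVD orthogonal Procrustes with `det(R) = +1` — reflections are never fitted,
since mandible images are flipped to one side during digitization.
Convergence is declared when the RMS change of the consensus drops below
`tol` (default 1e-8, `max_iter` 100). There is no tangent-space projection:
shape variation at this scale is small enough that the difference is below
test tolerances, and PCA operates on the Procrustes coordinates directly.

The final orientation is canonicalized — the consensus is rotated onto its
principal axes with the 180° ambiguity broken by the sign of the third
moment of the x coordinates — so GPA output is reproducible and invariant
(to tolerance) under arbitrary similarity transforms of the input, rather
than depending on the orientation of the first specimen.

### Bending energy and sliding

The thin-plate-spline bending-energy matrix of the consensus uses kernel
`U(r) = r² log r²` (with `U(0) = 0`), `L = [[K, Q], [Qᵀ, 0]]`, `Q = [1 x y]`;
`B` is the upper-left block of `L⁻¹`, symmetric PSD with a 3-dimensional
affine null space. A condition-number guard (`cond(L) > 1e14`) rejects
(near-)collinear references.

Semilandmarks slide along tangent directions estimated from neighbour
chords (interior: chord between the two curve neighbours; curve endpoints:
chord to the single neighbour). Per specimen, the slide amounts `t`
minimize `(v + U t)ᵀ B̃ (v + U t)` where `B̃` is `B` expanded over x and y
and `U` is the tangent design restricted to semilandmarks; fixed landmarks
are immobile; the linear system is solved by least squares (the minimum-norm
solution handles the singular no-displacement case). Sliding is against the
current consensus, followed by a full GPA re-fit, for `n_cycles` (default
3) cycles. Energy bookkeeping brackets the slide step itself (same
consensus, same `B`), where the least-squares property guarantees
non-increase; after the GPA re-fit the consensus changes and per-specimen
energies are not comparable across cycles. No bounds are imposed on slide
magnitudes; the maximum |t| is logged (`max_slide_`) so runaway sliding is
visible. Tangents from neighbour chords (not spline derivatives) are
standard, stable for 45 semilandmarks on smooth 2-D curves, and make the
"displacement along the tangent is exactly recoverable" property testable.

## PCA and axis significance

PCA is an eigendecomposition of the covariance matrix of column-centred
data (for the five suture LRs this is deliberate: all five share one
dimensionless scale, so no correlation-matrix rescaling). Axis signs follow
a deterministic convention — the largest-magnitude loading of each axis is
positive. Rows with missing cells are dropped with logged ids.

Axis significance is Monte Carlo: each column is permuted independently
(destroying inter-variable covariance but preserving margins), eigenvalue
proportions are recomputed, and
`p_k = (1 + #{proportion*_k ≥ proportion_k}) / (n_perm + 1)` (default
n_perm = 999). On isotropic Gaussian data the per-axis rejection rate at
0.05 calibrates to 0.05 (checked at 200×10 over 50 replicates).

## Procrustes ANOVA

Sequential (Type I) decomposition in the fixed order group, sex, size,
group:size, sex:size (matching the study's table layout), where size is
log₁₀ centroid size. For a multivariate response, each term's SS is the
trace difference of residual cross-product matrices of nested fits — hence
every statistic is invariant to rotations of the response space, which is
what makes "ANOVA on Procrustes coordinates" and "ANOVA on PC scores"
consistent. `F = MS_term / MS_resid` with the full-model residual.

Inference is residual randomization (RRPP): for each term, residuals of the
reduced model (all preceding terms) are row-permuted and added back to the
reduced fit, and the term's F is recomputed;
`p = (1 + #{F* ≥ F}) / (n_perm + 1)`, default n_perm = 999. The effect size
`Z` is the standard deviate of log F within the log-transformed permutation
distribution (observed included); the alternative reading — normal quantile
of the empirical position — differs only in the extreme tail where the
empirical position saturates. A numerically constant response returns all
zero SS and F with p = 1 rather than 0/0 noise. Aliased terms raise with
the offending term named.

The Procrustes ANOVA of mandible shape is run on PC1+PC2 scores by default
(mirroring the study's table); the full-coordinate response is equally
supported since the trace-based SS is basis-invariant up to the discarded
axes.

Pairwise group contrasts use the Euclidean distance between group mean
vectors (= Procrustes distance between mean shapes for aligned
coordinates), label-permutation p-values, and Holm correction by default
(Bonferroni and none available). Groups with fewer than 2 members are
excluded with a warning.

## Univariate ANCOVA

Parametric sequential least squares via statsmodels (`anova_lm`, Type I) in
the order group, remaining factors, covariates, with UNKNOWN-sex specimens
excluded (logged) whenever sex is modelled. Adjusted group means are
least-squares means: predictions at the covariate mean, balanced over the
other factor's levels. Post-hoc contrasts are t-tests on adjusted-mean
differences (contrast vector = difference of averaged design rows, residual
df), Holm-corrected. Permutation inference is reserved for the
multivariate shape data; parametric p-values match mainstream ANCOVA
practice for the univariate traits.

## Morphospace overlap

Groups are modelled as multivariate normal in (PC1, PC2, log₁₀ centroid
size). Under the noninformative prior `p(μ, Σ) ∝ |Σ|^−(d+1)/2` the
posterior is `Σ ~ IW(n−1, centred cross-products)`, `μ|Σ ~ N(x̄, Σ/n)`.
The niche region of B at level α (default 0.95) is the Mahalanobis
ellipsoid at the χ²_d(α) quantile; overlap(A → B) is the Monte Carlo
probability (default 10,000 draws) that a draw from A's distribution lands
in it. The posterior distribution of overlap uses 3,000 posterior
iterations by default; within an iteration one (μ, Σ) is drawn per group
and each group's Monte Carlo sample is reused against every other group's
region, so all pairs within an iteration share parameter draws.

Numerical notes: membership is decided from squared Mahalanobis distances
compared to the χ² threshold, so with a fixed seed overlap is monotone
increasing in α; the construction is invariant under a common affine
transformation of all groups (exactly for the region test, to Monte Carlo
error for the sampled points). The α level refers to the niche region; the
95% reported with each pair is the credible interval of the overlap
distribution — two different 95%s. For an identical pair of groups the
posterior mean overlap approaches α from below with finite-sample bias of
order d/n.

## Synthetic data

The generator emulates the study's structure with five groups of
n = 14/10/19/13/14 and per-stage ground truth serialized beside every
dataset:

* **Bite force:** target `log₁₀ F` = reference allometric baseline
  (0.3849·log₁₀ mass + 0.6970) + group offset + sex effect + N(0, 0.05);
  inverted through the calibration to Zi and to (ap, ml) at a fixed aspect
  ratio 0.55. Default offsets (−0.09, −0.15, 0.03, −0.03, 0.09 log₁₀ N for
  AlloDoug/HZDoug/Hybrid/HZRed/AlloRed) give red > Douglas, allopatric >
  hybrid-zone within species, hybrids near hybrid-zone reds — distinct
  values with gaps ≈ 2–3 adjusted-mean standard errors, so rank recovery is
  expected but not trivial. Mass is N(220 g, 20 g) in **every** group: with
  group-correlated mass the pooled residual step itself confounds group and
  slope (see Bite force), and the generator's purpose is validation against
  known truth.
* **Sutures:** per (specimen, suture) an LR target = group×suture mean + 
  N(0, 0.04); a sinusoidal polyline along a unit chord with the amplitude
  solved by root finding so the polyline LR meets the target (to ~1e-6),
  then randomly rotated/scaled/translated. Default LR means make the
  premaxillofrontal, maxillofrontal and sagittal sutures group-informative
  and the nasofrontal and coronal flat, as in the study system.
* **Mandible shape:** a deterministic 60-point mandible-like template (15
  fixed, 45 semilandmarks on curves of 20/15/10) — topologically plausible,
  not anatomical. Group mean displacement = `shape_effect_scale ×` a
  group-specific combination of two fixed smooth unit-norm fields (Douglas
  and red ends opposite, hybrid-zone groups pulled inward, hybrids central);
  allometric displacement = `allometry_slope × (log₁₀ CS − mean)` along the
  first field; isotropic landmark noise (sd 0.004 Procrustes units); then a
  random similarity transform so GPA is exercised. Defaults:
  `shape_effect_scale = 0.02` (5× landmark noise — clear group separation,
  allopatric pairs nearly disjoint, adjacent groups broadly overlapping) and
  `allometry_slope = 0.3` (within-group allometric signal comparable to
  landmark noise, so the ANOVA size term is detectable but not saturated).
* **Admixture:** Q uniform in (0.01, 0.10) for Douglas groups, (0.90, 0.99)
  for red groups, `0.1 + 0.8·Beta(2.5, 2.5)` for hybrids (mean 0.5, range
  within the open hybrid interval).

What the generator does **not** emulate: measurement error correlated
across traits within a specimen, damaged/missing-data patterns, allometric
curvature, asymmetry, interrupted sutures, or real squirrel anatomy. A
passing pipeline on synthetic data therefore demonstrates the statistical
machinery — estimator correctness, calibration, ground-truth recovery — not
biological validity on real specimens.

## Problem sizes used in validation

The validation suite uses the study-sized default dataset (70 specimens)
and these simulation sizes, chosen to make each check informative at
interactive cost: 2001-vertex semicircle for the LR oracle; 10⁶-step
rotation grid for the Procrustes-distance oracle; 200 replicates × 199
permutations for permutation-null uniformity; 50 replicates of 200×10 for
axis-test calibration; 3,000 posterior × 10,000 MC draws at n = 300/group
for overlap calibration (tolerance 0.02 ≈ finite-sample bias d/n plus 3
Monte Carlo SE); 200,000 draws for the 1-D closed form (tolerance 3 MC SE);
20 seeds of the default dataset for ground-truth recovery.

## Known limitations

* 2-D landmarks only; no surface/patch semilandmarks; no
  minimum-Procrustes-distance sliding (bending energy only).
* No tangent-space projection; at large shape variance PCA on Procrustes
  coordinates and on tangent coordinates would diverge.
* Niche-region overlap assumes multivariate normality of each group; no
  kernel or hull alternatives.
* The univariate ANCOVAs assume homoskedastic normal errors (no Welch
  correction); permutation inference is available only through the
  Procrustes-ANOVA route.
* Suture interruption is an input-side exclusion, not detected from traces.
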