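# Methods

This note documents the models, estimators and numerical choices behind
`tactsel`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one defensible option existed.

## The inferential target

Two male reproductive tactics (courter, sneaker) share traits — standard
length, body depth, sword length, and geometric shape descriptors. The
question is whether selection through reproductive success is *tactically
antagonistic*: do the tactics have different fitness optima for a shared
trait, and is at least one tactic displaced from its optimum? Both
conditions together indicate the potential for intralocus tactical conflict
(a shared genetic architecture preventing each tactic from reaching its own
optimum; demonstrating the conflict itself additionally requires
between-tactic genetic correlations, which are outside this package's
scope).

Operationally, with relative fitness `w = W / mean(W)` over **all** males
and traits standardized to zero mean and unit variance over **all** males:

- selection differential *s*: OLS of `w` on one standardized trait plus ART
  and ART×trait. Under the default sum-to-zero ART coding (courter +1/2,
  sneaker −1/2) the trait main effect is the across-tactic **average
  slope** — its significance means at least one tactic is off its optimum —
  and the interaction is the **slope difference** — its significance means
  the optima differ.
- linear gradients **β**: the same, with all traits entered jointly and no
  quadratic terms (quadratic terms would contaminate β when traits are not
  multivariate normal).
- quadratic gradients **γ**: linear + squared terms; the fitted quadratic
  coefficient is **doubled** in reports because the regression coefficient
  is half the curvature of the fitness surface. Permutation p-values are
  computed on the fitted (undoubled) coefficient — doubling is purely a
  reporting transform. Cross-product (correlational) terms are off by
  default and available via a flag.
- per-tactic follow-up models (`w ~ z` within tactic, `w` still
  population-relative) are fitted when the interaction is significant, and
  give each tactic's direction of selection. A flag allows re-standardizing
  traits within tactic for these follow-ups; the default keeps
  population-wide z.

Zero-fitness males are always retained: refusing to drop them is enforced
in `prepare()`, since males that sired nothing carry most of the
information about directional selection.

## Permutation inference

Model residuals from count-based fitness are far from normal, so parametric
p-values are not trusted. Instead relative fitness is shuffled across the
whole male population (traits and tactic labels stay attached to
individuals), the model is refitted, and the observed coefficient is
compared with its permutation null; 9,999 permutations by default,
seed-reproducible, identical permutations used for all terms of one model.

The **default p-value is two-sided**: `p = #{|b*| ≥ |b|} / n_perm`. By
exchangeability this is exactly calibrated at any α whatever the shape of
the null distribution. The sign-directed single-tail count (exceedances
above the estimate when positive, below when negative), common in selection
studies, is available as `p_method="directional"` — but note that for a
symmetric null it rejects at roughly 2α when compared against α, and the
package intentionally does not use it for inference. Measured type-I rates
under a null generator: ~0.05 for the two-sided default, ~0.10–0.13 for the
directional variant at α = .05. Ties count as exceedances (conservative);
a degenerate shuffle (all-equal fitness) therefore yields p = 1. A
`plus_one` flag switches to the conservative `(b+1)/(m+1)` estimator.

## Parentage model

**LOD score.** For offspring *o* with known dam *d* and candidate sire *c*,
per locus `L1 = (1−e)² T(g_o|g_d,g_c) + (1−(1−e)²) P_HW(g_o)` and
`L2 = (1−e)² T(g_o|g_d) + (1−(1−e)²) P_HW(g_o)`, with `T` the Mendelian
transition probability (random-male version integrates the paternal allele
over population frequencies) and `e` the per-genotype error rate;
`LOD = Σ ln(L1/L2)`. This "observed genotype is true with probability
(1−e)², otherwise a Hardy–Weinberg draw" mixture is a deliberate
simplification of the fully error-integrated categorical-allocation
likelihood: it keeps every score hand-computable, and preserves the two key
behaviors — a Mendelian mismatch is an absolute exclusion (LOD = −∞) only
at e = 0, and becomes a large finite penalty as e grows. Loci missing in
any of the three individuals are skipped; offspring typed at fewer than 2
loci (configurable) are not assigned.

**Delta and confidence.** Candidates are ranked by LOD;
`Δ = LOD₁ − max(LOD₂, 0)`, so a lone candidate still needs a positive LOD.
Exact ties at rank 1 are left unassigned (conservative fitness estimates).
Critical Δ values come from simulation: offspring are generated from random
dam × sire pairs under the observed allele frequencies, the true sire is
included in the candidate pool with probability `prop_sampled`, loci are
typed with probability `prop_typed`, genotypes are corrupted at the error
rate, and the threshold for each confidence level is the most inclusive Δ
cutoff at which the proportion of correct assignments still meets the
level (collapsing to 0 when accuracy holds over the whole sample).
Defaults mirror a field-study protocol: 10,000 simulated offspring, 92
candidates, 87% of sires sampled, 100% of loci typed, e = 0.01, levels
0.95/0.80.

**Locus QC.** The Hardy–Weinberg exact test runs a Markov chain over
genotype tables with allele counts fixed. The chain state is the
*slot-level* assignment of allele copies to individuals; under the HWE
conditional distribution every arrangement is equally likely, so the
symmetric swap proposal (one allele from each of two individuals) is always
accepted, and the induced distribution over genotype-count tables is
exactly `P ∝ 2^h / Π n_g!`. The p-value is the fraction of sampled tables
with conditional probability ≤ the observed table's. Chain defaults follow
the classic 1,000 dememorization / 5,000 batches / 1,000 iterations-per-
batch schedule; tests and the acceptance script use shorter chains
(hundreds of thousands of steps are unnecessary at these locus sizes — the
chain agrees with full enumeration on two-allele cases to MC error within a
few thousand steps). The LD test permutes one locus's genotypes across
individuals and compares genotype-class contingency chi-squares. Null
alleles use Brookfield's estimator 1, `r = (He − Ho)/(1 + He)` floored at
0, with He as Nei's gene diversity; exclusion probabilities use the
one-parent-known formula of Jamieson & Taylor.

## Morphometrics

GPA centers each configuration, scales to unit centroid size, and
iteratively rotates to the evolving consensus by least squares with
**reflections disallowed** (det +1 enforced); convergence at RMS consensus
change < 1e-8, max 100 iterations (results are insensitive below 1e-6).
Because the superimposition is only defined up to a global rotation, the
converged consensus is rotated to its **principal axes** with a
deterministic sign rule, which makes tangent coordinates invariant (to
1e-8) under arbitrary similarity transforms of the raw input — a property
the test suite asserts directly.

Semilandmarks slide along the chord between their neighbors by the scalar
that minimizes distance to the consensus (the Procrustes-distance
criterion, not bending energy), alternating with re-superimposition. The
summed squared distance to the consensus is recorded each pass and asserted
nonincreasing.

Tangent projection maps each aligned configuration `x` (unit norm) to
`c + (x − (x·c)c)` at the unit-norm consensus `c`: the consensus projects
to itself, the map is idempotent, and tangent distances agree with
Procrustes distances to < 1% in the small-dispersion regime the tests
cover. PCA is an eigendecomposition of the tangent-coordinate covariance
(n−1 denominator); axes with ≥ 10% of total variance are retained; each
eigenvector's largest-magnitude loading is made positive so signs are
platform-stable. Missing landmarks are estimated by a thin-plate spline
(kernel `r² log r`) fitted from the reference configuration's present
landmarks to the specimen's, which reproduces affine deformations exactly;
the reference defaults to the GPA consensus of complete specimens.

TPS files are read in the tpsDig dialect (`LM=`, coordinate lines, `ID=`,
`IMAGE=`, `SCALE=` applied multiplicatively); a `flip_y` option negates the
y-axis for image-coordinate files and is off by default because the
generator writes mathematical coordinates.

## The synthetic generator

The generator's defaults are the study conditions the pipeline is meant to
exercise: 36 courters, 44 sneakers, 43 dams; tactic trait means separated
by 11.2 mm (standard length), 4.5 mm (body depth) and 8.6 mm (sword), with
within-tactic SDs of roughly 7–17% CV and a common correlation structure
(SL–BD 0.6, SL–sword 0.4, BD–sword 0.3); mean fitness ≈ 6 offspring for
courters and ≈ 3 for sneakers (population ≈ 4); five microsatellite loci of
10 alleles with Dirichlet(3) frequencies, one locus carrying a 0.17
null-allele frequency, all with 0.01 typing error; 10-point fish-outline
consensus shapes per tactic (semilandmarks at points 2, 6, 9) with 0.15
unit isotropic landmark noise, then random rotation, translation and
log-normal scale per specimen.

Fitness is Poisson with a log link,
`λ = exp(a + βᵀz + ½ γᵀz²)`, which guarantees nonnegative integer
offspring counts including zeros. The ½ in the exponent makes the doubled
quadratic regression estimate agree with the surface's γ. The surface is
evaluated on standardized traits; `surface_scale` selects the scale:
`"tactic"` (default; z-scored by the male's own tactic's configured
moments — selection on relative trait value within tactic, appropriate
when tactic trait distributions barely overlap) or `"population"`
(z-scored by the analytic two-tactic mixture moments — the same scale the
selection module estimates on, so surface coefficients are directly
comparable to estimated gradients). `calibrated_intercept()` solves for
the intercept giving a desired mean fitness under either scale.

Offspring are assigned a uniformly random dam each; brood structure and
sperm storage are not modeled (they are irrelevant to the downstream
estimators — brood sizes come out multinomial with mean
total offspring / n_dams, ≈ 12 at the defaults). Founder genotypes are
drawn from the locus models with the null treated as an extra hidden
allele; offspring inherit one uniformly chosen allele per parent at the
*true* genotype level; null masking (heterozygote-with-null appears
homozygous, null/null fails to amplify) and per-allele frequency-weighted
typing error corrupt only the observed calls. The sword-extension flag
uses a fixed 12 mm visibility threshold that sits between the tactic sword
means.

What the generator does **not** emulate: multi-generation evolution,
anisotropic or landmark-specific digitizing error, allometry, linkage
between loci, age structure, and the survival ("invisible fraction")
component of selection. Passing tests therefore validate the estimators
under the stated sampling models, not the field-data idiosyncrasies those
models abstract away.

## Validation strategy and problem sizes

Every estimator is checked two ways: against closed forms or independent
library implementations on small instances (statsmodels normal equations
for all OLS estimates at 1e-10; scipy for Welch, chi-square and quantiles;
scikit-learn for PCA; full enumeration for the two-allele HWE test), and
against the generator's ground truth in parameter-recovery simulations.
The recovery experiment for antagonistic sword selection uses tactically
*homogeneous* trait distributions (both tactics share trait moments) so
that the generating coefficients (+0.5 courter, −0.3 sneaker) live exactly
on the analysis scale; with dimorphic distributions the population-scale
slopes are rescaled by σ_pop/σ_tactic and — at this package's default
SDs — the two tactics' contributions to the average slope cancel almost
exactly, which says something interesting about dimorphism but nothing
about estimator correctness. At 500 males per tactic over 200 replicates
the per-tactic differentials recover truth with |bias| < 0.01 (an O(1/n)
ratio-estimator effect, not a defect) and both conflict criteria are
flagged in ~100% of replicates.

Default problem sizes in the test suite and acceptance script (hundreds of
permutation replicates, 999-permutation fits, HWE chains of tens of
thousands of steps, ~1,000-offspring parentage experiments) were chosen so
Monte-Carlo error is small relative to the asserted tolerances while the
whole suite stays fast; all are parameters, and production analyses should
use the 9,999-permutation / full-chain defaults in `RunConfig`.

## Known limitations

- The LOD error model is the simplified mixture described above, not the
  fully integrated likelihood; with appreciable error rates its scores
  differ from categorical-allocation software in the third decimal, though
  rankings are extremely stable.
- Quadratic-gradient recovery under the Poisson log link is approximate:
  OLS estimates the covariance-based gradient, so tolerances are SE-based.
- The HWE chain reports a single p-value without a Monte-Carlo standard
  error; run it at the full schedule when the answer is borderline.
- Confidence-ellipse parameters assume approximate bivariate normality of
  group mean scores.
- Maternity is taken as known; maternity inference, parent-pair inference
  and sibship reconstruction are out of scope.
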