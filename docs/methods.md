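# Methods

This note records the modeling assumptions, default values, numerical
choices and known limitations behind `ebvselect`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pedigree machinery

Unknown parents are treated as unrelated, non-inbred members of the base
population; unknown-parent groups are not modeled. Generation numbers are
1 + max(parent generation) with founders at 0.

Inbreeding uses the Meuwissen–Luo recursion: A_ii = 1 + F_i is
accumulated as Σ_j L²_ij D_j over the ancestors of i, where D is the
Mendelian-sampling variance scalar (1 for founders, 0.75 − 0.25 F_known
with one known parent, 0.5 − 0.25(F_s + F_d) with both). The O(n²)
elementwise tabular method lives only in the test suite as an independent
oracle. A⁻¹ is assembled from Henderson's rules with the same D scalars,
so it is exact under inbreeding; tests verify A·A⁻¹ = I against the
tabular A.

Two inbreeding-rate conventions are provided because practitioners quote
both. The **endpoint** method, the default, is the plain difference of
cohort means divided by the span — this is the arithmetic behind
statements like "mean F rose from 3.4% to 16% over eight generations,
1.6 points per generation". The **classical** method standardizes each
step by the remaining heterozygosity, ΔF = (F_t − F_{t−1})/(1 − F_{t−1}),
which is the quantity that maps to effective population size via
Ne = 1/(2ΔF). At the inbreeding levels a managed colony tolerates
(F ≲ 0.2) the two differ by at most ~20%; both are reported by
`program_metrics`.

## Variance components (EM-REML)

The animal model is y = Xb + Za + e, Var(a) = A σ²ₐ, Var(e) = I σ²ₑ.
Updates are the classical EM-REML fixed-point iterations, evaluated on
the marginal (y-space) form with P the REML projection matrix and
H = ZAZ':

    σ²ₐ ← σ²ₐ + (σ⁴ₐ/q)(y'PHPy − tr(PH)),
    σ²ₑ ← σ²ₑ + (σ⁴ₑ/n)(y'PPy − tr(P)).

A fixed point satisfies the REML score equations y'PVᵢPy = tr(PVᵢ). A
single symmetric eigendecomposition of H per dataset makes each
subsequent iteration O(n p²), so replicated fits at n ≈ 2,000 cost a few
seconds each. H is obtained from the sparse A⁻¹ by a sparse LU solve for
the observed animals' columns, so the public interface needs only the
design and A⁻¹.

Defaults: initial values split the phenotypic variance evenly;
tolerance 1e−6 on the maximum relative parameter change; `max_iter` 200
(EM is slow near convergence — at n ≈ 2,000 the 1e−6 tolerance typically
needs 200–400 iterations, so convergence-critical callers pass
`max_iter=1000`; iterations are cheap after the eigendecomposition).
Non-positive updates are floored at 1e−8 and annotated. Estimation is
univariate; multi-trait genetic covariances are deliberately
*inputs* (see below), not estimated.

The 15% heritability screen is boundary-inclusive ("at least 15%") and
only converged fits pass.

## EBVs

Linear traits solve the mixed-model equations exactly: densely (Cholesky)
below 2,000 equations, by sparse LU above; both paths are checked against
an independent dense GLS oracle. Every pedigree member receives an EBV;
with no data the prior mean 0 is returned. Prediction-error variances
come from the inverse coefficient matrix (exact; computed in 512-column
blocks on the sparse path), giving accuracy r = √(1 − PEV/((1+F)σ²ₐ))
clamped to [0, 1] — an animal with no information has r = 0 exactly.
Percentiles use the strictly-lower convention: 100 × (#cohort members
with strictly lower EBV)/(cohort size), so ties do not raise a rank.

Multi-trait BLUP with *user-supplied* G and R covariance matrices is
provided for traits recorded on identical designs (same dogs, same fixed
effects), via the Kronecker-structured MME assembled densely. This covers
the practical use case of adding a correlated helper trait with known
covariances; general unequal designs are out of scope.

The threshold model treats a binary trait as liability l = Xb + Za + e
with e ~ N(0, 1) (residual fixed at 1 for identifiability; threshold at 0
with an intercept in b). Gibbs sampling alternates truncated-normal
draws of l (inverse-CDF method), a joint Gaussian draw of (b, a) from the
full conditional via dense Cholesky, and a scaled-inverse-χ² draw of σ²ₐ
(ν₀ = 4, scale anchored at the initial value; σ²ₐ can instead be fixed).
Chain defaults are 10,000 iterations, 2,000 burn-in, thinning 10; the
seed is mandatory. Tests use shorter chains (hundreds to a few thousand
iterations) to stay within the suite's time budget — posterior means at
those lengths are accurate to a few hundredths of a liability SD, which
the assertions account for. Effective sample sizes are computed with
arviz and returned as diagnostics.

## Selection index, candidates, matings

Standardized weight = relative weight / genetic SD, which makes each
trait's index contribution invariant to its measurement units (tested to
1e−12). An index whose relative weights do not sum to 1 triggers a
warning, not an error, since published eras are quoted in percents that
round. Dogs missing an index-trait EBV are excluded with a warning by
default (zero-imputation is available but biases ranks toward the mean).

Candidate selection takes the top-index dogs per sex (defaults 9 females,
3 males per round, matching monthly practice in large colonies) after
removing dogs carrying screening flags. Among *exactly tied* indexes
straddling the cut, the dog with lower mean kinship to the current
breeder pool wins — with discrete scores (ordinal phenotype selection)
these tie groups are large and the rule matters; with continuous EBVs it
rarely fires.

Mate allocation is greedy, mirroring described practice rather than a
global optimizer: dams in index order; for each dam the feasible sire
with minimal predicted litter F (= pair kinship), ties to the least-used
sire (the equal-stud-usage rule), then lexical id for determinism.
Feasibility = not previously bred together, neither dog affected, at most
one carrier in the pair, under the litter caps, under the optional
predicted-F cap. Caps default to 8 litters per sire and 4 per dam ("3 or
4" — 4 chosen, configurable). Unpaired dams are reported with reason
codes. Optimal-contribution selection is a documented non-goal. The
"complement weaknesses with strengths" pairing heuristic has no published
formula; it is not implemented beyond the index itself, and the mating
rationale field records the minimal-F choice instead.

## The synthetic colony

The simulator emulates a closed working-dog colony:

* **Demography.** Discrete, non-overlapping generations (the real colony
  overlaps years; discrete cycles are the testable idealization — with
  every breeder living one cycle, lifetime litter caps coincide with
  per-cycle caps). Default 30 litters/cycle with litter sizes Poisson
  (mean 6.8) truncated at ≥1, i.e. ~204 pups per cycle, matching the
  ~200-pups-per-year reference scenario; a 520-pup colony is a config
  change. The breeder pool is 15 males and 32 females per cycle — the
  published 38♂/82♀ pool of a 520-pup colony scaled to 200 pups.
* **Genetics.** Total phenotypic variance is normalized to 1 per trait,
  so σ²ₐ = h². Founder breeding values are multivariate normal with the
  configured genetic correlation matrix; offspring get the parent mean
  plus a Mendelian deviation with variance 0.5 σ²ₐ (1 − (F_s + F_d)/2),
  correlated across traits. The engine maintains the full relationship
  matrix incrementally (tabular rows), so F and pair kinships are exact;
  the analysis-side Meuwissen–Luo routine recomputes them independently
  and the self-consistency test requires agreement to 1e−12.
* **Phenotypes.** One record per dog per trait (repeat records are not
  simulated). Latent value = BV + optional year/sex shifts + N(0, 1−h²)
  residual; `ordinal5` cuts the latent value at standard-normal quintiles
  (5 = most desirable), `binary` thresholds it at the configured
  incidence. Year effects house scenario shocks (e.g. an environmental
  disruption raising fearfulness in one cohort).
* **Selection modes.** `random`, `phenotypic` (index weights applied to
  observed scores), `index` (weights applied to true breeding values —
  idealized truncation selection), and `ebv_index` (weights applied to
  BLUP EBVs refitted each cycle on all data so far, using the true
  variance ratios). The default trait is a single ordinal hip-quality
  trait at h² = 0.52, the reference program's published value.

What a green simulator-backed test does *not* establish: anything about
overlapping generations, frozen-semen imports, multi-breed pooling,
repeated phenotyping, maternal or litter environmental effects, or
genotype-by-year interaction — none are modeled.

### A note on BLUP selection and inbreeding

Under `ebv_index` selection with no family-level safeguard, the simulated
colony's inbreeding rate runs at roughly 2.5–3 points per generation:
BLUP EBVs are family-correlated, so truncation co-selects full sibs and
the realized number of contributing families collapses (a well-known
phenomenon in BLUP-selected populations). Real programs counter it by
explicitly favoring less-related candidates and spreading matings — the
kinship tie-break and equal-usage rules here, which for continuous EBVs
seldom bind. The ≤2-points-per-generation claim for the capped 200-pup
colony is therefore exercised under `index` (true-BV) truncation, where
the caps and minimal-kinship pairing hold the measured mean rate near
1.3 points per generation (20 replicates; the capped-vs-uncapped
monotonicity test quantifies the caps' own contribution). Reproducing the
diversity management that lets a real BLUP-selected colony stay under the
bound would need overlapping generations and relatedness-penalized
selection, both out of scope.

## Numerical conventions

* Stable topological order: Kahn's algorithm with input position as
  priority; a written pedigree reloads to the identical order.
* Exact-agreement tests (inbreeding vs oracle, predicted vs realized
  litter F) use 1e−12 absolute tolerance — the recursions produce dyadic
  rationals whose floating-point rounding enters only past ~50 bits.
* Solver tolerances: MME solutions vs oracle at 1e−8; index unit
  invariance at 1e−12.
* All randomness flows through `numpy.random.default_rng` seeded from
  the config; simulations and chains are bit-reproducible.

## Scaled-down checks

Two module-level recovery checks run at reduced size to keep the suite
fast, with tolerances unchanged: the h²-grid recovery test (truths 0.1,
0.3, 0.5, 0.7) uses n ≈ 1,200 with 12 replicates, and the pure-noise
screen uses 10 replicates. The headline h² = 0.52 recovery and the
inbreeding-bound checks run at full size (n ≈ 2,000, 20 replicates) in
`tests/test_acceptance.py` and `scripts/acceptance.py`.
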