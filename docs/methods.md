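# Methods

This note documents the models implemented in `eggnest`, their
assumptions, the tunable parameters that matter, and the numerical and
design choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Egg geometry

An egg is a surface of revolution about its long axis. The meridian
`r(z)`, `z ∈ [0, B]`, comes either from a tabulated `(z, r)` table (for
profiles digitised from photographs) or from the two-parameter family

```
r(x) ∝ sqrt(1 − x²) · (1 + asymmetry·x + ellipticity·x²),   x = 2z/B − 1,
```

rescaled radially so `max r = A/2` exactly. `ellipticity = asymmetry = 0`
gives a prolate spheroid (a sphere when `A = B`); positive asymmetry
makes one end blunter. Admissible shape parameters are capped at |0.5|
and checked for positivity. Samples are cosine-spaced in `x` so the
polyline resolves the poles, where `dr/dz` diverges. Volume is
`π ∫ r² dz` by Simpson quadrature; when egg mass is missing, weight is
estimated as volume × whole-egg density (default 1031 kg m⁻³) × g
(9.81 m s⁻²).

## 2. Shell mechanics

**Model.** Axial plate compression of a shell of revolution is, in the
linear small-displacement limit, an axisymmetric problem, so the 3-D
shell-plus-contact simulation reduces to a 1-D problem on the meridian.
The meridian is discretised into straight conical-frustum elements with
Kirchhoff–Love kinematics: linear meridional displacement, cubic-Hermite
normal displacement, nodal degrees of freedom `(u_r, u_z, θ)` with `θ`
the meridian rotation. Strains per element (local tangential `u`, normal
`w`, arc coordinate `s`, tangent radial component `t_r`):

```
ε_s = u',    ε_θ = u_r / r,    κ_s = −w'',    κ_θ = −w' t_r / r,
```

with membrane stiffness `C = Et/(1−ν²)` and bending stiffness
`D = Et³/12(1−ν²)`; 4-point Gauss integration of `2πr` weighted energy.

**Contact.** Rigid frictionless plates at the linear limit act as
concentrated axial loads at the two poles (the contact patch shrinks to
a point as the displacement → 0). One pole is fixed axially, the other
loaded; `K = F/Δ` is the plate-to-plate stiffness and therefore has the
two pole dimples in series. Pole boundary conditions: `u_r = 0`, `θ = 0`
(axisymmetry regularity).

**Meshing and convergence.** Nodes are cosine-graded in arc length
toward both poles because the point-load boundary layer scales as
`sqrt(R t)`. The solver always performs at least one uniform refinement
(n → 2n elements, up to 3 refinements) and reports the relative change;
`converged` means that change is below 0.5%. Default 200 elements
(final meshes of 400); a solve takes ~50 ms.

**Oracle.** For a thin sphere the point-load stiffness has the Reissner
closed form `K_single = 4Et²/(R·sqrt(3(1−ν²)))`; the plate-to-plate
reference is `K_single/2`. The solver agrees within 0.8–2.6% over
`t/R ∈ [0.005, 0.02]` (the residual deviation carries the expected
`O(t/R)` thick-shell correction to the asymptotic formula, growing with
`t/R`). Linearity in `E` is exact; the fitted thickness exponent over
the same range is ≈ 2.0. For spheroids the solver tracks the
local-curvature generalisation `K ∝ 1/R_pole` with `R_pole = a²/c`
(equatorial semi-axis `a`, polar semi-axis `c`): elongating an egg at
fixed breadth *sharpens* the poles and *stiffens* the shell to axial
point loads.

**Scope.** Compression along the axis of revolution only: a short-axis
compression is not axisymmetric, so `solve_axial_stiffness` raises for
`axis="short"`. Nonlinear buckling, fracture and non-uniform shell
thickness are out of scope; thickness is uniform (one tabulated value
per species). Inputs with `t/A ≥ 0.1` trigger a thin-shell warning.

## 3. The C number

```
C_long  = (K/W) · A²/B          C_short = (K/W) · 2AB/(A+B)
```

Both forms are dimensionless and coincide (`K·D/W`) for a sphere. The
long-axis form divides stiffness-per-weight by the length and multiplies
by breadth squared, removing egg-size and geometry-induced rigidity so
that shells of different-sized eggs are comparable. The printed source
formula for C is typographically ambiguous; this reconstruction is fixed
by dimensional analysis, by the sphere-degeneracy requirement, and by
chicken-scale magnitudes (C ≈ 1.3·10⁴, log₁₀ C ≈ 4.1) landing where
fitted intercepts of log₁₀ C models sit (~4.1). Material defaults
(E = 30 GPa, ν = 0.3) are typical published eggshell values and
configurable; they scale C multiplicatively and cancel from
within-study comparisons made with shared defaults.

## 4. PGLS with Pagel's λ

With tip covariance `V` (shared root-to-MRCA path lengths), Pagel's λ
scales only the off-diagonal entries: `V(λ) = λV + (1−λ)·diag(V)`.
The model `y = Xβ + ε`, `ε ~ N(0, σ²V(λ))` is fitted by **maximum
likelihood** (not REML): the analyses compare models with different
fixed effects by AICc, and ML keeps those comparisons valid. λ is
profiled out by bounded scalar search on [0, 1] (tolerance 1e-6,
boundary candidates checked explicitly); `β̂` is GLS at `λ̂`; standard
errors use the residual-df variance estimate with `t` tests on `n − p`
degrees of freedom. The parameter count for AICc is `k = p + 2`
(coefficients + σ² + λ).

Design matrices are treatment-coded against the lowest-risk reference
levels (basal, others, scrape/platform). Clutch size enters as a
numeric covariate. The attachment × site interaction model aggregates
attachment to basal/non-basal and site to non-tree-vegetation/others
before coding, because not all raw level combinations exist.

**Risk recoding.** A species reported with several nest types is
assigned the highest-risk category it uses (least stable attachment or
site, most enclosed structure), with the total orders
basal < lateral/horizontal < pensile; others < tree < non-tree
vegetation; scrape/platform < cavity < cup < dome. Cavity sits below cup
because cavity nests on average lack the rim that defines a cup.

**Grouping selection.** Multiple comparison among a character's levels
enumerates every set-partition of the levels (Bell(k) models, ≤ 6
levels), refits the PGLS with levels merged, and reports the lowest-AICc
partition as a compact letter display (letters ordered by fitted group
effect). Note the statistical character of AIC-family selection: a
partition with one superfluous extra group beats the truth whenever it
improves 2·logLik by more than ≈ 2, which happens with probability
≈ 15% per candidate — so even under a true single-group null the
single-group partition wins only ~60–65% of replicates (it is the modal
choice, and truly different levels are virtually never merged with equal
ones). The tests assert those achievable properties.

## 5. Correlated evolution of two binary traits

States are ordered `(0,0), (0,1), (1,0), (1,1)` for (C class, nest
class). The **dependent** model has the eight single-change rates
`q12 q13 q21 q24 q31 q34 q42 q43` (double transitions are zero); the
**independent** model ties each trait's gain/loss rates across the other
trait's states (`q13=q24, q31=q42, q12=q34, q21=q43`), leaving four.

*Likelihood.* Felsenstein pruning with per-branch `exp(Qb)` computed
from one eigendecomposition of Q vectorised over branches (expm
fallback if Q is near-defective), with per-node rescaling against
underflow; the kernel is numba-jitted and generic over the state count,
so the 2-state marginal used in cross-checks shares the same code path.
Root states are combined **likelihood-weighted** (`p_i ∝ L_i`, the
convention of the tool family these models come from); uniform and
stationary weighting are available. The likelihood-weighted root also
factorises exactly for independent traits, preserving the
product-of-marginals identity the tests check to 1e-10.

*Binarisation.* C is split at the sample median, strictly-greater →
high; ties (and all-equal samples) go to low — deterministic and
conservative toward the reference class. Nest characters binarise as
lowest-risk level vs all others.

*MCMC.* Metropolis–Hastings over the rates: single-rate lognormal
multiplier proposals (Hastings-corrected), exponential prior (default
mean 10) on every rate, proposal scale adapted toward 30% acceptance
during burn-in only, deterministic given the seed. Branch lengths are
pre-scaled by 0.001 (the convention for trees in units of millions of
years), which makes posterior rate magnitudes commensurate with the
prior mean of 10. The full-data convention is 5.05 M iterations /
50 k burn-in / thin 1000; desk defaults are 40 k / 8 k / 10. A data-free
model (constant likelihood) turns the sampler into a prior sampler; the
tests require every posterior rate mean within 10 ± 0.5 over ≥ 20 000
samples.

*Marginal likelihood.* Stepping-stone sampling along the power path
`β_k = (k/K)^(1/0.3)` from prior (β=0) to posterior (β=1), each stone's
ratio estimated by `logsumexp((β_{k+1}−β_k)·loglik)` over samples from
the β_k power posterior, chains warm-started stone to stone. A constant
likelihood yields `log ML = log L₀` exactly (the prior integrates
to 1). Desk settings: 10–12 stones × 1200–2000 iterations.

*Bayes factor.* `BF = 2(log ML_dep − log ML_indep)`; >2 positive, >10
strong. With desk-scale stepping-stone settings the estimator carries a
Monte-Carlo SD of roughly 1–2 log units, which the test tolerances
account for.

## 6. Ancestral reconstruction and trends

Under Brownian motion, tips and internal nodes are jointly Gaussian
with covariances given by MRCA depths. The **GLS reconstruction** is
the closed-form conditional mean of nodes given tips with the root
estimated by GLS and σ² by ML; it equals the minimiser of
`Σ_edges (Δv)²/branch` (verified to 1e-8 against an independently coded
solver). The **MCMC reconstruction** samples σ² (MH with lognormal
multipliers, exponential prior) and the root (Gibbs, flat prior), and
draws node states from their exact conditional normal at each retained
iteration; per-node posterior mean/median/SD are reported. Convergence
is checked by running `n_runs` chains from different seeds and flagging
when the across-run SD of node means exceeds 5% of the tip SD. The
desk prior mean for σ² is 0.1 (matched to unit-depth trees, where BM
rates are O(0.01–1)); 0.001 is the convention for trees and trait
scales where rates are of that order.

**Quantile trends.** Tips (observed values) and nodes (posterior
medians) are pooled; the τ-th conditional quantile of log₁₀ C given
node depth, a passerine indicator and their interaction is fitted by
check-loss minimisation (statsmodels' IRLS quantile regression as the
solver; the solution is verified against exhaustive enumeration of
exact-fit bases on small fixtures). Standard errors and percentile CIs
come from a seeded row-resampling bootstrap (default 1000 replicates —
a conventional choice). An internal node counts as passerine when all
its descendant tips are. Spline summaries take running quantiles in ~10
equal-count depth windows per group (median depth vs window quantile)
and interpolate them with a cubic spline; groups are fitted in
isolation and the curves carry no inferential content. Trend fits run
on the log₁₀ scale; back-transform only for display.

## 7. Consensus trees

The tree-sample workflow builds a majority-rule consensus containing
exactly the rooted clades present in **strictly more than half** of the
sample (ties excluded), then fits edge lengths by nonnegative least
squares (NNLS on the clade-path incidence system) against the **mean**
patristic distance matrix of the sample (the mean is the deterministic,
standard summary; median is available). Tip-to-tip distances cannot
split the two root edges of a bifurcating root — only their sum is
identified — so that one degeneracy is resolved by balancing mean tip
depth across the two sides, which restores the generating lengths
whenever the input distances came from an ultrametric tree.
Unidentifiable interior edges are driven to zero by the nonnegativity
constraint.

## 8. Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume:

* **Trees**: Yule (birth–death) ultrametric trees, rescaled to depth 1
  (trait studies) or depth 100 (coevolution studies, mimicking
  million-year timescales so that branch scaling by 0.001 and prior
  mean 10 interact as in real analyses).
* **Nest characters**: symmetric stepwise Markov chains between
  adjacent risk levels (rate 3 per unit depth; root level drawn from
  the stationary law so all levels occur at realistic frequencies).
* **log₁₀ C**: `y = Xβ + b + e` with `b` Brownian of rate σ²λ simulated
  node by node (its node values are the ASR ground truth) and `e`
  independent with variance σ²(1−λ)·depth — together exactly the
  Pagel-λ covariance. Default effects are on the fitted-model scale
  (dome +0.136, cavity +0.066, cup +0.070; pensile +0.111,
  lateral +0.052; non-tree vegetation +0.081, tree +0.050;
  clutch +0.017 per egg; intercept 4.10; σ² = 0.025, giving a tip SD of
  ~0.16 matching the observed 5th–95th percentile spread of log₁₀ C).
* **Paired binary traits**: exact Gillespie simulation of the 4-state
  chain; the dependent condition elevates one gain rate 10× (base 10,
  elevated 100 on the scaled timescale, ≈ 1 event per lineage).
* **Geometries**: a latent lognormal size with allometric breadth,
  length (×1.35), thickness (×0.009) and volume-density mass, each with
  4% lognormal noise; thin-shell `t/A < 0.05` by construction.

It does **not** emulate: real avian taxonomy or trait covariation
beyond the modelled effects, measurement error in egg photographs,
among-tree topological uncertainty (analyses run on one tree or a
consensus), non-ultrametric trees, or rate heterogeneity through time.
Passing tests therefore demonstrate correctness of the estimators under
the assumed generating processes, not robustness to violations of them.

## 9. Problem sizes

Chosen as the package's test scale: PGLS recovery at n = 400 tips ×
200 replicates (tests) / 100 replicates (acceptance script); Bayes
factors at n = 300 (dependent) and n = 200 (null) × 20 replicates
(tests) / 10 (script) with 10 stones × 1200 iterations; ASR on a 50-tip
fixture; prior recovery over 20 000 retained samples; full-scale
conventions (1350 species, 1000 trees, 5.05 M iterations) are
documented on the relevant configuration objects and reachable by
setting them.

## 10. Known limitations

* The shell element is a faceted (conical-frustum) approximation; the
  ~1–3% systematic offset from the Reissner asymptote at larger `t/R`
  mixes mesh facet error with genuine thick-shell corrections.
* Short-axis stiffness requires a non-axisymmetric (3-D or Fourier)
  shell model and is not provided; the short-axis C form is exposed for
  stiffnesses obtained elsewhere.
* Stepping-stone marginal likelihoods at desk settings carry ~1–2 log
  units of Monte-Carlo error; single-dataset Bayes factors near the
  decision threshold of 2 should be read accordingly.
* AICc grouping selection inherits the ~15% per-candidate overfit rate
  of AIC-family criteria (see §4).
* λ estimation at the [0, 1] boundary is reported as a boundary
  estimate; no boundary-corrected uncertainty is attempted.
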