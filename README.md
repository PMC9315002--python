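# eggnest

Dimensionless eggshell stiffness and the comparative biology of egg–nest
coevolution.

Birds that build unsteady nests (hanging from a branch, swaying on reeds)
or enclosed nests (domes with a small entrance) expose their eggs to a
higher risk of egg-to-egg collision. `eggnest` provides the complete
quantitative toolkit for testing whether eggshell stiffness evolved in
response to that risk across a phylogeny:

1. **Shell mechanics.** The absolute stiffness *K* (N m⁻¹) of an egg
   compressed between rigid plates is computed with an axisymmetric
   thin-shell finite-element model of the egg meridian. Because *K*
   confounds material stiffness with size and geometry, it is converted
   to the dimensionless **C number**

   *C* = (*K* / *W*) · (*A*² / *B*),

   where *W* is egg weight (N), *A* breadth and *B* length (m). For a
   sphere both the long- and short-axis forms reduce to *K·D/W*. C
   compares shell stiffness across species from wrens to ostriches.
2. **PGLS with Pagel's λ.** log₁₀ C is regressed on nest attachment
   (basal < lateral/horizontal < pensile), nest site (others < tree <
   non-tree vegetation) and nest structure (scrape/platform < cavity <
   cup < dome), with clutch size as covariate, under the error covariance
   σ²·V(λ) (off-diagonal Brownian covariances scaled by λ ∈ [0, 1],
   estimated by maximum likelihood). Multiple comparison of category
   levels uses AICc model selection over every set-partition of the
   levels, reported as a compact letter display.
3. **Correlated evolution.** Whether high/low C (median split) and a
   binarised nest character evolved interdependently is tested with the
   dependent vs independent 4-state Markov models, MCMC rate sampling
   under exponential priors, stepping-stone marginal likelihoods and
   Bayes factors on the 2·Δlog ML scale (>2 positive, >10 strong).
4. **Ancestral trends.** Ancestral log₁₀ C values are reconstructed
   under a non-directional Brownian random walk (closed-form GLS and a
   posterior sampler, cross-checked against each other), then tips and
   nodes are pooled in quantile regressions of C against node depth with
   a passerine indicator, with bootstrap standard errors and spline
   summaries of the non-linear trend.
5. **Synthetic studies.** A seeded generator produces Yule trees, nest
   characters evolving as Markov chains, clutch sizes, log₁₀ C with known
   λ and effect sizes, and allometric egg geometries — so every stage of
   the pipeline is testable end to end with known ground truth.

## Worked example

Stiffness and C number for a chicken-scale egg (breadth 44.3 mm, length
57.0 mm, shell 0.35 mm, mass 60 g, shell modulus 30 GPa):

```python
from eggnest import (build_profile, EggSpecimen, ShellMaterial,
                     solve_axial_stiffness, c_number)

profile = build_profile(breadth=0.0443, length=0.0570,
                        ellipticity=0.05, asymmetry=0.12)
egg = EggSpecimen(profile, ShellMaterial(thickness=3.5e-4), mass=0.060)
result = solve_axial_stiffness(egg, mesh_elements=200)
c = c_number(result.stiffness, egg.weight, 0.0443, 0.0570, axis="long")
print(f"K = {result.stiffness:,.0f} N/m")
print(f"C = {c.value:,.0f}  (log10 C = {c.log10_value:.3f})")
```

prints

```
K = 228,783 N/m
C = 13,382  (log10 C = 4.127)
```

— a stiffness of ~2.3·10⁵ N/m and a C number of ~1.3·10⁴, i.e. the shell
supports ~13 000 times the egg's own weight per characteristic
displacement. A PGLS fit on a synthetic 200-species study generated with
the package's own defaults (dome effect +0.136, clutch effect +0.017 on
log₁₀ C, Brownian residuals):

```python
from eggnest.simulate import SimulationConfig, simulate_study
from eggnest.pgls import PGLS

tree, traits, truth = simulate_study(SimulationConfig(n_tips=200, seed=42))
fit = PGLS.from_dataframe(traits, "log10_C", tree,
                          characters=["structure"],
                          covariates=["clutch_size"]).fit()
print(fit.summary())
```

```
PGLS (Pagel's lambda, ML)
n = 200, k = 7, lambda = 1.000, sigma2 = 0.02826
logLik = 243.085, AICc = -471.587
----------------------------------------------------------------------------
                                     coef       SE        t           p
Intercept                           4.184    0.050    84.13   3.37e-155
structure[cavity]                   0.063    0.015     4.18    4.48e-05
structure[cup]                      0.089    0.019     4.65    6.09e-06
structure[dome]                     0.133    0.023     5.91    1.53e-08
clutch_size                         0.017    0.000   143.03   2.12e-199
```

The dome and clutch coefficients recover the generating effects (0.136
and 0.017), and λ̂ = 1 recovers the Brownian residual structure.

## Command line

Each analysis stage is also a subcommand writing outputs plus a JSON
manifest (inputs, seeds, version, wall time); reruns with the same seeds
are bit-for-bit reproducible:

```sh
eggnest simulate  --out data --n-tips 200 --seed 1
eggnest validate  --traits data/traits.csv --tree data/tree.nwk
eggnest stiffness --input eggs.csv --out stiffness.csv
eggnest pgls      --traits data/traits.csv --tree data/tree.nwk \
                  --character structure --grouping --out pgls
eggnest coevolve  --traits data/traits.csv --tree data/tree.nwk \
                  --character attachment --seed 2 --out coevolve
eggnest asr       --traits data/traits.csv --tree data/tree.nwk \
                  --seed 3 --out asr
eggnest trend     --traits data/traits.csv --tree data/tree.nwk \
                  --seed 4 --out trend
eggnest all       --config run.yaml
```

## Further reading

`docs/methods.md` documents the models, their assumptions, all tunable
parameters with defaults and units, the synthetic-data generator's scope,
and the numerical choices made throughout.
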