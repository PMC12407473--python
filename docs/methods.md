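# Methods

## Model and scope

`glmpower` computes power for tests of fixed effects in balanced general
linear mixed models that are *reversible*, i.e. losslessly re-expressible
as a general linear multivariate model `Y = X B + E` with i.i.d. rows of
`E ~ N_p(0, Σ)`.  Reversibility requires three things: complete data,
covariates constant within each independent sampling unit (ISU), and a
common error covariance across ISUs (which forces equal cluster sizes).
`glmpower.bridge.check_reversibility` reports these conditions; when they
fail, complete-data power is an upper bound on the truth, not an estimate
of it.

Only the population-average form of the mixed model is represented.  Power
depends on the marginal covariance Σ alone, so the random-effects
decomposition (Z, d, and their covariances) is deliberately never
instantiated; the bridge module maps the multivariate formulation onto the
stacked mixed-model formulation (`X_m = X ⊗ I_p`, `β_m = vec(B')`,
`C_m = C ⊗ U'`) purely as bookkeeping, and changes no numeric result.

Out of scope by design: non-Gaussian outcomes, missing-data-aware analytic
power, unequal cluster sizes, Gaussian covariates (unconditional power),
crossover and stepped-wedge designs, and multivariate statistics other than
the Hotelling–Lawley trace (Wilks, Pillai, UNIREP).

## The test and its F approximation

The general linear hypothesis `H0: C B U = Θ0` is tested with the
Hotelling–Lawley trace `T = tr(H E⁻¹)`, where
`H = (CB̂U − Θ0)' M⁻¹ (CB̂U − Θ0)`, `M = C (X'X)⁻¹ C'`, and `E` is the
error SSCP of the `U`-projected residuals.  Its reference distribution is
the McKeon F with

```
df1 = a·b
df2 = 4 + (a·b + 2)·t1/t2
t1  = νe² − νe(2b+3) + b(b+3)
t2  = νe(a+b+1) − (a + 2b + b² − 1)
νe  = N − q
```

mapped by `F_obs = T·(νe − b − 1)·df2 / (df1·(df2 − 2))`.  Two exact
reductions pin this down: for `b = 1`, `df2 = νe` and `F_obs` is the
ordinary univariate F; for `a = 1`, `df2 = νe − b + 1` and `F_obs` is the
exact Hotelling T² F.  The mapping constant is further constrained by a
moment identity — under the null, `E[T] = ab/(νe − b − 1)` exactly, so
`E[F_obs] = df2/(df2 − 2)`, the mean of the reference F — which the test
suite checks by simulation for `s = min(a,b) ≥ 2`.

### Noncentrality

Power is the upper tail of a noncentral `F(df1, df2, ω)` at the central-F
critical value, with the **unscaled trace noncentrality**

```
ω = tr( (U'ΣU)⁻¹ Δ' M⁻¹ Δ ),    Δ = C B U − Θ0.
```

This was the one genuinely open numerical decision in the design.  Three
candidates from the literature were evaluated: the unscaled trace, a
`(df2/νe)`-scaled trace, and a moment-matched
`df2(νe−b−1)/((df2−2)νe)`-scaled trace.  All three coincide for
`a = b = 1`.  The unscaled form is the only one that (i) is exact for every
`s = 1` case (it reproduces the noncentral-T² F, verified to 1e−12 against
closed forms), and (ii) agrees with the Monte Carlo oracle within its 95%
binomial CI on all five packaged validation designs, including the two
`s = 2` designs.  The scaled variants miss the `s = 1` exactness by a
factor `df2/νe` and land visibly outside the simulation CIs, so the
unscaled trace is used throughout, identically on the analytic and
simulation sides.

## Covariance model

The within-ISU covariance is `Σ = Σ_o ⊗ Σ_r ⊗ Σ_c`:

* **Σ_o** (outcomes): unstructured correlation scaled by per-outcome SDs.
  All measurement variance lives here; the other two blocks are pure
  correlations.  Units are those of the outcome; an SD must be given per
  outcome (default correlation: identity).
* **Σ_r** (repeated measures): unstructured, compound symmetric (one ρ),
  AR(1), or LEAR.  LEAR correlates measures at distance `d` as
  `ρ_base^(d_min + δ·(d − d_min)/(d_max − d_min))` with `d_min`/`d_max`
  the extreme pairwise distances of the measurement grid; `δ = 0` gives
  compound symmetry at `ρ_base^{d_min}`, and a two-point grid uses the
  exponent `d_min`.  `ρ_base ∈ (0,1)`, `δ ≥ 0`, timings strictly
  increasing in arbitrary time units.
* **Σ_c** (nested clusters): the Longford variance-components correlation,
  built recursively from innermost level 1 to outermost level D as
  `P(d) = I_{k_d} ⊗ P(d−1) + ρ_d(11' − I)`, `P(0) = 1`.  **Per-level ρ_d
  are incremental**: two members whose lowest common cluster is level d
  correlate at `ρ_d + ρ_{d+1} + ... + ρ_D`.  This is what the recursion
  computes; users whose ICCs are marginal totals must difference them
  first.  Sizes are limited to 10,000 per level and results are checked
  positive definite (relative eigenvalue floor 1e−10; near-singular
  combinations are rejected, never regularized).

### Blockwise reduction and large clusters

Power needs Σ only through `Σ* = U'ΣU`, computed factor-by-factor:
`Σ* = (U_o'Σ_oU_o) ⊗ (U_r'Σ_rU_r) ⊗ (U_c'Σ_cU_c)`.  When the cluster
contrast is the averaging column (the usual case — cluster members are
exchangeable), `U_c'Σ_cU_c` equals the scalar

```
γ_D = γ_{D−1}/k_D + ρ_D(1 − 1/k*(D)),   γ_0 = 1,
```

the Spearman–Brown prophecy factor extended to nested levels (for D = 1 it
is the design effect `1 + (k−1)ρ` over k).  γ equals the mean of all
entries of P(D) — a property test verifies this against brute force up to
D = 4 — so the averaging path never materializes P(D) and is O(D) in time
regardless of cluster size.

## Design representation

Cell-mean coding: one indicator column per design cell (Cartesian product
of between-factor levels, first factor slowest), so `X'X` is the diagonal
of cell counts and trivially full rank; no generalized inverses anywhere.
Effect contrasts are successive differences, with equal-weight averaging
over non-tested factors and over cluster members; power is invariant to
any full-rank recoding of the same test space (property-tested).  `Θ0`
defaults to zero; grand-mean tests must supply it explicitly since their
null is not zero.

The cell-means table carries one row per cell and one column per
(outcome, time) coordinate, outcome-major, matching the Kronecker order of
Σ.  Members of a cluster share the cell mean (exchangeability), which is
what lets the means table omit the member coordinate and the reduction
collapse it analytically.

Sample-size search: allocation ratios constrain feasible totals to
multiples of their sum; the solver brackets the target power by doubling
along that lattice and bisects, asserting monotonicity as it goes (a
decrease would signal an approximation pathology and raises).  The dropout
rule of thumb divides the complete-data total by `1 − x/100` and rounds up
to the lattice.

## Monte Carlo validator

Each replication draws `E` with rows `N(0, Σ)` via a symmetric
eigendecomposition factor (chosen over Cholesky so near-singular Σ fails
at the PD check, not inside sampling), forms `Y = XB + E`, fits by least
squares, and computes the HLT p-value against the McKeon reference —
the same statistic and reference used analytically.  Empirical power is
the rejection proportion, reported with the standard Wald 95% CI
`p̂ ± 1.96·√(p̂(1−p̂)/reps)`.

Because the statistic depends on `Y` only through `Y U` (N × b), the
default simulation path draws the projected errors directly from
`N_b(0, U'ΣU)` — distributionally identical, and verified against the
full-matrix route both deterministically (equal statistics on shared data)
and statistically.  This keeps 10,000-replication runs on the
480-dimensional multilevel longitudinal design to a few seconds.

Seeding: one root seed keys a Philox generator; replication r uses the
jumped stream `Philox(key=seed).jumped(r)`, so results are reproducible
and any single replication can be replayed in isolation.

## Validation designs and what they show

Five designs ship as JSON fixtures and anchor the test suite end to end:
a two-arm cluster-randomized trial (power 0.909), a three-visit
longitudinal trial (0.906), a three-arm two-level-nested MANOVA (0.659), a
2:1-allocated three-level-nested longitudinal design with LEAR correlation
(0.909), and a treatment-by-genotype interaction analysis (0.792).  The
first four are fully determined by their published inputs.  The fifth
states only a total of 30 participants across 8 cells; the packaged
allocation (genotype counts 2, 2, 4, 7 in each arm) was reconstructed to
match the design's published power and is labelled synthetic in the
fixture — other allocations within a ±0.005 power band exist.

For each fixture the suite checks the analytic power, checks the
10,000-replication empirical power against its published 95% CI, and
checks |analytic − empirical| ≤ 0.01.  These are simulations from the
assumed model: they validate the distributional approximation, not the
realism of any particular set of means, SDs or ICCs, and say nothing about
robustness to missing data or unequal clusters (which break reversibility
outright).

## Numerical choices and limitations

* All distribution functions at double precision from scipy
  (`ncf`, `f`); no series truncation parameters are exposed.
* PD tolerance: smallest eigenvalue > 1e−10 × largest, everywhere.
* `νe > b + 1` is required (else the McKeon df2 and the trace's null mean
  are undefined); degenerate small-sample designs raise rather than
  extrapolate.
* Monte Carlo replication counts: 10,000 for headline validation (binomial
  SE ≈ 0.005 at p ≈ 0.9), 1,500–2,000 in the quicker statistical tests,
  with assertions at 3–4 SEs.
* The LEAR exponent uses the min/max-distance normalization described
  above; other LEAR parameterizations exist in the literature and will not
  match numerically.
* Allocation ratios must be integers; fractional cell counts are not
  representable, which is deliberate (they are not realizable designs).
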