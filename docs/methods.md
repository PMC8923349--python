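# Methods

This note records the statistical model behind each stage, the parameter
conventions, the numerical design choices, and what the test suite does and
does not establish.

## 1. Phylogenetic model

### Covariance

For a rooted tree with branch lengths, the Brownian-motion trait covariance
between tips i and j is the root-to-MRCA shared path length,
`C[i, j] = depth(MRCA(i, j))`, with `C[i, i]` the tip's root distance.
Polytomies are allowed; negative branch lengths are rejected; `None`
lengths count as zero.

### Pagel's λ

The λ model rescales shared history only:

```
V(λ) = λ·C + (1 − λ)·diag(C),   λ ∈ [0, 1]
```

λ = 0 means phylogenetically independent tips, λ = 1 the full Brownian
structure. Both the signal estimate (`y ~ 1`) and PGLS (`y ~ 1 + x`) are
maximum-likelihood fits of `y ~ N(Xβ, σ²V(λ))`, profiled over λ.

**Profiling trick.** With `D = diag(C)` and
`M = D^{-1/2} C D^{-1/2} = Q W Qᵀ`, the fixed rotation `Qᵀ D^{-1/2}`
diagonalizes V(λ) for *every* λ simultaneously, with weights
`w_k(λ) = 1 − λ + λ e_k` (e_k the eigenvalues of M). Profiling therefore
costs one symmetric eigendecomposition plus O(n) per candidate λ. The
maximizer is found on a 101-point grid followed by bounded scalar
refinement, so it can never fall below the grid optimum.

A relative eigenvalue floor (`JITTER = 1e-10`) guards against numerically
singular V(λ) from near-zero-length cherries in user-supplied trees.

### Tests

* λ = 0 fits equal OLS; λ = 1 fits equal a dense GLS solve with the same
  1e-10 ridge (tolerance 1e-8, 20 random 10–50-tip instances).
* The λ profile is invariant to tip permutations, recovers ≈0 on iid noise
  and ≈1 on Brownian draws, and its mean over 100 replicates is within 0.1
  of the truth at λ ∈ {0, 0.5, 1} (n = 300).
* Cross-check against R: `phytools::phylosig` for the signal λ̂ and
  `nlme::gls` + `ape::corPagel` for the PGLS slope. nlme optimizes λ
  *unbounded* (it can go negative), so the oracle profiles fixed-λ `gls`
  fits over a 0.01 grid on [0, 1] — an independent evaluation of the same
  bounded-ML objective. R is used only as an oracle, never as the
  implementation.

### Inference conventions

* Signal test: likelihood ratio of λ̂ vs λ = 0 against the 50:50
  χ²₀/χ²₁ boundary mixture (λ = 0 lies on the parameter boundary);
  `chisq_mixture=False` selects the plain χ²₁ reference.
* PGLS slope p-value: t statistic with n − 2 df using the unbiased
  residual variance `RSS/(n − 2)` at the fitted λ.

## 2. D-ratio step statistic

For each integer temperature i with both sides populated,

```
D_i = mean(abundance | Topt ≥ i) / mean(abundance | Topt < i)
```

`D_max` is the largest finite D_i inside a trusted window (default
[20, 64] °C, where per-side sample sizes keep the means stable); ties break
to the smallest i; a zero lower mean gives +inf, which is excluded from
the maximum but counted.

**Permutation null.** Abundances are shuffled against the fixed temperature
axis (equivalently: species are placed randomly along the Topt axis) and
`D_max` recomputed; the default p-value counts strictly larger null maxima,
`p = #(null > observed)/n_perm`. `p_variant="conservative"` gives
`(k + 1)/(n_perm + 1)`. The computation is vectorized: one stable sort,
prefix sums, and `searchsorted` split indices shared across permutations.

**Exactness and calibration.** On a two-level toy the Monte-Carlo null is
verified against exhaustive enumeration of all C(10,5) assignments (exact
tie-inclusive p = 1/252 on the five-1s/five-9s example). Under the
exchangeable null simulator (no step, iid abundance effects, n = 1500) the
measured rejection rate at α = 0.05 is ≈0.058 over 500 replicates.

**Limitation — exchangeability.** The permutation null assumes abundances
are exchangeable across species. When abundance itself carries phylogenetic
signal *and* Topt does too, the null is violated and the test is
anti-conservative (measured rejection ≈0.08 at α = 0.05 under this
package's generator defaults with λ_topt = 0.9, λ_abund = 0.5). This is a
property of the published test itself, inherited deliberately; treat
borderline p-values with caution when both traits show strong signal.

## 3. Smooth localization

Abundance is regressed on temperature through a cubic B-spline basis
(default `basis_dim = 10`) with knots at temperature quantiles, penalized
by the exact integrated squared second derivative (2-point Gauss–Legendre
per knot interval — exact because the second derivative is piecewise
linear). The smoothing parameter is selected by GCV over a log-spaced grid
(`1e-4 … 1e4`, 81 points). Two deliberate departures from a vanilla
penalized regression spline:

* **Natural boundary constraints.** `f''(min) = f''(max) = 0`, imposed by
  reparameterizing into the null space of the boundary constraint matrix.
  This is the classical smoothing-spline solution space and suppresses
  boundary curl that otherwise produces spurious derivative spikes in the
  sparse hot tail (74–85 °C).
* **GCV df-cost inflation, γ = 1.4.** GCV is known to undersmooth; the
  standard correction multiplies the degrees-of-freedom cost.

A secondary rank-1 shrinkage of the slope direction in the penalty null
space, selected on the same GCV grid, lets trendless data collapse to
edf ≈ 1 (exactly linear data collapse to edf ≈ 2 via the main penalty).
Interpolation-level residuals are floored to zero so GCV ties resolve
toward the smallest edf. The constant direction is never penalized, so
fitted values always preserve the data mean exactly.

The transition temperature is the integer °C nearest the argmax of the
first derivative (finite differences on a 0.1 °C prediction grid).

**Scale caveats.** With the default basis the knot spacing (~11 °C over a
4–85 °C range) cannot represent a unit-scale sigmoid exactly; the
derivative-argmax contract holds at `basis_dim = 10`, while curve-shape
recovery to 0.1 absolute error needs `basis_dim ≈ 40`. Localization is
reliable at study scale (n ≈ 1500: argmax within [42, 48] in ≥ 80% of
replicates, measured 0.88); at a few hundred species the sparse hot end can
still capture the argmax.

## 4. Window and category scans

`segmental_pgls` sorts species by (Topt, species id), slides a fixed-size
window (default 200 species, stride 1) and refits the λ-model PGLS per
window on the corresponding covariance submatrix; constant-temperature
windows are skipped and counted. Under the exchangeable null the pooled
window-level false-positive rate at α = 0.05 measured ≈0.054 (20
replicates, n = 500; overlapping windows within a replicate are strongly
correlated by construction, so rates are pooled rather than averaged
per replicate).

`category_pgls` fits within fixed bands (default 4–34 / 35–49 / 50–85 °C
plus the full range); bands with < 4 species are reported as skipped.
`tertile_split` places boundaries between runs of equal temperatures at the
cuts nearest n/3 and 2n/3, so ties are never divided. The
bacteria-vs-archaea comparison averages each measure within domain at every
shared integer Topt and applies the Wilcoxon signed-rank test (exact null
for ≤ 25 untied informative pairs, tie-corrected normal approximation
otherwise; all-zero differences give p = 1).

## 5. Synthetic generator

`simulate_dataset` draws, from a single seed (sub-seeds via
`SeedSequence.spawn`):

1. **Tree**: pure-birth (Yule) with `n_tips` (default 1500) extant tips,
   rescaled to unit median tip depth. The birth-death process stops exactly
   at the n-th birth, which would leave a zero-length cherry; every tip
   edge is therefore extended by one Exp(n·birth_rate) waiting time — the
   time to the next, uncommitted event — keeping the tree ultrametric and
   almost surely non-degenerate.
2. **Topt**: a latent Gaussian with λ_topt-scaled tree covariance
   (default 0.9) pushed through the normal CDF, affinely mapped to
   [4, 85] °C and rounded to integers — range respected exactly, signal
   tunable.
3. **Abundance**: negative-binomial counts (size = `dispersion`, default 1;
   `inf` = Poisson) around the sigmoidal step mean

   ```
   μ(T) = baseline_mu + step_delta / (1 + exp(−(T − t_star)/step_scale))
   ```

   (defaults 0.5 → 4.0 around 45 °C, unit scale), multiplied by a
   mean-preserving log-normal phylogenetic effect
   `exp(phylo_sd·z − phylo_sd²/2)` with z drawn from the λ_abund-scaled
   covariance (defaults 0.5, 0.5), then thinned by structural zeros
   (`zero_inflation = 0.55`).

`CorrelatedSampler` caches the Cholesky factor of V(λ) so replicated
experiments on a pooled tree cost one matrix-vector product per draw.
Replicated acceptance experiments reuse small tree pools (5–10 trees) with
fresh trait draws per replicate; all replicate counts (500 calibration, 50
recovery, 100 per λ value) and the n = 500 segmental-scan instances are
this package's own budget choices. Distinct seeds feed every independent
stream (a shared seed between the Topt and abundance samplers would couple
their underlying normal sequences).

## 6. What the tests do and do not show

The acceptance suite establishes: exact agreement with closed-form/dense
oracles and R reference implementations; exactness of the D statistic
against enumeration; calibration of the permutation test *under its own
exchangeable null*; power and localization accuracy *under this package's
generator* at the stated sizes; and structural identities of the pipeline.
It does **not** establish: calibration under phylogenetically correlated
abundances (see §2), smoother localization at small n, or agreement with
any particular empirical dataset — real-data analyses additionally depend
on trait curation and tree quality, which are validated only at the schema
level here.
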