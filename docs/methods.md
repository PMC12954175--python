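# Methods

## The model

`spacebf` treats bivariate spatial co-expression as a regression problem:
for each ordered molecule pair (m′ → m) it fits a spatially varying
coefficient (SVC) model over the n measured locations. For counts the
outcome is negative binomial with a logit link on the failure probability,

    X^m(s_k) ~ NB(psi_k, r),   logit(psi_k) = eta_k,
    eta_k = beta0(s_k) + x_k beta1(s_k) + C(s_k)' alpha,

where x is the transformed predictor expression (log1p for counts,
z-score for continuous intensities — matching the scale on which the
synthetic generators define the association), r > 0 is a
location-constant dispersion (r → ∞ recovers Poisson), and covariates are
optional fixed effects under a flat prior (none by default). For
continuous data the Gaussian analogue with i.i.d. N(0, σ²) errors is
used. The spatially varying intercept absorbs the marginal spatial
autocorrelation of m; this is what protects the slope from the spurious
associations that contaminate lagged-correlation statistics.

## The fused horseshoe prior

Spatial smoothness of each coefficient field is imposed on the edges of a
spatial graph. For edge i = (k1, k2) and field j ∈ {0, 1},

    Δβ_ji = β_j(s_k1) − β_j(s_k2) ~ N(0, Λ²_ji τ_j² σ²),
    Λ_ji ~ C+(0, 1),   τ_j ~ C+(0, 1),

which induces the intrinsic GMRF kernel
(τ_j²σ²)^(−ℓ/2) exp{−β_j' L(Λ_j) β_j / (2τ_j²σ²)} with
L(Λ_j) = D' diag(Λ_j⁻²) D and ℓ = rank(L) = n − C (C connected
components). The global scale controls overall fusion; the half-Cauchy
local scales give an infinitely tall spike at zero (aggressive smoothing
of small differences) and heavy tails (sharp boundaries escape). Λ ≡ 1 is
exactly the ICAR prior, available as `PriorConfig(prior="icar")`. σ² = 1
in the NB model. The generalized determinant of L(Λ) depends on Λ but not
on β or τ², so it never enters the Gibbs updates; consequently the
per-edge local-scale updates are exact on acyclic graphs (MST) and a
composite-likelihood approximation on cyclic ones (kNN, Delaunay).

Because the intrinsic prior is rank-deficient, every coefficient also
carries a small proper ridge precision (1e-6). When the outcome or the
predictor is more than 75% zeros — common in sparse spatial
transcriptomics — a proper N(0, 10) prior is switched on automatically,
which markedly improves mixing; `weak_prior_sd2` overrides the rule.

### Graphs

MST (default; unique after Uniform(0, jitter_scale·d_min) tie-breaking
noise, seeded), union-symmetrised kNN, Delaunay, and ε-neighbourhood
(auto ε = max nearest-neighbour distance) constructions are provided, all
on Euclidean distances. The incidence orientation is +1 on the
lower-indexed endpoint; the prior depends only on squared differences, so
the choice is a reproducibility convention. Disconnected graphs are
allowed; C propagates into ℓ = n − C.

## Posterior computation

One Gibbs sweep updates, in order: the Pólya–Gamma auxiliaries ω_k ~
PG(y_k + r, η_k) (NB only), the stacked coefficient block (β₀, β₁, α)
jointly from its Gaussian full conditional, the local scales (per-edge
inverse-gamma steps via the half-Cauchy auxiliary-variable mixture), the
global scales (inverse-gamma with shape ℓ/2 + 1/2), an interweaved
non-centered update of each global scale (below), and σ² (Gaussian,
conjugate inverse-gamma) or r (NB, adaptive random-walk Metropolis on
log r against the exact NB likelihood, proposal adapted toward 40%
acceptance during burn-in). The dispersion prior is Gamma(2, 1) — mean 2,
diffuse over the range typical of UMI counts. This choice matters more
than usual: the flexible spatial intercept absorbs most overdispersion,
leaving r weakly identified, so its posterior tracks the prior; a prior
centred far above the data's dispersion regime makes the count model
near-Poisson, understates sampling noise and visibly inflates the
empirical type-I error of the global test. `PriorConfig(r_prior_shape,
r_prior_rate)` overrides it.

Implementation notes:

- **Pólya–Gamma draws** use the exact infinite gamma-series
  representation truncated at 32 terms (the sampler default; the
  stand-alone generator defaults to 64) with the analytic mean of the
  discarded tail added back; the mean is exact and the variance deficit
  decays as the cube of the truncation point. At 32 terms the augmented
  posterior is indistinguishable from an exact-likelihood
  Metropolis–Hastings reference within Monte Carlo error.
- **Coefficient block.** With no covariates the 2n-dimensional precision
  is assembled directly in LAPACK banded storage after a
  reverse-Cuthill–McKee reordering of the interleaved (β₀, β₁) indices,
  so a sweep costs O(n·bw²); covariate models and test oracles use a
  dense Cholesky. A failed factorization retries once with a tenfold
  ridge before erroring.
- **Interweaving.** The centered conjugate updates traverse the
  (β_j, τ_j²) funnel slowly when a pair is weakly identified (e.g., the
  predictor is mostly zero), which leaves chains stuck in one scale
  regime and makes tail summaries overconfident. After the centered
  updates, each global scale receives an ancillarity–sufficiency
  interweaving move: holding β_j/τ_j fixed, log τ_j² is proposed with a
  unit-variance random walk and accepted against the exact likelihood,
  the proper diagonal prior, the half-Cauchy density and the Jacobian;
  the τ auxiliary is refreshed after acceptance. The move leaves the
  target invariant and costs one likelihood evaluation per field.
- **Numerical guards.** Scale draws are floored at 1e-12, and the
  combined per-edge prior precision 1/(Λ²τ²σ²) is capped at 1e10 — at
  that precision an edge difference has standard deviation 1e-5 and is
  numerically fused, while the full conditional remains factorizable in
  double precision.
- The NB dispersion and interweaving updates marginalize over ω; ω is
  refreshed at the start of the next sweep before anything conditions on
  it (a partially collapsed scheme).

Defaults are 5,000 iterations with 2,500 burn-in, thinning 1. Runs are
bit-reproducible given a seed.

## Hypothesis testing

The global null is a zero tissue-wide mean slope. Each retained draw
contributes its spatial mean; the test reports the equal-tailed credible
interval, the probability of direction p_d (share of draws matching the
sign of the posterior median; zeros count toward both signs), and
P_two = 2(1 − p_d). Significance is called when P_two < α (default 0.05) —
the CI is reported alongside. Local tests call a location significant
when its equal-tailed CI excludes zero. BH adjustment (via statsmodels)
controls FDR across pairs (default reporting threshold 0.1). The Geweke
diagnostic compares the first 10% and last 50% of a chain with
spectral-density-at-zero variance estimates from AIC-selected AR fits;
|z| > 2 is flagged.

## Synthetic data generators

Three generators cover the benchmark settings; all are seeded and
deterministic, and all use a Gaussian copula that preserves exact
NB(ψ, r) marginals (`gp_to_nb`), with spatial dependence from the
exponential kernel H = exp(−d/l). The displayed-kernel convention (L1
distance) is the default; L2 is available and recorded in metadata.

1. **Constant slope (design 1):** X^m′ from the copula; X^m from the NB
   SVC model with slope ν on log1p(X^m′) and intercept
   β₀ ~ MVN(0, 0.5H). Grids: ν ∈ {−0.75 … 0.75}, l ∈ {3.6, 7.2, 18}.
2. **Joint copula (design 2):** (Z^m, Z^m′) ~ MVN(0, [[1, ν], [ν, 1]] ⊗ H),
   both margins mapped to NB(0.5, 1); the association is nonlinear in ν
   and ν = 0 gives exact independence with marginal autocorrelation —
   the adversarial null for lagged-correlation statistics.
   l ∈ {0.6, 1.8, 3.6, 7.2}.
3. **Sharp slope fields (design 3):** X^m′ as design 1 with l = 7.2; the
   slope field has a linear-partition boundary (N(±ν, σ_k²) on two
   median-defined regions, σ_k ~ U(0.3, 0.6), 0 elsewhere) or a circular
   boundary (mean ±ν inside/outside a disc at the coordinate-wise
   median, sd 0.3 in / 0.6 out). ν ∈ {2, 4}, boundary parameter
   r ∈ {1, 2} by default and fully configurable (figure-scale discs of
   radius 4–6 are reproducible by passing those radii). One stated
   parameter of this design, ψ_m′ = 1, is a degenerate failure
   probability; the generator uses ψ_m′ = 0.5, consistent with designs
   1–2.

Locations default to a jittered unit-spacing grid (n = 293, the melanoma
sample's size); the benchmark conclusions do not depend on the particular
layout. What the generators do **not** emulate: library-size variation,
zero inflation beyond NB, segmentation noise, multi-sample batch
structure, or cell-type composition — passing benchmarks here shows
correctness of the method under its own assumptions, not robustness to
those real-data artifacts.

## Benchmarks and problem sizes

The packaged benchmarks are scaled to run on one CPU:

- Null calibration (acceptance script and suite): replicated design-2
  data at ν = 0, n = 150 locations, 2,500 iterations — the reduced desk
  setting. Each replicate draws its own jittered-grid layout and MST, so
  rejection-rate estimates carry no shared-layout random effect; the
  binomial-band check of the 0.05 level is applied to the pooled
  replicates, and the permutation baselines (bivariate Moran's I on
  Delaunay weights, Lee's L on the ε-graph, Pearson; 199 permutations)
  are evaluated on identical replicates.
- Power: design 1 with ν = ±0.75, l = 3.6 at the study scale n = 293,
  2,500 iterations, 50 replicates.
- Boundary recovery: design 3 (linear, ν = 4), HS vs ICAR on the same
  kNN (k = 3) graph, n = 293, 20 replicates, slope-field MSE.
- Sampler oracles: dense closed-form conditional (n = 15), exact-likelihood
  Metropolis–Hastings (n = 10), and 200-replicate simulation-based
  calibration (n = 20). The SBC generator samples the implied prior by a
  prior-only Gibbs chain written directly from the conditional densities:
  the coefficient prior is defined as the product of the IGMRF kernel and
  the proper diagonal factor, so its joint normalization is implicit and
  forward sampling of (τ, Λ, β) from closed form would target a different
  joint.

## Known limitations

- Local-scale updates on cyclic graphs are composite-likelihood (exact on
  trees); this mirrors the design trade-off of using denser backbones.
- Per-pair chains at small n with weakly identified slopes carry
  noticeable Monte Carlo noise in tail summaries at 2,500 iterations;
  longer chains sharpen p_d.
- The dispersion r is location-constant; no zero-inflated variant.
- Graphs are static: the spanning tree is not resampled within MCMC.
- 2D coordinates only.
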