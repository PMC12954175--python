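# spacebf

Bayesian spatial co-expression analysis for spatial omics data.

Spatial transcriptomics and mass-spectrometry imaging measure molecule
abundance at thousands of tissue locations. A recurring question is whether
two molecules — a ligand and its receptor, two keratins, two ECM peptides —
are *co-expressed*, and where. Exploratory geospatial indices (bivariate
Moran's I, Lee's L) answer this with a spatially lagged correlation, but
when each molecule is itself spatially autocorrelated their permutation
tests reject far too often. `spacebf` instead fits a generative spatially
varying coefficient (SVC) regression per molecule pair and reads
co-expression off the posterior of the slope field.

## Model

For locations s_1..s_n, outcome molecule m and predictor molecule m′:

- Gaussian: X^m(s_k) = β₀(s_k) + X^{m′}(s_k) β₁(s_k) + ε_k, ε_k ~ N(0, σ²)
- Negative binomial (counts): X^m(s_k) ~ NB(ψ_k, r) with
  logit(ψ_k) = β₀(s_k) + X^{m′}(s_k) β₁(s_k), dispersion r constant.

β₁(s_k) > 0 means local co-expression at s_k, β₁(s_k) < 0 avoidance; the
tissue-wide mean  β̄₁ = (1/n) Σ_k β₁(s_k) summarises the global pattern.

Smoothness is imposed through a **fused horseshoe** prior on the edges of a
spatial graph (MST by default, kNN/Delaunay/ε-neighbourhood supported): for
each edge i joining (k₁, k₂) and field j ∈ {0, 1},

    Δβ_ji = β_j(s_{k₁}) − β_j(s_{k₂}) ~ N(0, Λ²_ji τ_j² σ²),
    Λ_ji ~ C⁺(0,1),   τ_j ~ C⁺(0,1),

an intrinsic GMRF with precision L(Λ_j)/τ_j²σ², L(Λ_j) = D′ diag(Λ_j⁻²) D.
The global scale τ_j sets overall smoothness; the heavy-tailed local scales
let individual edges escape shrinkage, so sharp expression boundaries are
preserved. Setting Λ ≡ 1 recovers the standard ICAR prior. Inference is a
Gibbs sampler with Pólya–Gamma augmentation for the NB likelihood, sparse
banded Cholesky coefficient updates, and an interweaved non-centered update
of the global scales. Global and local significance use credible intervals
and the probability of direction p_d (P_two = 2(1 − p_d)), with BH FDR
control across pairs.

## Worked example

```python
import numpy as np
from spacebf import (grid_coords, simulate_design1, make_predictor,
                     SVCModelSpec, build_mst, fit, global_test, local_test)

coords = grid_coords(n=293, seed=0)                  # jittered unit grid
pair = simulate_design1(coords, l=3.6, nu=0.75, seed=1)   # NB counts
graph = build_mst(coords, jitter_scale=0.01, seed=0)
spec = SVCModelSpec(y=pair.xm, x=make_predictor(pair.xmp, "nb"),
                    graph=graph, family="nb")
draws = fit(spec, n_iter=2500, burn_in=1250, seed=2)
res = global_test(draws)
sig, ci = local_test(draws)
print(f"mean slope {res.mean_slope:.2f}, "
      f"95% CI ({res.global_ci[0]:.2f}, {res.global_ci[1]:.2f}), "
      f"p = {res.global_p:.4f}, significant spots: {int(sig.sum())}")
```

Output:

```
mean slope 0.78, 95% CI (0.15, 1.42), p = 0.0304, significant spots: 137
```

The simulated truth is a constant slope of 0.75: the posterior mean of the
tissue-wide slope (0.78) is close to it, the credible interval excludes 0,
and the two-sided probability-of-direction p-value flags the pair as
globally co-expressed; 137 of 293 locations are individually significant.

A command-line interface mirrors the library:

```sh
spacebf simulate --design 2 --n 150 --l 1.8 --nu 0 --seed 1 --out sim/
spacebf fit --expression expr.csv --coords coords.csv --pairs pairs.tsv \
            --family nb --graph mst --out results/
spacebf baselines --expression expr.csv --coords coords.csv \
            --pairs pairs.tsv --method moran --weights delaunay --out moran.tsv
spacebf benchmark --design 2 --l 1.8 --nu 0 --reps 100 --out bench.tsv
```

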