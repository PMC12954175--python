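"""Replicated benchmark drivers: type-I error / power grids and slope-field
MSE comparisons between priors, mirroring the simulation study layouts.

These are the workhorses behind the ``spacebf benchmark`` CLI command and
the reproduction script; each replicate simulates a pair, fits the NB SVC
model, and applies the global test (or scores the slope field against the
simulated truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import baselines as bl
from .graph import SpatialGraph, build_delaunay, build_knn, build_mst
from .model import SVCModelSpec, make_predictor
from .sampler import PriorConfig, fit
from .simulate import (SimulatedPair, grid_coords, simulate_design1,
                       simulate_design2, simulate_design3, slope_mse)
from .testing import global_test

__all__ = ["make_graph", "fit_pair", "rejection_benchmark", "mse_benchmark",
           "BenchmarkResult"]


def make_graph(coords, kind: str = "mst", k: int = 3,
               seed: int | None = 0) -> SpatialGraph:
    if kind == "mst":
        return build_mst(coords, jitter_scale=0.01, seed=seed)
    if kind == "knn":
        return build_knn(coords, k=k)
    if kind == "delaunay":
        return build_delaunay(coords)
    raise ValueError(f"unknown graph kind {kind!r}")


def fit_pair(pair: SimulatedPair, graph: SpatialGraph | None = None,
             graph_kind: str = "mst", prior: str = "horseshoe", k: int = 3,
             n_iter: int = 5000, burn_in: int = 2500,
             seed: int | None = None, family: str = "nb", **fit_kwargs):
    """Fit one simulated pair: transform the predictor, build the graph,
    run the chain.  Returns the PosteriorDraws."""
    if graph is None:
        graph = make_graph(pair.coords, graph_kind, k=k, seed=seed)
    x = make_predictor(pair.xmp, family)
    spec = SVCModelSpec(y=pair.xm, x=x, graph=graph, family=family)
    cfg = PriorConfig(prior=prior)
    return fit(spec, cfg, n_iter=n_iter, burn_in=burn_in, seed=seed,
               **fit_kwargs)


@dataclass
class BenchmarkResult:
    rejections: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    baseline_pvalues: dict | None = None
    mse: dict | None = None
    config: dict | None = None

    @property
    def rejection_rate(self) -> float:
        return float(np.mean(self.rejections))


def _simulate(design: int, coords, l, nu, seed, boundary="linear",
              r_boundary=1.0):
    if design == 1:
        return simulate_design1(coords, l=l, nu=nu, seed=seed)
    if design == 2:
        return simulate_design2(coords, l=l, nu=nu, seed=seed)
    if design == 3:
        return simulate_design3(coords, boundary=boundary,
                                r_boundary=r_boundary, nu=nu, l=l, seed=seed)
    raise ValueError("design must be 1, 2 or 3")


def rejection_benchmark(design: int, nu: float, l: float, n: int = 293,
                        n_reps: int = 100, n_iter: int = 2500,
                        burn_in: int | None = None, alpha: float = 0.05,
                        seed: int = 0, graph_kind: str = "mst",
                        prior: str = "horseshoe",
                        run_baselines: bool = False,
                        n_perm: int = 199) -> BenchmarkResult:
    """Empirical rejection rate of the global test over replicates.

    nu = 0 estimates the type-I error; nu != 0 the power.  Optionally runs
    the permutation-test baselines (bivariate Moran's I on Delaunay
    weights, Lee's L on the epsilon-neighbourhood graph, Pearson) on the
    identical replicates.
    """
    if burn_in is None:
        burn_in = n_iter // 2
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(2**31, size=n_reps)
    rej = np.zeros(n_reps, dtype=bool)
    pvals = np.zeros(n_reps)
    base_p = {"moran": [], "lee": [], "pearson": []} if run_baselines else None
    # a fresh layout and graph per replicate: rejection-rate estimates then
    # carry no shared-layout random effect across replicates
    for i, s in enumerate(rep_seeds):
        coords = grid_coords(n, seed=int(s) + 3)
        graph = make_graph(coords, graph_kind, seed=int(s) + 4)
        pair = _simulate(design, coords, l, nu, int(s))
        draws = fit_pair(pair, graph=graph, prior=prior, n_iter=n_iter,
                         burn_in=burn_in, seed=int(s) + 1)
        res = global_test(draws, alpha=alpha)
        rej[i] = res.global_sig
        pvals[i] = res.global_p
        if run_baselines:
            xl, yl = np.log1p(pair.xmp), np.log1p(pair.xm)
            for name, fn, W in (("moran", bl.bivariate_moran,
                                 bl.delaunay_weights(coords)),
                                ("lee", bl.lee_l, bl.eps_weights(coords, "auto")),
                                ("pearson", bl.pearson, None)):
                _, p = bl.permutation_test(fn, xl, yl, W, n_perm=n_perm,
                                           seed=int(s) + 2)
                base_p[name].append(p)
    if run_baselines:
        base_p = {k: np.asarray(v) for k, v in base_p.items()}
    return BenchmarkResult(
        rejections=rej, pvalues=pvals, baseline_pvalues=base_p,
        config=dict(design=design, nu=nu, l=l, n=n, n_reps=n_reps,
                    n_iter=n_iter, burn_in=burn_in, alpha=alpha, seed=seed,
                    graph_kind=graph_kind, prior=prior))


def mse_benchmark(boundary: str = "linear", r_boundary: float = 1.0,
                  nu: float = 4.0, n: int = 293, n_reps: int = 20,
                  n_iter: int = 2500, burn_in: int | None = None,
                  seed: int = 0, k: int = 3,
                  priors: tuple = ("horseshoe", "icar"),
                  graph_kind: str = "knn") -> BenchmarkResult:
    """Slope-field MSE of competing priors on the same replicates
    (spatially varying truth with a sharp boundary)."""
    if burn_in is None:
        burn_in = n_iter // 2
    master = np.random.default_rng(seed)
    coords = grid_coords(n, seed=int(master.integers(2**31)))
    rep_seeds = master.integers(2**31, size=n_reps)
    graph = make_graph(coords, graph_kind, k=k, seed=int(master.integers(2**31)))
    mse = {p: np.zeros(n_reps) for p in priors}
    for i, s in enumerate(rep_seeds):
        pair = _simulate(3, coords, 7.2, nu, int(s), boundary=boundary,
                         r_boundary=r_boundary)
        for p in priors:
            draws = fit_pair(pair, graph=graph, prior=p, n_iter=n_iter,
                             burn_in=burn_in, seed=int(s) + 1)
            mse[p][i] = slope_mse(draws.beta1.mean(axis=0), pair.truth)
    return BenchmarkResult(
        mse=mse,
        config=dict(boundary=boundary, r_boundary=r_boundary, nu=nu, n=n,
                    n_reps=n_reps, n_iter=n_iter, burn_in=burn_in, seed=seed,
                    k=k, graph_kind=graph_kind))
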