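"""Downstream analysis of fitted slope surfaces.

Standardise each pair's posterior-mean slope field to beta1* (centred,
unit sample sd), cluster pairs into recurring spatial patterns and spots
into regions (agglomerative Ward clustering, deterministic), sum beta1*
within annotated cell types as an enrichment score, and zero out locations
that fail the local significance test before export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "SlopeSurface",
    "standardize_surface",
    "cluster_patterns",
    "cluster_spots",
    "celltype_enrichment",
    "mask_insignificant",
]


@dataclass
class SlopeSurface:
    beta1_mean: np.ndarray
    beta1_star: np.ndarray
    mean_slope: float
    sd_slope: float
    pair_id: str | None = None


def standardize_surface(beta1_mean, pair_id: str | None = None) -> SlopeSurface:
    """beta1* = (beta1 - mean) / sd, sample sd (n - 1 denominator)."""
    b = np.asarray(beta1_mean, dtype=float).ravel()
    if b.size < 2:
        raise ValueError("need at least 2 locations")
    mu = float(b.mean())
    sd = float(b.std(ddof=1))
    if sd == 0:
        raise ValueError("constant slope surface cannot be standardized")
    return SlopeSurface(b, (b - mu) / sd, mu, sd, pair_id)


def _ward_labels(X: np.ndarray, n_clusters: int) -> np.ndarray:
    if not 1 <= n_clusters <= X.shape[0]:
        raise ValueError("n_clusters must be between 1 and the number of rows")
    if n_clusters == X.shape[0]:
        return np.arange(X.shape[0])
    Z = linkage(X, method="ward", metric="euclidean")
    return fcluster(Z, t=n_clusters, criterion="maxclust") - 1


def cluster_patterns(surfaces, n_clusters: int = 3) -> np.ndarray:
    """Group pairs (rows = standardized surfaces) into spatial patterns."""
    X = np.atleast_2d(np.asarray(surfaces, dtype=float))
    return _ward_labels(X, n_clusters)


def cluster_spots(surfaces, n_clusters: int = 4) -> np.ndarray:
    """Group spots by their across-pair slope profiles (transposed input)."""
    X = np.atleast_2d(np.asarray(surfaces, dtype=float)).T
    return _ward_labels(X, n_clusters)


def celltype_enrichment(beta1_star, labels) -> dict:
    """Per-category sum of beta1*; categories sum to ~0 by centring."""
    b = np.asarray(beta1_star, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if labels.shape != b.shape:
        raise ValueError("labels must cover every location")
    return {str(c): float(b[labels == c].sum()) for c in np.unique(labels)}


def mask_insignificant(beta1_star, local_sig_mask) -> np.ndarray:
    """Zero out locations whose local credible interval includes 0."""
    b = np.asarray(beta1_star, dtype=float).ravel()
    m = np.asarray(local_sig_mask, dtype=bool).ravel()
    if m.shape != b.shape:
        raise ValueError("mask length must match the surface")
    return np.where(m, b, 0.0)
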