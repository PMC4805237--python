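"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cuckoomorph as cm

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_table() -> pd.DataFrame:
    """One paper-like synthetic museum series (274 specimens, seed 1)."""
    return cm.sample_specimens(cm.build_config("paper_like", seed=1))


@pytest.fixture(scope="session")
def paper_config():
    return cm.build_config("paper_like", seed=1)


def brute_force_complete_linkage(X: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) agglomerative complete linkage by direct recomputation.

    At every step recomputes all pairwise maximum inter-cluster distances
    from scratch and merges the closest pair.  Returns (cluster_a,
    cluster_b, height) merges with clusters as frozensets of leaf indices.
    """
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or h < best[2]:
                    best = (a, b, h)
        a, b, h = best
        merged = clusters[a] | clusters[b]
        merges.append((clusters[a], clusters[b], h))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def lda_argmax_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-specimen classification by direct discriminant-score argmax.

    Pooled covariance as the prior-weighted mean of biased class
    covariances, proportional priors, linear discriminant scores
    delta_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k.
    """
    labels, counts = np.unique(y, return_counts=True)
    priors = counts / counts.sum()
    mus = np.array([X[y == lab].mean(axis=0) for lab in labels])
    S = sum(
        p * np.cov(X[y == lab], rowvar=False, bias=True)
        for p, lab in zip(priors, labels)
    )
    Sinv = np.linalg.inv(S)
    scores = X @ Sinv @ mus.T - 0.5 * np.einsum("kj,jl,kl->k", mus, Sinv, mus) + np.log(priors)
    return labels[np.argmax(scores, axis=1)]


@pytest.fixture(scope="session")
def complete_linkage_oracle():
    return brute_force_complete_linkage


@pytest.fixture(scope="session")
def lda_oracle():
    return lda_argmax_oracle


def exact_correlation_sample(R: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Draw an n x p sample whose *sample* correlation matrix equals R exactly.

    Whitens a random Gaussian draw against its own sample correlation, then
    recolors with the Cholesky factor of the target.
    """
    p = R.shape[0]
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    L = np.linalg.cholesky(np.corrcoef(X, rowvar=False))
    W = X @ np.linalg.inv(L).T          # sample correlation = identity
    Y = W @ np.linalg.cholesky(R).T
    return (Y - Y.mean(0)) / Y.std(0, ddof=1)


@pytest.fixture(scope="session")
def exact_corr_sampler():
    return exact_correlation_sample
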