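"""Partial-distance-strategy fuzzy C-means (PDSFCM) over NaN-padded PP windows.

The 48-sample post-meal windows carry NaNs both from sensor dropouts and from
structural padding; the partial distance of Hathaway & Bezdek rescales the
observed-coordinate sum of squares by D/I (D = 48 dimensions, I = observed
count) so distances stay comparable across windows with different amounts of
missingness.  Cluster count and fuzzifier are picked by exhaustive grid
search minimizing the Fukuyama–Sugeno validity index (lower is better).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

D_FULL = 48  # dimensionality of a PP window


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterSet:
    """A fitted fuzzy partition: prototypes, memberships and validity score."""

    n_clusters: int
    fuzzifier: float
    prototypes: np.ndarray  # (nC, D) complete vectors, mg/dL
    memberships: np.ndarray  # (N, nC); rows sum to 1
    objective_history: tuple[float, ...]
    validity: float  # Fukuyama–Sugeno index of this fit
    seed: int

    def hard_assignments(self) -> np.ndarray:
        """Argmax membership per profile, ties to the lowest cluster index."""
        return np.argmax(self.memberships, axis=1)

    def to_json(self, path) -> None:
        payload = {
            "n_clusters": self.n_clusters,
            "fuzzifier": self.fuzzifier,
            "seed": self.seed,
            "validity": self.validity,
            "prototypes": self.prototypes.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass(frozen=True)
class ClusterSearchGrid:
    """Grid-search configuration for (nC, m) selection.

    The fuzzifier grid spans the conventional (1, 3] range but starts at 1.2:
    the membership update degenerates as m -> 1 (crisp limit).
    """

    nC_range: tuple[int, ...] = tuple(range(2, 31))
    m_grid: tuple[float, ...] = tuple(np.round(np.arange(1.2, 3.01, 0.2), 1))
    restarts: int = 5
    tol: float = 1e-5
    max_iter: int = 200
    min_cluster_size: int = 3

    def __post_init__(self) -> None:
        if any(nc < 2 for nc in self.nC_range):
            raise ClusteringError("every nC must be >= 2")
        if any(m <= 1 for m in self.m_grid):
            raise ClusteringError("every fuzzifier must be > 1")


def _as_2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def _pairwise_partial_sqdist(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Squared partial distances between rows of X (with NaN) and complete rows of V.

    d^2(x, v) = (D / I) * sum_{k observed}(x_k - v_k)^2 with D the full
    dimensionality and I the number of observed coordinates of x.
    """
    X = _as_2d(X)
    V = _as_2d(V)
    obs = ~np.isnan(X)
    counts = obs.sum(axis=1)
    if np.any(counts == 0):
        raise ClusteringError("a profile has no observed entries")
    X0 = np.where(obs, X, 0.0)
    sq = (
        (X0**2 * obs).sum(axis=1, keepdims=True)
        - 2.0 * X0 @ V.T
        + obs.astype(float) @ (V**2).T
    )
    np.maximum(sq, 0.0, out=sq)
    return (X.shape[1] / counts)[:, None] * sq


def partial_distance(x: np.ndarray, v: np.ndarray) -> float:
    """Partial (missing-tolerant) Euclidean distance between a profile and a prototype.

    Coincides with the plain Euclidean distance when ``x`` is complete.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if x.shape != v.shape:
        raise ClusteringError("x and v must have the same length")
    return float(np.sqrt(_pairwise_partial_sqdist(x[None, :], v[None, :])[0, 0]))


def _memberships_from_sqdist(sq: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; rows sum to 1.

    Zero-distance convention: a profile at distance 0 from one or more
    prototypes splits membership 1/|Z| over those prototypes.
    """
    W = np.zeros_like(sq)
    zero = sq <= 0.0
    has_zero = zero.any(axis=1)
    if has_zero.any():
        z = zero[has_zero]
        W[has_zero] = z / z.sum(axis=1, keepdims=True)
    reg = ~has_zero
    if reg.any():
        r = sq[reg] ** (-1.0 / (m - 1.0))
        W[reg] = r / r.sum(axis=1, keepdims=True)
    return W


def update_memberships(X: np.ndarray, V: np.ndarray, m: float) -> np.ndarray:
    """Fuzzy membership matrix (N x nC) for profiles X given prototypes V."""
    if m <= 1:
        raise ClusteringError("fuzzifier m must be > 1")
    return _memberships_from_sqdist(_pairwise_partial_sqdist(X, V), m)


def update_centroids(X: np.ndarray, W: np.ndarray, m: float) -> np.ndarray:
    """Prototype update: per-coordinate weighted mean over observing profiles.

    Each coordinate of each prototype averages only the profiles that observe
    that coordinate, weighted by membership^m, so prototypes are always
    complete even when every profile has gaps.
    """
    X = _as_2d(X)
    W = _as_2d(np.asarray(W, dtype=float))
    obs = ~np.isnan(X)
    U = W**m
    X0 = np.where(obs, X, 0.0)
    num = U.T @ X0
    den = U.T @ obs.astype(float)
    bad = den <= 0.0
    if bad.any():
        i, k = np.argwhere(bad)[0]
        raise ClusteringError(
            f"coordinate {k} of prototype {i} is observed by no weighted profile"
        )
    return num / den


def _objective(sq: np.ndarray, W: np.ndarray, m: float) -> float:
    return float((W**m * sq).sum())


def pdsfcm_fit(
    X: np.ndarray,
    n_clusters: int,
    m: float,
    grid: ClusterSearchGrid | None = None,
    seed: int = 0,
) -> ClusterSet:
    """Fit partial-distance fuzzy C-means by alternating minimization.

    Memberships are initialized from a symmetric Dirichlet(1) per row;
    prototypes and memberships alternate until the largest membership change
    drops below ``grid.tol`` or ``grid.max_iter`` iterations; the best of
    ``grid.restarts`` seeded restarts (by final objective) is returned.
    """
    grid = grid or ClusterSearchGrid()
    X = _as_2d(X)
    N = X.shape[0]
    if N <= n_clusters:
        raise ClusteringError(f"need more profiles ({N}) than clusters ({n_clusters})")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(grid.restarts):
        W = rng.dirichlet(np.ones(n_clusters), size=N)
        history: list[float] = []
        for _it in range(grid.max_iter):
            V = update_centroids(X, W, m)
            sq = _pairwise_partial_sqdist(X, V)
            W_new = _memberships_from_sqdist(sq, m)
            history.append(_objective(sq, W_new, m))
            delta = np.abs(W_new - W).max()
            W = W_new
            if delta < grid.tol:
                break
        V = update_centroids(X, W, m)
        obj = history[-1]
        if best is None or obj < best[0]:
            best = (obj, V, W, history)
    obj, V, W, history = best
    return ClusterSet(
        n_clusters=n_clusters,
        fuzzifier=float(m),
        prototypes=V,
        memberships=W,
        objective_history=tuple(history),
        validity=fukuyama_sugeno(X, W, V, m),
        seed=seed,
    )


def fukuyama_sugeno(X: np.ndarray, W: np.ndarray, V: np.ndarray, m: float) -> float:
    """Fukuyama–Sugeno cluster-validity index; lower is better.

    FS = sum_ij w_ij^m [ d^2(x_j, v_i) - ||v_i - v_bar||^2 ] where d is the
    partial distance, v_bar is the grand prototype (the membership-weighted
    mean of X under the same partial-data convention), and the separation
    term uses the plain Euclidean distance — prototypes are complete.
    """
    X = _as_2d(X)
    W = _as_2d(np.asarray(W, dtype=float))
    V = _as_2d(V)
    sq = _pairwise_partial_sqdist(X, V)
    # grand prototype: partial-data weighted mean of X, one profile weight
    # u_j = sum_i w_ij^m, each coordinate averaged over observing profiles
    u = (W**m).sum(axis=1, keepdims=True)
    obs = ~np.isnan(X)
    num = (u * np.where(obs, X, 0.0)).sum(axis=0)
    den = (u * obs).sum(axis=0)
    if np.any(den <= 0):
        raise ClusteringError("a coordinate is observed by no profile")
    v_bar = num / den
    sep = ((V - v_bar[None, :]) ** 2).sum(axis=1)
    U = W**m
    return float((U * (sq - sep[None, :])).sum())


def select_clustering(
    X: np.ndarray, grid: ClusterSearchGrid | None = None, seed: int = 0
) -> ClusterSet:
    """Exhaustive (nC, m) grid search minimizing the Fukuyama–Sugeno index.

    Fits every grid cell with ``pdsfcm_fit``; cells whose smallest
    hard-assigned cluster holds fewer than ``grid.min_cluster_size`` profiles
    are rejected (a seasonal model cannot be identified on so few PPs).
    Deterministic for a given seed.
    """
    grid = grid or ClusterSearchGrid()
    X = _as_2d(X)
    N = X.shape[0]
    best: ClusterSet | None = None
    for cell, (nc, m) in enumerate(
        (nc, m) for nc in sorted(grid.nC_range) for m in sorted(grid.m_grid)
    ):
        if N <= nc:
            continue
        fit = pdsfcm_fit(X, nc, m, grid, seed=seed + 7919 * cell)
        counts = np.bincount(fit.hard_assignments(), minlength=nc)
        if counts.min() < grid.min_cluster_size:
            logger.info(
                "grid cell nC=%d m=%.2f rejected: smallest cluster %d", nc, m, counts.min()
            )
            continue
        if best is None or fit.validity < best.validity:
            best = fit
    if best is None:
        raise ClusteringError(
            "every grid cell was rejected (clusters too small); more data needed"
        )
    return best


def score_membership(partial_pp: np.ndarray, cluster_set: ClusterSet) -> np.ndarray:
    """Membership weights of a partially observed window against fitted prototypes.

    Unobserved positions must be NaN; the fitted fuzzifier is reused, so the
    weights are exactly the training-time membership rule applied to the
    observed prefix.  Weights sum to 1.
    """
    x = np.asarray(partial_pp, dtype=float)
    if np.all(np.isnan(x)):
        raise ClusteringError("cannot score an all-missing window")
    if cluster_set.n_clusters == 1:
        return np.ones(1)
    sq = _pairwise_partial_sqdist(x[None, :], cluster_set.prototypes)
    return _memberships_from_sqdist(sq, cluster_set.fuzzifier)[0]
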