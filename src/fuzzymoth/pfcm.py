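"""Pythagorean fuzzy c-means (PFCM) clustering, used to group moths with
similar stimulus-response behavior.

PFCM is the classical fuzzy c-means alternating scheme run on PFN-valued
data points with the Pythagorean distance: the per-coordinate distance is
Euclidean in ``(mu^2, nu^2, pi^2)`` space scaled by ``1/sqrt(2)`` and
coordinates are aggregated root-mean-square.  Cluster centroids are
degenerate-interval PFN vectors updated as membership-weighted means in
squared-degree space (the Frechet mean under the chosen metric).

Initial centroids are either random data points or searched by WWO, where
each candidate centroid set is scored by the final clustering objective of
a short PFCM run started from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from . import pfn as pf
from . import wwo

__all__ = ["PythagoreanFuzzyCMeans", "ClusterConfig", "update_memberships",
           "update_centroids", "pfcm_objective", "pfcm_cluster",
           "wwo_init_centroids", "group_training_set"]


@dataclass
class ClusterConfig:
    """PFCM defaults: five clusters with fuzzifier ``m = 2``."""

    c: int = 5
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 200
    u_floor: float = 0.1
    init: str = "random"
    wwo_budget: int = 200
    seed: int | None = None

    def __post_init__(self):
        if self.m <= 1 or self.c < 2 or self.tol <= 0:
            raise ValueError("require m > 1, c >= 2, tol > 0")


def _as_pfn_data(X: np.ndarray) -> np.ndarray:
    """Accept crisp ``(n, D)`` (fuzzified) or PFN ``(n, D, 4)`` data."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        return pf.arr_fuzzify(X)
    if X.ndim == 3 and X.shape[-1] == 4:
        return X
    raise ValueError("data must be (n, D) crisp or (n, D, 4) PFN")


def _sq_degrees(P: np.ndarray) -> np.ndarray:
    """Map PFN data to centroid squared-degree coordinates
    ``(mu^2, nu^2, pi^2) / sqrt(2)`` — the space in which the Pythagorean
    distance is Euclidean."""
    c = pf.arr_centroid(P)
    mu2 = c[..., 0] ** 2
    nu2 = c[..., 1] ** 2
    pi2 = np.maximum(0.0, 1.0 - mu2 - nu2)
    return np.stack([mu2, nu2, pi2], axis=-1) / np.sqrt(2.0)


def _dist_sq(Phi_x: np.ndarray, Phi_v: np.ndarray) -> np.ndarray:
    """Squared PFN vector distances ``(c, n)`` from squared-degree
    coordinates ``Phi_x (n, D, 3)`` and ``Phi_v (c, D, 3)`` (RMS over D)."""
    D = Phi_x.shape[1]
    diff = Phi_x[None, :, :, :] - Phi_v[:, None, :, :]
    return np.einsum("cndk,cndk->cn", diff, diff) / D


def update_memberships(data: np.ndarray, V: np.ndarray, m: float = 2.0) -> np.ndarray:
    """FCM membership update ``u_ij = 1 / sum_k (d_ij/d_kj)^(2/(m-1))``;
    points coinciding with centroids split full membership equally among
    the zero-distance clusters.  Columns sum to 1."""
    P, Vp = _as_pfn_data(data), _as_pfn_data(V)
    d2 = _dist_sq(_sq_degrees(P), _sq_degrees(Vp))       # (c, n)
    zero = d2 <= 1e-30
    U = np.empty_like(d2)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
    any_zero = zero.any(axis=0)
    U[:, ~any_zero] = inv[:, ~any_zero] / inv[:, ~any_zero].sum(axis=0)
    if any_zero.any():
        U[:, any_zero] = zero[:, any_zero] / zero[:, any_zero].sum(axis=0)
    return U


def update_centroids(data: np.ndarray, U: np.ndarray, m: float = 2.0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Weighted-mean centroid update in squared-degree space with weights
    ``u^m``; emits degenerate-interval PFN centroids (renormalised onto the
    Pythagorean simplex where needed).  A cluster with all-zero weight is
    reseeded at a random data point."""
    P = _as_pfn_data(data)
    c0 = pf.arr_centroid(P)
    mu2, nu2 = c0[..., 0] ** 2, c0[..., 1] ** 2        # (n, D)
    W = np.asarray(U, dtype=float) ** m                 # (c, n)
    tot = W.sum(axis=1)
    V = np.empty((U.shape[0], P.shape[1], 4))
    for i in range(U.shape[0]):
        if tot[i] <= 0:
            j = (rng or np.random.default_rng(0)).integers(P.shape[0])
            warnings.warn(f"cluster {i} lost all weight; reseeded at data "
                          f"point {j}", RuntimeWarning, stacklevel=2)
            V[i] = P[j]
            continue
        m2 = W[i] @ mu2 / tot[i]
        n2 = W[i] @ nu2 / tot[i]
        over = m2 + n2 > 1.0
        if np.any(over):                                # numerical guard
            s = np.where(over, m2 + n2, 1.0)
            m2, n2 = m2 / s, n2 / s
        mu, nu = np.sqrt(m2), np.sqrt(n2)
        V[i] = np.stack([mu, mu, nu, nu], axis=-1)
    return V


def pfcm_objective(data: np.ndarray, U: np.ndarray, V: np.ndarray,
                   m: float = 2.0) -> float:
    """Clustering objective ``J(U, V) = (1/(c n)) sum_ij u_ij^m d_ij^2``."""
    P, Vp = _as_pfn_data(data), _as_pfn_data(V)
    d2 = _dist_sq(_sq_degrees(P), _sq_degrees(Vp))
    c, n = d2.shape
    return float(np.sum(np.asarray(U) ** m * d2) / (c * n))


def _random_init(P: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(P.shape[0], size=c, replace=False)
    return P[idx].copy()


def wwo_init_centroids(data: np.ndarray, config: ClusterConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """WWO search for high-quality initial centroids.

    The genome is a flattened ``(c, D, 2)`` box: genes ``(a, b)`` map to a
    degenerate PFN with ``mu^2 = a`` and ``nu^2 = b (1 - a)`` (valid by
    construction).  Each candidate is scored by the objective reached after
    a short PFCM refinement started from it.
    """
    P = _as_pfn_data(data)
    rng = rng or np.random.default_rng(config.seed)
    n, D = P.shape[0], P.shape[1]

    def decode(genome: np.ndarray) -> np.ndarray:
        G = genome.reshape(config.c, D, 2)
        mu = np.sqrt(G[..., 0])
        nu = np.sqrt(G[..., 1] * (1.0 - G[..., 0]))
        return np.stack([mu, mu, nu, nu], axis=-1)

    def objective(genome: np.ndarray) -> float:
        V = decode(genome)
        for _ in range(3):
            U = update_memberships(P, V, config.m)
            V = update_centroids(P, U, config.m, rng)
        return pfcm_objective(P, U, V, config.m)

    space = wwo.SearchSpace.unit(config.c * D * 2)
    res = wwo.optimize(objective, space,
                       wwo.OptimizerConfig(budget=config.wwo_budget), rng)
    return decode(res.x)


def pfcm_cluster(data: np.ndarray, config: ClusterConfig | None = None,
                 rng: np.random.Generator | None = None,
                 V0: np.ndarray | None = None):
    """Alternate membership/centroid updates until the membership matrix
    changes by less than ``tol`` (max-abs) or ``max_iter`` is reached.

    Returns ``(U, V, trace)`` where ``trace`` is the non-increasing
    objective after each iteration.
    """
    cfg = config or ClusterConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    P = _as_pfn_data(data)
    if P.shape[0] < cfg.c:
        raise ValueError("need at least c data points")
    if V0 is not None:
        V = _as_pfn_data(V0)
    elif cfg.init == "wwo":
        V = wwo_init_centroids(P, cfg, rng)
    else:
        V = _random_init(P, cfg.c, rng)
    U_prev = None
    trace = []
    for _ in range(cfg.max_iter):
        U = update_memberships(P, V, cfg.m)
        V = update_centroids(P, U, cfg.m, rng)
        trace.append(pfcm_objective(P, U, V, cfg.m))
        if U_prev is not None and np.max(np.abs(U - U_prev)) < cfg.tol:
            break
        U_prev = U
    return U, V, trace


def group_training_set(data, U: np.ndarray, i: int, u_floor: float = 0.1):
    """Training subset for group ``i``: indices of the points with
    ``u_ij > u_floor`` and their membership weights."""
    u = np.asarray(U)[i]
    idx = np.flatnonzero(u > u_floor)
    if idx.size == 0:
        raise ValueError(
            f"no point has membership above u_floor={u_floor} for group {i}; "
            "lower u_floor")
    return idx, u[idx]


class PythagoreanFuzzyCMeans(ClusterMixin, BaseEstimator):
    """Soft clustering of PFN-valued (or crisp, fuzzified on the fly) data.

    Parameters mirror :class:`ClusterConfig`; ``init='wwo'`` seeds the
    centroids with a WWO search.  After ``fit``:

    ``membership_matrix_`` : (c, n) column-stochastic memberships
    ``centroids_``         : (c, D, 4) degenerate-interval PFN centroids
    ``labels_``            : hard assignment (argmax membership)
    ``objective_trace_``   : non-increasing objective values
    """

    def __init__(self, n_clusters=5, m=2.0, tol=1e-5, max_iter=200,
                 u_floor=0.1, init="random", wwo_budget=200, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.u_floor = u_floor
        self.init = init
        self.wwo_budget = wwo_budget
        self.random_state = random_state

    def _config(self) -> ClusterConfig:
        return ClusterConfig(c=self.n_clusters, m=self.m, tol=self.tol,
                             max_iter=self.max_iter, u_floor=self.u_floor,
                             init=self.init, wwo_budget=self.wwo_budget,
                             seed=self.random_state)

    def fit(self, X, y=None):
        rng = np.random.default_rng(self.random_state)
        U, V, trace = pfcm_cluster(X, self._config(), rng)
        self.membership_matrix_ = U
        self.centroids_ = V
        self.objective_trace_ = trace
        self.labels_ = np.argmax(U, axis=0)
        self.n_iter_ = len(trace)
        return self

    def predict_membership(self, X) -> np.ndarray:
        check_is_fitted(self, "centroids_")
        return update_memberships(X, self.centroids_, self.m)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_membership(X), axis=0)

    def group_indices(self, i: int):
        """Points (and weights) whose membership in group ``i`` clears the
        floor ``u_floor``."""
        check_is_fitted(self, "membership_matrix_")
        return group_training_set(None, self.membership_matrix_, i, self.u_floor)
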