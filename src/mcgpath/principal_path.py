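"""Principal-path clustering: an ordered, regularized k-means.

The cost of K representatives W (endpoints pinned to the two reference
conformations) with frame assignments c is

    cost(W, c) = Σ_i ‖x_i − W_{c(i)}‖²  +  s · Σ_j ‖W_{j+1} − W_j‖²,

a plain within-cluster sum of squares plus an elastic penalty chaining
consecutive representatives.  Alternating minimization (nearest-representative
assignment, then an exact block-tridiagonal solve for the interior
representatives) decreases the cost monotonically; s = 0 with free endpoints
recovers Lloyd's k-means.  The regularization weight s is selected by
maximizing a Laplace approximation of the Bayesian evidence of the posterior
∝ exp(−cost).

Conformational frames (F, N, 3) are first Kabsch-superposed onto endpoint A
and flattened to 3N vectors, removing roto-translation in the same way the σ
analysis does; generic point clouds (F, D) are used as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded

from .structures import CaTrace, kabsch_superpose

__all__ = [
    "PrincipalPath",
    "pp_cost",
    "fit_principal_path",
    "select_s",
    "nearest_frames",
    "align_frames",
]


def _coords(obj) -> np.ndarray:
    return obj.coords if isinstance(obj, CaTrace) else np.asarray(obj, float)


def align_frames(frames, reference) -> np.ndarray:
    """Kabsch-superpose every frame onto ``reference``; flatten to (F, 3N)."""
    ref = _coords(reference)
    out = np.empty((len(frames), ref.size))
    for i, f in enumerate(frames):
        out[i] = kabsch_superpose(_coords(f), ref)[0].ravel()
    return out


def _as_matrix(frames) -> np.ndarray:
    if hasattr(frames, "coords") and hasattr(frames, "times"):
        frames = frames.coords
    x = np.asarray(frames, float)
    if x.ndim == 3:
        return x.reshape(x.shape[0], -1)
    if x.ndim == 2:
        return x
    raise ValueError(f"frames must be (F, D) or (F, N, 3); got {x.shape}")


@dataclass
class PrincipalPath:
    """Fitted principal path.

    ``representatives`` is (K, D) in the flattened metric space (endpoints
    included); ``assignments`` maps each frame to a representative index;
    ``cost_history`` holds the (non-increasing) cost after each alternating
    iteration.  For conformational input, ``conformations`` carries the
    representatives reshaped to (K, N, 3).
    """

    representatives: np.ndarray
    assignments: np.ndarray
    s: float
    log_evidence: float
    cost_history: np.ndarray
    conformations: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.representatives.shape[0]


def pp_cost(frames, W, assignments, s: float) -> float:
    """Regularized clustering cost (Å² for conformational data).

    Frames and representatives are compared in the flattened coordinate
    space; conformational frames must already share a common alignment
    (see :func:`align_frames`).
    """
    if s < 0:
        raise ValueError("regularization weight s must be non-negative")
    X = _as_matrix(frames)
    W = _as_matrix(W)
    c = np.asarray(assignments, int)
    if c.shape[0] != X.shape[0]:
        raise ValueError("one assignment per frame required")
    if np.any((c < 0) | (c >= W.shape[0])):
        raise ValueError("assignment index out of range")
    data = float(np.sum((X - W[c]) ** 2))
    spring = float(np.sum(np.diff(W, axis=0) ** 2))
    return data + s * spring


def _update_interior(X, W, c, s, pin_endpoints):
    """Exact minimizer of the cost over representatives at fixed assignments.

    Stationarity gives a symmetric tridiagonal system per coordinate:
    (n_j + 2s) W_j − s W_{j−1} − s W_{j+1} = Σ_{i∈C_j} x_i, with pinned
    neighbours moved to the right-hand side.
    """
    K = W.shape[0]
    counts = np.bincount(c, minlength=K).astype(float)
    sums = np.zeros_like(W)
    np.add.at(sums, c, X)

    if s == 0.0:
        Wn = W.copy()
        rng = range(1, K - 1) if pin_endpoints else range(K)
        for j in rng:
            if counts[j] > 0:
                Wn[j] = sums[j] / counts[j]
            else:
                warnings.warn(f"empty cluster {j} with s = 0: representative "
                              "kept at its previous position", stacklevel=3)
        return Wn

    if pin_endpoints:
        m = K - 2
        if m == 0:
            return W.copy()
        diag = counts[1:-1] + 2.0 * s
        rhs = sums[1:-1].copy()
        rhs[0] += s * W[0]
        rhs[-1] += s * W[-1]
        if np.any(counts[1:-1] == 0):
            for j in np.nonzero(counts[1:-1] == 0)[0]:
                warnings.warn(
                    f"empty cluster {j + 1}: representative tethered by the "
                    "spring term only", stacklevel=3)
    else:
        m = K
        # free ends have spring degree 1
        diag = counts + 2.0 * s
        diag[0] -= s
        diag[-1] -= s
        rhs = sums.copy()

    if m == 1:
        sol = rhs / diag[0]
    else:
        ab = np.zeros((2, m))
        ab[0, 1:] = -s
        ab[1] = diag
        sol = solveh_banded(ab, rhs)
    Wn = W.copy()
    if pin_endpoints:
        Wn[1:-1] = sol
    else:
        Wn[:] = sol
    return Wn


def _laplace_log_evidence(cost: float, counts: np.ndarray, s: float,
                          spring_min: float, D: int) -> float:
    """Laplace approximation of the log marginal likelihood at the fitted path.

    The cost is read as −log of (likelihood × spring prior): frames are
    Gaussian about their representative, and the elastic term s·Σ‖ΔW‖² is a
    Gaussian-process prior over the K−2 interior representatives (endpoints
    pinned).  The prior must enter *normalized* — its partition function
    scales as s^{−(K−2)D/2}, which is what penalizes vanishing s and gives
    the evidence an interior maximum.  Both Gaussian integrals are over
    block-tridiagonal forms, so only scalar (K−2)-size determinants appear:
    the posterior Hessian has diagonal 2(n_j + 2s) and off-diagonals −2s,
    the prior one is 2s·tridiag(−1, 2, −1) with determinant (2s)^{K−2}(K−1).

    ``spring_min`` is the minimum of the spring energy over interior
    representatives (attained at uniform spacing on the endpoint segment);
    it recenters the prior exponent.
    """
    K = counts.shape[0]
    m = K - 2
    if m <= 0:
        return -cost
    if s <= 0:
        return -np.inf
    diag = 2.0 * (counts[1:-1] + 2.0 * s)
    T = np.diag(diag) + np.diag(np.full(m - 1, -2.0 * s), 1) \
        + np.diag(np.full(m - 1, -2.0 * s), -1)
    sign, logdet_h = np.linalg.slogdet(T)
    if sign <= 0:
        return -np.inf
    # log det of the prior Hessian 2s·tridiag(−1,2,−1): det tridiag = m+1
    logdet_p = m * np.log(2.0 * s) + np.log(m + 1.0)
    return (-cost + s * spring_min
            - 0.5 * D * logdet_h + 0.5 * D * logdet_p)


def fit_principal_path(frames, endpoint_A, endpoint_B, K: int, s: float,
                       pin_endpoints: bool = True, tol: float = 1e-8,
                       max_iter: int = 500, W0=None) -> PrincipalPath:
    """Fit a principal path of K representatives between two endpoints.

    Conformational frames are aligned onto ``endpoint_A`` and flattened
    first.  Interior representatives start on the linear interpolation
    A → B (deterministic initialization) unless ``W0`` is given.  Iterates
    nearest-representative assignment and the exact interior update until
    the relative cost change drops below ``tol``.
    """
    if K < 3:
        raise ValueError("K must be at least 3")
    if s < 0:
        raise ValueError("s must be non-negative")
    conformational = np.asarray(_coords(endpoint_A)).ndim == 2 and \
        np.asarray(_coords(endpoint_A)).shape[1] == 3
    if conformational:
        a = _coords(endpoint_A)
        X = align_frames(list(frames) if not hasattr(frames, "coords")
                         else list(frames.coords), a)
        A = a.ravel()
        B = kabsch_superpose(_coords(endpoint_B), a)[0].ravel()
    else:
        X = _as_matrix(frames)
        A = np.asarray(endpoint_A, float).ravel()
        B = np.asarray(endpoint_B, float).ravel()
    if X.shape[0] < K:
        raise ValueError(f"need at least K = {K} frames, got {X.shape[0]}")

    if W0 is not None:
        W = _as_matrix(W0).copy()
    else:
        t = np.linspace(0.0, 1.0, K)[:, None]
        W = (1 - t) * A[None, :] + t * B[None, :]

    history = []
    c = np.zeros(X.shape[0], dtype=int)
    prev = None
    for _it in range(max_iter):
        d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
        c = np.argmin(d2, axis=1)
        W = _update_interior(X, W, c, s, pin_endpoints)
        cost = pp_cost(X, W, c, s)
        history.append(cost)
        if prev is not None and prev - cost <= tol * max(abs(prev), 1.0):
            break
        prev = cost

    counts = np.bincount(c, minlength=K).astype(float)
    if pin_endpoints:
        spring_min = float(np.sum((B - A) ** 2)) / (K - 1)
        log_ev = _laplace_log_evidence(history[-1], counts, s, spring_min,
                                       X.shape[1])
    else:
        log_ev = -history[-1]
    conf = W.reshape(K, -1, 3) if conformational else None
    return PrincipalPath(representatives=W, assignments=c, s=float(s),
                         log_evidence=float(log_ev),
                         cost_history=np.asarray(history),
                         conformations=conf)


def default_s_grid(frames, n: int = 10) -> np.ndarray:
    """Log-spaced s grid spanning [1e−3, 1e3] × mean squared frame step."""
    X = _as_matrix(frames)
    step = float(np.mean(np.sum(np.diff(X, axis=0) ** 2, axis=1)))
    if step <= 0:
        step = 1.0
    return step * np.logspace(-3, 3, n)


def select_s(frames, endpoint_A, endpoint_B, K: int, s_grid=None,
             **fit_kwargs):
    """Select the regularization weight by Bayesian-evidence maximization.

    Fits the path for every s in the grid (default: 10 log-spaced values
    scaled by the mean squared frame-to-frame displacement) and returns
    ``(s_star, table)`` where the table lists s, final cost and
    log-evidence per candidate.
    """
    if s_grid is None:
        s_grid = default_s_grid(frames)
    s_grid = np.asarray(s_grid, float)
    if s_grid.size == 1:
        warnings.warn("s_grid has a single value: no selection possible",
                      stacklevel=2)
    elif s_grid.size < 3:
        raise ValueError("s_grid needs at least 3 values (or exactly 1)")
    if np.any(s_grid <= 0):
        raise ValueError("s_grid values must be positive")

    rows = []
    best = (-np.inf, None)
    for s in s_grid:
        path = fit_principal_path(frames, endpoint_A, endpoint_B, K, s,
                                  **fit_kwargs)
        rows.append({"s": s, "cost": path.cost_history[-1],
                     "log_evidence": path.log_evidence})
        if path.log_evidence > best[0]:
            best = (path.log_evidence, s)
    if best[1] is None:
        raise ValueError("all fits degenerate: no finite evidence on the grid")
    return float(best[1]), pd.DataFrame(rows)


def nearest_frames(path: PrincipalPath, frames,
                   endpoint_A=None) -> np.ndarray:
    """Index of the closest frame to each representative (ties → earlier).

    Conformational frames are aligned onto ``endpoint_A`` (required in that
    case, and it must be the endpoint the path was fitted with) so distances
    live in the same metric space as the fit.
    """
    if hasattr(frames, "coords") and hasattr(frames, "times"):
        frames = frames.coords
    arr = np.asarray(frames, float) if not isinstance(frames, list) \
        else np.asarray([_coords(f) for f in frames])
    if arr.ndim == 3:
        if endpoint_A is None:
            raise ValueError("endpoint_A required to align conformational "
                             "frames")
        X = align_frames(list(arr), _coords(endpoint_A))
    else:
        X = arr
    W = path.representatives
    d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=0)  # first occurrence wins ties
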