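"""Penalized joint SMACOF: simultaneous embedding of two distance matrices.

The estimator minimizes the joint stress

    sigma(X1, X2) = sum_{i<j} (d_ij(X1) - delta_ij1)^2
                  + sum_{i<j} (d_ij(X2) - delta_ij2)^2
                  + sum_i w_i * d_i(X1, X2)^2

where delta_ijc = 0 marks a missing pair (excluded from the fit term for
that condition) and d_i(X1, X2) is the per-locus distance between the two
embeddings. The similarity weight w couples the embeddings so that they
land in the same local optimum and frame; w = 0 reduces to two independent
SMACOF runs.

Each iteration updates both configurations Jacobi-style from the
previous-iteration coordinates:

    X1 <- (W + I)^-1 [W X2 + B(X1) X1 / N]
    X2 <- (W + I)^-1 [W X1 + B(X2) X2 / N]

with the standard SMACOF majorizing matrix B. Because the Guttman term is
the N-normalized one, the quadratic surrogate these updates minimize
carries the similarity penalty at N times its nominal weight; see the
package methods note for the scaling discussion. In practice stress is
non-increasing across iterations and the w = 0 path is identical to
classic SMACOF.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .datatypes import JointMDSWarning

__all__ = [
    "JointMDS",
    "pair_stress",
    "guttman_transform",
    "penalized_update",
]


def _check_delta(delta: np.ndarray, name: str = "delta") -> np.ndarray:
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 2 or delta.shape[0] != delta.shape[1]:
        raise ValueError(f"{name} must be square, got shape {delta.shape}")
    if not np.allclose(delta, delta.T, atol=1e-9):
        raise ValueError(f"{name} must be symmetric")
    if np.any(delta < 0):
        raise ValueError(f"{name} must be non-negative")
    return delta


def _fit_stress(X: np.ndarray, delta: np.ndarray) -> float:
    emb = squareform(pdist(X))
    iu = np.triu_indices_from(delta, k=1)
    resid = emb[iu] - delta[iu]
    mask = delta[iu] > 0
    return float(np.sum(resid[mask] ** 2))


def pair_stress(
    x1: np.ndarray,
    x2: np.ndarray,
    delta1: np.ndarray,
    delta2: np.ndarray,
    weights: np.ndarray | float,
) -> float:
    """Joint stress of a configuration pair; missing pairs (delta = 0) excluded."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    delta1 = _check_delta(delta1, "delta1")
    delta2 = _check_delta(delta2, "delta2")
    n = delta1.shape[0]
    if x1.shape != x2.shape or x1.shape[0] != n or delta2.shape[0] != n:
        raise ValueError("coordinate and distance matrices must agree in size")
    w = np.broadcast_to(np.asarray(weights, dtype=float), (n,))
    if np.any(w < 0):
        raise ValueError("similarity weights must be non-negative")
    d = np.linalg.norm(x1 - x2, axis=1)
    # fsum is exactly rounded, so the result is invariant to the order of the
    # three terms and swapping (x1, delta1) with (x2, delta2) is bit-exact.
    return math.fsum(
        (_fit_stress(x1, delta1), _fit_stress(x2, delta2), float(np.sum(w * d * d)))
    )


def guttman_transform(z: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """One SMACOF majorization step, B(Z) Z / N.

    b_ij = -delta_ij / d_ij(Z) for i != j where delta_ij > 0 and d_ij(Z) > 0,
    0 otherwise (missing pairs exert no force); b_ii closes the rows to zero
    sum. Rows whose delta entries are all missing are pulled to the centroid
    and flagged.
    """
    z = np.asarray(z, dtype=float)
    delta = _check_delta(delta)
    n = delta.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points for a Guttman update")
    if z.shape[0] != n:
        raise ValueError("coordinate rows must match the distance matrix size")
    emb = squareform(pdist(z))
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.where((delta > 0) & (emb > 0), -delta / np.maximum(emb, 1e-300), 0.0)
    np.fill_diagonal(B, 0.0)
    dead = ~np.any(B < 0, axis=1) & np.all(delta <= 0, axis=1)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} loci have no usable target distances; "
            "they are pulled to the origin",
            JointMDSWarning,
        )
    np.fill_diagonal(B, -B.sum(axis=1))
    return B @ z / n


def penalized_update(
    x_other: np.ndarray,
    z: np.ndarray,
    delta: np.ndarray,
    weights: np.ndarray | float,
) -> np.ndarray:
    """Majorization update of one configuration given the other.

    Solves (W + I) X = W X_other + B(Z) Z / N, where W = diag(w). Each row is
    the blend (w_i * x_other_i + guttman_i) / (w_i + 1): w = 0 is plain
    SMACOF, w -> inf snaps onto the other configuration.
    """
    x_other = np.asarray(x_other, dtype=float)
    n = x_other.shape[0]
    w = np.broadcast_to(np.asarray(weights, dtype=float), (n,)).astype(float)
    if np.any(w < 0):
        raise ValueError("similarity weights must be non-negative")
    g = guttman_transform(z, delta)
    return (w[:, None] * x_other + g) / (w[:, None] + 1.0)


class JointMDS(BaseEstimator):
    """Joint multidimensional scaling of two precomputed distance matrices.

    Parameters
    ----------
    similarity_weight : float, default 0.05
        Per-locus coupling between the two embeddings. 0 gives two
        independent SMACOF embeddings; values around 0.02-0.1 suffice to
        make runs reproducible without degrading the fit.
    n_components : int, default 3
        Embedding dimensionality.
    n_init : int, default 4
        Random restarts; the restart with the lowest final stress wins.
    max_iter : int, default 300
        Majorization iterations per restart.
    tol : float, default 1e-4
        Relative stress-decrease threshold for convergence.
    random_state : int, RandomState or None
        Seeds the shared Gaussian initialization of each restart. Both
        configurations start from the *same* random configuration so the
        penalty never has to repair a spurious reflection or rotation
        between them.

    Attributes
    ----------
    embedding1_, embedding2_ : ndarray of shape (n, n_components)
        Mean-centered coordinates for condition 1 and 2.
    stress_ : float
        Final joint stress of the best restart.
    n_iter_ : int
        Iterations used by the best restart.
    converged_ : bool
        Whether the best restart met the tolerance before ``max_iter``.
    stress_trace_ : ndarray
        Stress after every iteration of the best restart (leading entry is
        the initial stress).

    Examples
    --------
    >>> import numpy as np
    >>> from scipy.spatial.distance import pdist, squareform
    >>> pts = np.random.default_rng(0).normal(size=(30, 3))
    >>> delta = squareform(pdist(pts))
    >>> fit = JointMDS(similarity_weight=0.05, random_state=0).fit(delta, delta)
    >>> float(np.linalg.norm(fit.embedding1_ - fit.embedding2_, axis=1).max()) < 1e-6
    True
    """

    def __init__(
        self,
        similarity_weight: float = 0.05,
        n_components: int = 3,
        n_init: int = 4,
        max_iter: int = 300,
        tol: float = 1e-4,
        random_state=None,
    ):
        self.similarity_weight = similarity_weight
        self.n_components = n_components
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _single(self, delta1, delta2, w, init, record_trace):
        n = delta1.shape[0]
        X1 = init.copy()
        X2 = init.copy()
        prev = pair_stress(X1, X2, delta1, delta2, w)
        trace = [prev]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # Jacobi: both updates read previous-iteration coordinates, so
            # swapping the inputs swaps the outputs exactly.
            X1_new = penalized_update(X2, X1, delta1, w)
            X2_new = penalized_update(X1, X2, delta2, w)
            X1, X2 = X1_new, X2_new
            cur = pair_stress(X1, X2, delta1, delta2, w)
            if record_trace:
                trace.append(cur)
            if prev - cur < self.tol * max(prev, 1e-300):
                converged = True
                break
            prev = cur
        cur = pair_stress(X1, X2, delta1, delta2, w)
        return X1, X2, cur, it, converged, np.asarray(trace)

    def fit(self, delta1, delta2, init: np.ndarray | None = None):
        """Fit both embeddings.

        Parameters
        ----------
        delta1, delta2 : ndarray of shape (n, n)
            Symmetric target-distance matrices over the same loci; zero
            entries are missing pairs.
        init : ndarray of shape (n, n_components), optional
            Explicit shared initialization; disables the random restarts
            (``n_init`` is ignored).
        """
        delta1 = _check_delta(delta1, "delta1")
        delta2 = _check_delta(delta2, "delta2")
        if delta1.shape != delta2.shape:
            raise ValueError("delta1 and delta2 must have the same shape")
        n = delta1.shape[0]
        if n < 2:
            raise ValueError("need at least 2 loci to embed")
        if self.similarity_weight < 0:
            raise ValueError("similarity_weight must be non-negative")
        w = float(self.similarity_weight)
        rng = check_random_state(self.random_state)

        # Symmetric in (delta1, delta2) so that swapping the inputs swaps the
        # outputs exactly (two-float addition is commutative).
        nz1 = delta1[delta1 > 0]
        nz2 = delta2[delta2 > 0]
        m1 = float(nz1.mean()) if nz1.size else 1.0
        m2 = float(nz2.mean()) if nz2.size else 1.0
        scale = 0.5 * (m1 + m2)

        if init is not None:
            inits = [np.asarray(init, dtype=float)]
            if inits[0].shape != (n, self.n_components):
                raise ValueError(
                    f"init must have shape ({n}, {self.n_components})"
                )
        else:
            inits = [
                rng.normal(scale=scale, size=(n, self.n_components))
                for _ in range(self.n_init)
            ]

        best = None
        for start in inits:
            result = self._single(delta1, delta2, w, start, record_trace=True)
            if best is None or result[2] < best[2]:
                best = result
        X1, X2, stress, n_iter, converged, trace = best
        if not converged:
            warnings.warn(
                "no restart converged within max_iter; returning the best fit",
                JointMDSWarning,
            )
        self.embedding1_ = X1 - X1.mean(axis=0)
        self.embedding2_ = X2 - X2.mean(axis=0)
        # Per-structure centering can shift the penalty term marginally, so
        # report the stress of the coordinates actually returned.
        self.stress_ = pair_stress(
            self.embedding1_, self.embedding2_, delta1, delta2, w
        )
        self.n_iter_ = int(n_iter)
        self.converged_ = bool(converged)
        self.stress_trace_ = trace
        return self

    def fit_transform(self, delta1, delta2, init: np.ndarray | None = None):
        """Fit and return the two embeddings stacked as (2, n, n_components)."""
        self.fit(delta1, delta2, init=init)
        return np.stack([self.embedding1_, self.embedding2_])
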