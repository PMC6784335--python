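"""High-level joint-embedding operations on :class:`DistMatrix` pairs.

Thin wrappers over :class:`jointmds.estimator.JointMDS` that speak the
package's genomic containers and add the weight-selection heuristic.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import AlignedPair, DistMatrix, JointFit, Structure
from .estimator import JointMDS

__all__ = [
    "joint_mds",
    "select_similarity_weight",
    "embedding_error",
]


def _check_pair(d1: DistMatrix, d2: DistMatrix) -> None:
    if not d1.same_loci(d2):
        raise ValueError("the two distance matrices must share an identical locus list")


def joint_mds(
    d1: DistMatrix,
    d2: DistMatrix,
    weight: float = 0.05,
    n_init: int = 4,
    max_iter: int = 300,
    tol: float = 1e-4,
    seed: int = 0,
) -> JointFit:
    """Simultaneously embed and align two target-distance matrices in 3D.

    Deterministic given ``seed``. Returns the best of ``n_init`` restarts;
    both structures are mean-centered and live in a common frame (the
    similarity penalty anchors them to each other, so no post-hoc
    superposition is needed).
    """
    _check_pair(d1, d2)
    est = JointMDS(
        similarity_weight=weight,
        n_components=3,
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(d1.delta, d2.delta)
    x1 = Structure(d1.chrom, d1.bin_size, d1.bins.copy(), est.embedding1_)
    x2 = Structure(d2.chrom, d2.bin_size, d2.bins.copy(), est.embedding2_)
    return JointFit(
        pair=AlignedPair(x1, x2, weight=weight),
        final_stress=est.stress_,
        n_iterations=est.n_iter_,
        converged=est.converged_,
        seed=seed,
        stress_trace=est.stress_trace_,
    )


def select_similarity_weight(
    d1: DistMatrix,
    d2: DistMatrix,
    candidate_weights: list[float],
    n_runs: int = 5,
    seed: int = 0,
    plateau_tol: float = 0.01,
    **mds_kwargs,
) -> tuple[float, dict[float, float]]:
    """Pick the smallest weight whose run-to-run reproducibility has plateaued.

    For each candidate weight the joint embedding is repeated ``n_runs``
    times with distinct seeds; reproducibility is the mean pairwise Pearson
    correlation of the per-locus relocalization-magnitude profiles across
    runs. The chosen weight is the smallest one within ``plateau_tol`` of
    the maximum observed reproducibility.

    Returns ``(chosen_weight, curve)`` where ``curve`` maps each candidate
    to its reproducibility.
    """
    if not candidate_weights:
        raise ValueError("candidate_weights must be non-empty")
    if n_runs < 2 and len(candidate_weights) > 1:
        raise ValueError("n_runs must be at least 2")
    _check_pair(d1, d2)
    if len(candidate_weights) == 1:
        w = float(candidate_weights[0])
        return w, {w: _reproducibility(d1, d2, w, max(n_runs, 2), seed, mds_kwargs)}

    curve: dict[float, float] = {}
    for w in candidate_weights:
        curve[float(w)] = _reproducibility(d1, d2, float(w), n_runs, seed, mds_kwargs)
    best = max(curve.values())
    chosen = min(w for w, r in curve.items() if r >= best - plateau_tol)
    return chosen, curve


def _reproducibility(d1, d2, weight, n_runs, seed, mds_kwargs) -> float:
    profiles = []
    for r in range(n_runs):
        fit = joint_mds(d1, d2, weight=weight, seed=seed + 1000 * r, **mds_kwargs)
        disp = fit.pair.x2.coords - fit.pair.x1.coords
        profiles.append(np.linalg.norm(disp, axis=1))
    cors = [
        _safe_corr(a, b) for a, b in itertools.combinations(profiles, 2)
    ]
    return float(np.mean(cors))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        # Degenerate (e.g. identical inputs: all magnitudes ~0); profiles
        # carry no signal to disagree about.
        return 1.0
    return float(np.corrcoef(a, b)[0, 1])


def embedding_error(x: Structure, d: DistMatrix) -> float:
    """RMSD between the target distances and the embedded distances.

    Root mean square of ``d_ij(X) - delta_ij`` over pairs with a nonmissing
    target (delta > 0); measures how faithfully the structure reproduces the
    input contact-derived distances.
    """
    if x.chrom != d.chrom or x.bin_size != d.bin_size or not np.array_equal(x.bins, d.bins):
        raise ValueError("structure and distance matrix must share loci")
    emb = squareform(pdist(x.coords))
    iu = np.triu_indices(d.n_loci, k=1)
    mask = d.delta[iu] > 0
    if not mask.any():
        raise ValueError("no nonmissing pairs to evaluate")
    resid = emb[iu][mask] - d.delta[iu][mask]
    return float(np.sqrt(np.mean(resid**2)))
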