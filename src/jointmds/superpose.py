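"""Rigid-body superposition (Kabsch) and the independent-inference baseline.

The baseline mode embeds each dataset separately (similarity weight zero,
independent initializations) and then superposes the second structure onto
the first with the optimal proper rotation. It exists both as the
comparison mode and as the reference point against which the joint
algorithm's reproducibility gain is measured.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .datatypes import AlignedPair, DistMatrix, RigidTransform, Structure
from .estimator import JointMDS

__all__ = ["kabsch", "rmsd", "independent_compare"]


def rmsd(a: Structure, b: Structure) -> float:
    """Root mean square per-locus coordinate distance between two structures."""
    if not np.array_equal(a.bins, b.bins) or a.chrom != b.chrom:
        raise ValueError("structures must share an identical locus set")
    diff = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def kabsch(moving: Structure, target: Structure) -> tuple[RigidTransform, Structure]:
    """Optimal proper rotation + translation of ``moving`` onto ``target``.

    Minimizes RMSD over rigid motions; reflections are disallowed, so a
    chirality mismatch stays visible as residual RMSD. Requires at least 3
    non-collinear points.
    """
    if not np.array_equal(moving.bins, target.bins) or moving.chrom != target.chrom:
        raise ValueError("structures must share an identical locus set")
    P = moving.coords
    Q = target.coords
    if P.shape[0] < 3:
        raise ValueError("Kabsch superposition needs at least 3 points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-9) < 2 or np.linalg.matrix_rank(Qc, tol=1e-9) < 2:
        raise ValueError("degenerate input: points are collinear (rank < 2)")
    rot, _ = Rotation.align_vectors(Qc, Pc)
    R = rot.as_matrix()
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    transform = RigidTransform(R, t)
    aligned = Structure(
        moving.chrom, moving.bin_size, moving.bins.copy(), transform.apply(P)
    )
    return transform, aligned


def independent_compare(
    d1: DistMatrix,
    d2: DistMatrix,
    seed: int = 0,
    n_init: int = 4,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> AlignedPair:
    """Independent MDS on each dataset followed by Kabsch superposition.

    Each dataset is embedded on its own (weight 0, its own random
    initializations), so run-to-run the two embeddings can fall into
    different local optima and mirror images; Kabsch repairs orientation
    but not optimum choice, which is exactly the stochasticity the joint
    algorithm removes.
    """
    if not d1.same_loci(d2):
        raise ValueError("the two distance matrices must share an identical locus list")

    def embed(d: DistMatrix, sub_seed: int) -> np.ndarray:
        est = JointMDS(
            similarity_weight=0.0,
            n_components=3,
            n_init=n_init,
            max_iter=max_iter,
            tol=tol,
            random_state=sub_seed,
        ).fit(d.delta, d.delta)
        return est.embedding1_

    x1 = Structure(d1.chrom, d1.bin_size, d1.bins.copy(), embed(d1, seed))
    x2 = Structure(d2.chrom, d2.bin_size, d2.bins.copy(), embed(d2, seed + 500_009))
    _, x2_aligned = kabsch(x2, x1)
    return AlignedPair(x1, x2_aligned, weight=0.0)
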