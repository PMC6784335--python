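"""Turn a pair of contact matrices into comparable target-distance matrices.

The fixed pipeline is::

    intersect_loci -> mean_normalize_pair -> distance_decay_prior (each)
        -> contacts_to_distances (each)

Intersecting first keeps the distance-decay expected values from being
diluted by dead bins; normalizing before the prior makes the prior weight
comparable across datasets. :func:`prepare_pair` runs the whole chain.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import DistMatrix, JointMDSWarning, SparseContacts

__all__ = [
    "mean_normalize_pair",
    "intersect_loci",
    "distance_decay_prior",
    "contacts_to_distances",
    "expected_by_separation",
    "prepare_pair",
]

DEFAULT_PRIOR_WEIGHT = 0.05
DEFAULT_DISTANCE_EXPONENT = -0.25


def mean_normalize_pair(
    a: SparseContacts, b: SparseContacts
) -> tuple[SparseContacts, SparseContacts]:
    """Divide each matrix by the mean of its stored nonzero contacts.

    Puts the two datasets on approximately the same scale; within each matrix
    the relative ratios are untouched. After this the nonzero entries of each
    output have mean exactly 1.
    """
    out = []
    for m in (a, b):
        vals = m.nonzero_values()
        if vals.size == 0:
            raise ValueError("no informative contacts: matrix has no nonzero entries")
        scaled = m.copy()
        scaled.matrix = m.matrix / vals.mean()
        scaled.normalized = True
        out.append(scaled)
    return out[0], out[1]


def intersect_loci(
    a: SparseContacts, b: SparseContacts
) -> tuple[SparseContacts, SparseContacts]:
    """Drop loci with zero total counts in *both* datasets; keep all others in both.

    A locus observed in only one dataset is retained in both (with zero
    contacts in the other), so the two outputs always share an identical
    locus list.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"chromosome mismatch: {a.chrom!r} vs {b.chrom!r}")
    if a.bin_size != b.bin_size:
        raise ValueError(f"resolution mismatch: {a.bin_size} vs {b.bin_size}")

    union = np.union1d(a.bins, b.bins)

    def lifted(m: SparseContacts) -> np.ndarray:
        full = np.zeros((union.size, union.size))
        idx = np.searchsorted(union, m.bins)
        full[np.ix_(idx, idx)] = m.matrix
        return full

    ma, mb = lifted(a), lifted(b)
    alive = (ma.sum(axis=1) > 0) | (mb.sum(axis=1) > 0)
    if not alive.any():
        raise ValueError("no shared nonzero loci between the two datasets")
    keep = np.where(alive)[0]
    bins = union[keep]
    return (
        SparseContacts(a.chrom, a.bin_size, bins, ma[np.ix_(keep, keep)], a.normalized),
        SparseContacts(b.chrom, b.bin_size, bins, mb[np.ix_(keep, keep)], b.normalized),
    )


def _separation_matrix(m: SparseContacts) -> np.ndarray:
    return np.abs(m.bins[:, None] - m.bins[None, :])


def expected_by_separation(m: SparseContacts) -> np.ndarray:
    """Mean contact frequency per linear bin separation (zeros included in the mean).

    Returns an array indexed by separation s = |i - j| in bins; separations
    with no retained pair get 0.
    """
    sep = _separation_matrix(m)
    iu = np.triu_indices(m.n_loci, k=1)
    s = sep[iu]
    v = m.matrix[iu]
    max_sep = int(s.max()) if s.size else 0
    sums = np.bincount(s, weights=v, minlength=max_sep + 1)
    counts = np.bincount(s, minlength=max_sep + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return exp


def distance_decay_prior(m: SparseContacts, k: float = DEFAULT_PRIOR_WEIGHT) -> SparseContacts:
    """Shrink every within-span pair toward the mean contact at its separation.

    ``c_corrected = c_observed * (1 - k) + c_expected * k`` where c_expected
    is the average contact frequency over all retained pairs at the same
    linear separation. Observed-zero pairs are included (they can become
    nonzero), which is what regularizes sparse regions. ``k = 0`` is the
    identity.
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"prior weight k must be in [0, 1], got {k}")
    out = m.copy()
    if k == 0.0 or m.n_loci < 2:
        return out
    exp = expected_by_separation(m)
    sep = _separation_matrix(m)
    corrected = m.matrix * (1.0 - k) + exp[sep] * k
    np.fill_diagonal(corrected, 0.0)
    out.matrix = corrected
    return out


def contacts_to_distances(
    m: SparseContacts, exponent: float = DEFAULT_DISTANCE_EXPONENT
) -> DistMatrix:
    """Convert contact frequencies to target distances, d = c**exponent.

    The default exponent -1/4 reflects the empirical contact-distance scaling
    c ~ d^-4. Zero contacts become zero distances, which downstream MDS
    treats as missing.
    """
    if exponent >= 0:
        warnings.warn(
            "non-negative distance exponent: distances no longer decrease "
            "with contact frequency",
            JointMDSWarning,
        )
    with np.errstate(divide="ignore"):
        delta = np.where(m.matrix > 0, m.matrix ** exponent, 0.0)
    np.fill_diagonal(delta, 0.0)
    return DistMatrix(m.chrom, m.bin_size, m.bins.copy(), delta)


def prepare_pair(
    a: SparseContacts,
    b: SparseContacts,
    prior_weight: float = DEFAULT_PRIOR_WEIGHT,
    exponent: float = DEFAULT_DISTANCE_EXPONENT,
) -> tuple[DistMatrix, DistMatrix]:
    """Full preprocessing chain for a comparison pair; outputs share loci."""
    a, b = intersect_loci(a, b)
    a, b = mean_normalize_pair(a, b)
    a = distance_decay_prior(a, prior_weight)
    b = distance_decay_prior(b, prior_weight)
    return contacts_to_distances(a, exponent), contacts_to_distances(b, exponent)
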