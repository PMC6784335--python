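"""A/B compartment scores, the 3D compartment axis, and relocalization decomposition.

Compartment scores are the classic Hi-C eigenvector: PC1 of the Pearson
correlation matrix of the observed/expected contact matrix, rescaled to
[-1, 1]. The compartment axis of an embedded structure is the single 3D
direction that best predicts those scores (linear support vector
regression); per-locus relocalization can then be split into the component
along that axis versus the two orthogonal directions, with each fraction
normalized by its axis length so physically longer axes are not favoured.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.linalg import null_space
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.svm import LinearSVR

from .datatypes import (
    AlignedPair,
    AxisDecomposition,
    AxisFit,
    CompartmentTrack,
    JointMDSWarning,
    SparseContacts,
    Structure,
)
from .preprocess import expected_by_separation

__all__ = [
    "compartment_scores",
    "orient_scores",
    "fit_compartment_axis",
    "decompose_relocalization",
    "compartment_difference",
]


def compartment_scores(m: SparseContacts) -> CompartmentTrack:
    """Per-locus compartment score: PC1 of the observed/expected correlation matrix.

    The expected value at each linear separation is the mean contact over
    retained pairs at that separation (zeros included). Loci whose
    observed/expected row has zero variance carry no correlation signal and
    are dropped with a warning. Scores are scaled so max \\|score\\| = 1;
    ``pc1_variance_fraction`` reports the share of correlation-matrix
    variance the leading eigenvector explains.
    """
    if m.n_loci < 3:
        raise ValueError("compartment scores need at least 3 retained loci")
    exp = expected_by_separation(m)
    sep = np.abs(m.bins[:, None] - m.bins[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp[sep] > 0, m.matrix / np.where(exp[sep] > 0, exp[sep], 1.0), 0.0)
    np.fill_diagonal(oe, 0.0)

    keep = oe.std(axis=1) > 0
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(
            f"{n_drop} loci with zero-variance observed/expected rows were dropped",
            JointMDSWarning,
        )
    if keep.sum() < 3:
        warnings.warn(
            "matrix is essentially constant; returning a zero compartment track",
            JointMDSWarning,
        )
        return CompartmentTrack(m.chrom, m.bin_size, m.bins.copy(),
                                np.zeros(m.n_loci), 0.0)

    corr = np.corrcoef(oe[keep][:, keep])
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    pc1 = evecs[:, order[0]]
    # Deterministic sign: make the largest-magnitude loading positive.
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    score = pc1 / np.max(np.abs(pc1))
    frac = float(evals[0] / np.sum(np.clip(evals, 0.0, None)))
    return CompartmentTrack(m.chrom, m.bin_size, m.bins[keep].copy(), score, frac)


def orient_scores(track: CompartmentTrack, active_mask: np.ndarray) -> CompartmentTrack:
    """Flip the score sign, if needed, so the positive compartment is the active one.

    ``active_mask`` marks loci belonging to active chromatin (e.g. from an
    epigenomic annotation or gene density). The sign is flipped when the
    negative compartment has the greater fraction of active loci; ties and
    empty masks leave the track unchanged with a warning. Idempotent.
    """
    active_mask = np.asarray(active_mask, dtype=bool)
    if active_mask.shape != (track.n_loci,):
        raise ValueError("active_mask must cover the track's loci")
    out = track.copy()
    if not active_mask.any():
        warnings.warn("empty active mask; track left unchanged", JointMDSWarning)
        return out
    pos = track.score > 0
    neg = track.score < 0
    frac_pos = active_mask[pos].mean() if pos.any() else 0.0
    frac_neg = active_mask[neg].mean() if neg.any() else 0.0
    if frac_pos == frac_neg:
        warnings.warn(
            "active fraction tied between compartments; track left unchanged",
            JointMDSWarning,
        )
        return out
    if frac_neg > frac_pos:
        out.score = -out.score
    return out


def fit_compartment_axis(
    x: Structure, track: CompartmentTrack, method: str = "svr"
) -> AxisFit:
    """Fit the 3D axis that best explains the compartment scores.

    Linear epsilon-insensitive SVR (C = 1, epsilon = 0) of score on the 3D
    coordinates; ``method="ols"`` substitutes ordinary least squares, which
    must agree in direction on clean data and is useful as a cross-check.
    ``axis_length`` is the mean distance of the coordinates from their
    centroid along the fitted direction.
    """
    if not np.array_equal(x.bins, track.bins) or x.chrom != track.chrom:
        raise ValueError("structure and compartment track must share loci")
    if x.n_loci < 4:
        raise ValueError("axis fitting needs at least 4 loci")
    coords = x.coords
    if method == "svr":
        model = LinearSVR(C=1.0, epsilon=0.0, random_state=0, max_iter=100_000)
    elif method == "ols":
        model = LinearRegression()
    else:
        raise ValueError(f"unknown method {method!r}")
    model.fit(coords, track.score)
    beta = np.ravel(model.coef_)
    norm = np.linalg.norm(beta)
    if norm < 1e-12:
        raise ValueError("no compartment axis: fitted coefficients are zero")
    direction = beta / norm
    r2 = float(r2_score(track.score, model.predict(coords)))
    centered = coords - coords.mean(axis=0)
    axis_length = float(np.mean(np.abs(centered @ direction)))
    return AxisFit(direction, r2, axis_length)


def _orthonormal_complement(a: np.ndarray) -> np.ndarray:
    basis = null_space(a[None, :])  # (3, 2), orthonormal
    return basis.T


def decompose_relocalization(
    pair: AlignedPair, axis1: AxisFit, axis2: AxisFit
) -> AxisDecomposition:
    """Split per-locus relocalization along the compartment axis vs the orthogonal plane.

    The compartment axis is the normalized mean of the two per-structure
    axis directions (sign-aligned first); the orthogonal axes complete an
    orthonormal triad. Each locus's fraction of relocalization along an
    axis is divided by that axis's length (computed from the pooled pair
    coordinates) to remove the bias toward physically longer axes. The
    reported t test compares the compartment-axis normalized fractions
    against the pooled orthogonal-axis fractions (two-sided,
    equal-variance, independent samples); zero-magnitude loci are excluded.
    """
    d2 = axis2.direction.copy()
    if np.dot(axis1.direction, d2) < 0:
        d2 = -d2
    cosang = float(np.clip(np.dot(axis1.direction, d2), -1.0, 1.0))
    if np.degrees(np.arccos(cosang)) > 60.0:
        warnings.warn(
            "compartment axis unstable: per-structure axes disagree by more "
            "than 60 degrees after sign alignment",
            JointMDSWarning,
        )
    mean_dir = axis1.direction + d2
    norm = np.linalg.norm(mean_dir)
    if norm < 1e-12:
        raise ValueError("per-structure axes are antiparallel; no mean axis")
    comp_axis = mean_dir / norm
    axes = np.vstack([comp_axis, _orthonormal_complement(comp_axis)])

    pooled = np.vstack([pair.x1.coords, pair.x2.coords])
    pooled = pooled - pooled.mean(axis=0)
    axis_lengths = np.mean(np.abs(pooled @ axes.T), axis=0)

    disp = pair.x2.coords - pair.x1.coords
    mag = np.linalg.norm(disp, axis=1)
    components = disp @ axes.T
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(mag[:, None] > 0, np.abs(components) / mag[:, None], np.nan)
    normalized = fractions / axis_lengths[None, :]

    ok = mag > 0
    comp_frac = normalized[ok, 0]
    orth_frac = normalized[ok, 1:].ravel()
    if comp_frac.size >= 2 and orth_frac.size >= 2:
        t_stat, p_val = stats.ttest_ind(comp_frac, orth_frac, equal_var=True)
    else:
        t_stat, p_val = np.nan, np.nan
    return AxisDecomposition(
        bins=pair.x1.bins.copy(),
        axes=axes,
        axis_lengths=axis_lengths,
        components=components,
        fractions=fractions,
        normalized_fractions=normalized,
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )


def compartment_difference(
    track_a: CompartmentTrack, track_b: CompartmentTrack
) -> np.ndarray:
    """Per-locus absolute compartment-score difference between two oriented tracks."""
    if not np.array_equal(track_a.bins, track_b.bins) or track_a.chrom != track_b.chrom:
        raise ValueError("tracks must share an identical locus list")
    if track_a.n_loci >= 2:
        sa, sb = track_a.score, track_b.score
        if np.std(sa) > 0 and np.std(sb) > 0:
            r = float(np.corrcoef(sa, sb)[0, 1])
            if r < -0.3:
                warnings.warn(
                    f"tracks are negatively correlated (r = {r:.2f}); "
                    "did you forget orient_scores?",
                    JointMDSWarning,
                )
    return np.abs(track_a.score - track_b.score)
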