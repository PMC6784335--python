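"""Relocalization profiles, wavelet peak calling, peak filtering and virtual 4C.

A relocalization profile is the per-locus 3D displacement between two
aligned structures. Peaks in its magnitude are called with continuous
wavelet transform (Ricker) ridge lines over a range of candidate widths,
which finds peak-shaped features in noisy profiles without smoothing.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.signal import find_peaks_cwt

from .datatypes import (
    AlignedPair,
    CompartmentTrack,
    JointMDSWarning,
    Peak,
    RelocProfile,
    SparseContacts,
)

__all__ = [
    "relocalization_profile",
    "call_peaks",
    "filter_peaks_by_compartment",
    "split_peaks_by_compartment",
    "virtual_4c",
    "coverage_enrichment",
    "apply_blacklist",
]

DEFAULT_WIDTHS = tuple(range(1, 11))
DEFAULT_COMPARTMENT_DIFF_THRESHOLD = 0.2


def relocalization_profile(pair: AlignedPair) -> RelocProfile:
    """Per-locus displacement (structure 2 minus structure 1) and its magnitude.

    Loci absent in either structure are absent from the profile.
    """
    both = pair.x1.present & pair.x2.present
    disp = pair.x2.coords[both] - pair.x1.coords[both]
    return RelocProfile(
        pair.x1.chrom,
        pair.x1.bin_size,
        pair.x1.bins[both].copy(),
        disp,
        np.linalg.norm(disp, axis=1),
    )


def _ricker(points: int, a: float) -> np.ndarray:
    x = np.arange(points) - (points - 1) / 2.0
    amp = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25)
    return amp * (1.0 - (x / a) ** 2) * np.exp(-(x**2) / (2.0 * a**2))


def _width_class(signal: np.ndarray, index: int, widths) -> int:
    """Width whose Ricker response at the peak position is strongest."""
    best_w, best_r = widths[0], -np.inf
    for w in widths:
        kernel = _ricker(min(10 * int(w), signal.size), float(w))
        resp = np.convolve(signal, kernel, mode="same")[index]
        if resp > best_r:
            best_w, best_r = int(w), float(resp)
    return best_w


def call_peaks(profile: RelocProfile, widths=DEFAULT_WIDTHS, **cwt_kwargs) -> RelocProfile:
    """Call peaks in the relocalization magnitude with CWT ridge-line detection.

    Candidate peak widths default to 1..10 bins; ridge and SNR parameters
    are the standard algorithm defaults unless overridden through
    ``cwt_kwargs``. Returns a copy of the profile with ``peaks`` populated
    (position = locus index, plus the best-responding width class),
    ordered by position.
    """
    widths = np.asarray(sorted(int(w) for w in widths))
    if widths.size == 0 or widths[0] < 1:
        raise ValueError("widths must be positive integers")
    n = profile.n_loci
    if n < widths.max():
        widths = widths[widths <= max(n, 1)]
        warnings.warn(
            f"profile has only {n} loci; widths truncated to <= {n}",
            JointMDSWarning,
        )
    if np.ptp(profile.magnitude) == 0:
        indices = np.empty(0, dtype=int)  # constant signal: nothing to call
    else:
        indices = find_peaks_cwt(profile.magnitude, widths, **cwt_kwargs)
    indices = sorted(int(i) for i in np.atleast_1d(indices))
    peaks = [Peak(i, _width_class(profile.magnitude, i, widths)) for i in indices]
    return RelocProfile(
        profile.chrom,
        profile.bin_size,
        profile.bins.copy(),
        profile.displacement.copy(),
        profile.magnitude.copy(),
        peaks,
    )


def filter_peaks_by_compartment(
    profile: RelocProfile,
    diff: np.ndarray,
    threshold: float = DEFAULT_COMPARTMENT_DIFF_THRESHOLD,
) -> list[Peak]:
    """Keep peaks whose locus has absolute compartment-score difference < threshold.

    Strict inequality: a peak at exactly the threshold is dropped. These
    are the peaks where loci relocate *within* a compartment rather than
    switching compartments. Peaks with a missing (NaN) difference are
    dropped with a warning.
    """
    diff = np.asarray(diff, dtype=float)
    if diff.shape != (profile.n_loci,):
        raise ValueError("diff must provide one value per profile locus")
    kept = []
    n_missing = 0
    for p in profile.peaks:
        d = diff[p.index]
        if np.isnan(d):
            n_missing += 1
            continue
        if d < threshold:
            kept.append(p)
    if n_missing:
        warnings.warn(
            f"{n_missing} peaks dropped: missing compartment difference",
            JointMDSWarning,
        )
    return kept


def split_peaks_by_compartment(
    peaks: list[Peak],
    track_a: CompartmentTrack,
    track_b: CompartmentTrack,
) -> tuple[list[Peak], list[Peak], list[Peak]]:
    """Partition peaks into intra-A, intra-B and compartment-discordant sets.

    Intra-A: positive score in both (oriented) tracks; intra-B: negative in
    both; anything else (including exact zeros) is discordant.
    """
    if not np.array_equal(track_a.bins, track_b.bins):
        raise ValueError("tracks must share an identical locus list")
    intra_a, intra_b, discordant = [], [], []
    for p in peaks:
        sa, sb = track_a.score[p.index], track_b.score[p.index]
        if sa > 0 and sb > 0:
            intra_a.append(p)
        elif sa < 0 and sb < 0:
            intra_b.append(p)
        else:
            discordant.append(p)
    return intra_a, intra_b, discordant


def virtual_4c(m: SparseContacts, viewpoint: tuple[int, int]) -> np.ndarray:
    """Mean contact profile of a viewpoint interval against every other locus.

    ``viewpoint`` is a genomic interval (bp, half-open). Returns one value
    per locus of ``m``; the viewpoint bins themselves are NaN (missing).
    """
    start, end = viewpoint
    bin_starts = m.bins * m.bin_size
    in_view = (bin_starts < end) & (bin_starts + m.bin_size > start)
    if not in_view.any():
        raise ValueError(
            f"viewpoint {start}-{end} overlaps no bin of the matrix span"
        )
    profile = m.matrix[in_view].mean(axis=0)
    profile = profile.astype(float)
    profile[in_view] = np.nan
    return profile


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _normalize_intervals(intervals) -> dict[str | None, list[tuple[int, int]]]:
    by_chrom: dict[str | None, list[tuple[int, int]]] = {}
    for iv in intervals:
        if len(iv) == 3:
            c, s, e = iv
        elif len(iv) == 2:
            c, (s, e) = None, iv
        else:
            raise ValueError("intervals must be (start, end) or (chrom, start, end)")
        if e <= s:
            raise ValueError(f"empty or inverted interval {iv}")
        by_chrom.setdefault(c, []).append((int(s), int(e)))
    return by_chrom


def _coverage(intervals, features) -> np.ndarray:
    by_chrom = _normalize_intervals(features)
    merged = {c: _merge(ivs) for c, ivs in by_chrom.items()}
    out = []
    for iv in intervals:
        c, s, e = (iv if len(iv) == 3 else (None, *iv))
        covered = 0
        for fs, fe in merged.get(c, []):
            covered += max(0, min(e, fe) - max(s, fs))
        out.append(covered / (e - s))
    return np.asarray(out, dtype=float)


def apply_blacklist(intervals, blacklist) -> list:
    """Drop intervals that overlap any blacklist interval (half-open semantics)."""
    cov = _coverage(intervals, blacklist) if blacklist else np.zeros(len(intervals))
    return [iv for iv, c in zip(intervals, cov) if c == 0]


def coverage_enrichment(peaks, background, features) -> tuple[float, float]:
    """Feature-coverage enrichment of peak intervals over background intervals.

    Coverage of an interval is the fraction of its bases covered by the
    (merged) feature set; the enrichment ratio is mean peak coverage over
    mean background coverage (infinite when the background coverage is
    zero), and the p value is from a two-sided equal-variance t test on the
    two per-interval coverage samples.
    """
    if not peaks or not background:
        raise ValueError("peaks and background must both be non-empty")
    cov_p = _coverage(peaks, features)
    cov_b = _coverage(background, features)
    mb = cov_b.mean()
    ratio = float(cov_p.mean() / mb) if mb > 0 else float("inf")
    t, p = stats.ttest_ind(cov_p, cov_b, equal_var=True)
    return ratio, float(p)
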