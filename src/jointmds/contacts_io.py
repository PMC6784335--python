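"""Readers and writers for sparse Hi-C contact text dumps and structure/track TSVs.

Two contact dialects are supported:

* ``pairs`` — per-record genomic coordinates:
  ``chrom1 start1 chrom2 start2 count`` (5 columns) or the same with end
  columns, which are tolerated and ignored (7 columns).
* ``bins`` — per-record bin indices: ``bin_i bin_j count``; the bin size must
  then be given explicitly.

Files ending in ``.gz`` are decompressed transparently. Coordinates are
0-based, half-open throughout.
"""

from __future__ import annotations

import gzip
import io
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    CompartmentTrack,
    JointMDSWarning,
    RelocProfile,
    SparseContacts,
    Structure,
)

__all__ = [
    "read_contacts",
    "read_structure",
    "write_structure",
    "write_track",
    "write_profile",
    "write_peaks",
]


class ContactParseError(ValueError):
    """A malformed record in a contact file; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _parse_pairs_line(fields: list[str], lineno: int) -> tuple[str, int, str, int, float]:
    if len(fields) == 5:
        c1, s1, c2, s2, v = fields
    elif len(fields) == 7:
        c1, s1, _, c2, s2, _, v = fields
    else:
        raise ContactParseError(
            lineno, f"expected 5 or 7 whitespace-separated fields, got {len(fields)}"
        )
    try:
        return c1, int(s1), c2, int(s2), float(v)
    except ValueError as exc:
        raise ContactParseError(lineno, str(exc)) from None


def read_contacts(
    path,
    resolution: int | None = None,
    dialect: str = "pairs",
    region: tuple[int, int] | None = None,
) -> SparseContacts:
    """Read a sparse intrachromosomal contact matrix from a text dump.

    Parameters
    ----------
    path : str or Path
        Whitespace/tab-separated contact records; ``.gz`` accepted.
    resolution : int
        Bin size in bp; record coordinates must be multiples of it.
    dialect : {"pairs", "bins"}
    region : (start, end), optional
        Explicit genomic span (bp, half-open) overriding the observed
        min..max bin span.

    Returns
    -------
    SparseContacts
        Covers every bin of the span; absent pairs are zero. Duplicate
        records are summed with a warning; negative values are clamped to
        zero with a warning.
    """
    if dialect not in ("pairs", "bins"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "bins" and resolution is None:
        raise ValueError("the 'bins' dialect requires an explicit resolution")

    records: dict[tuple[int, int], float] = {}
    chrom: str | None = None
    n_dup = 0
    n_neg = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if dialect == "pairs":
                c1, s1, c2, s2, v = _parse_pairs_line(fields, lineno)
                if c1 != c2:
                    raise ContactParseError(
                        lineno,
                        f"mixed chromosomes {c1!r}/{c2!r} in intrachromosomal mode",
                    )
                if chrom is None:
                    chrom = c1
                elif c1 != chrom:
                    raise ContactParseError(
                        lineno, f"chromosome {c1!r} differs from {chrom!r}"
                    )
                if resolution is None:
                    raise ValueError("resolution is required for the 'pairs' dialect")
                if s1 % resolution or s2 % resolution:
                    raise ContactParseError(
                        lineno,
                        f"start {s1 if s1 % resolution else s2} is not a multiple "
                        f"of the resolution {resolution}",
                    )
                i, j = s1 // resolution, s2 // resolution
            else:
                if len(fields) != 3:
                    raise ContactParseError(
                        lineno, f"expected 3 fields (bin_i bin_j count), got {len(fields)}"
                    )
                try:
                    i, j, v = int(fields[0]), int(fields[1]), float(fields[2])
                except ValueError as exc:
                    raise ContactParseError(lineno, str(exc)) from None
                if i < 0 or j < 0:
                    raise ContactParseError(lineno, "bin indices must be non-negative")
                chrom = chrom or "chr?"
            if v < 0:
                n_neg += 1
                v = 0.0
            key = (i, j) if i <= j else (j, i)
            if key in records:
                n_dup += 1
                records[key] += v
            else:
                records[key] = v
    if n_dup:
        warnings.warn(
            f"{n_dup} duplicate contact records were summed", JointMDSWarning
        )
    if n_neg:
        warnings.warn(
            f"{n_neg} negative contact values were clamped to zero", JointMDSWarning
        )

    if chrom is None:
        chrom = "chr?"
    assert resolution is not None
    if not records:
        return SparseContacts(chrom, resolution, np.empty(0, dtype=np.int64),
                              np.empty((0, 0)), normalized=False)

    idx = np.array(sorted({k for pair in records for k in pair}))
    if region is not None:
        lo, hi = region[0] // resolution, -(-region[1] // resolution)
    else:
        lo, hi = int(idx.min()), int(idx.max()) + 1
    bins = np.arange(lo, hi, dtype=np.int64)
    n = bins.size
    mat = np.zeros((n, n))
    for (i, j), v in records.items():
        if not (lo <= i < hi and lo <= j < hi):
            continue
        if i != j:
            mat[i - lo, j - lo] += v
            mat[j - lo, i - lo] += v
    return SparseContacts(chrom, resolution, bins, mat, normalized=False)


def write_structure(structure: Structure, path) -> None:
    """Write a structure as TSV: chrom, start, end, x, y, z (absent loci: empty coords)."""
    if not structure.present.any():
        raise ValueError("cannot write a structure with zero present loci")
    starts = structure.bins * structure.bin_size
    df = pd.DataFrame(
        {
            "chrom": structure.chrom,
            "start": starts,
            "end": starts + structure.bin_size,
            "x": structure.coords[:, 0],
            "y": structure.coords[:, 1],
            "z": structure.coords[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.17g")


def read_structure(path) -> Structure:
    """Read a structure TSV written by :func:`write_structure`."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"structure file must have columns {sorted(required)}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("structure file must cover a single chromosome")
    bin_size = int((df["end"] - df["start"]).iloc[0])
    if not ((df["end"] - df["start"]) == bin_size).all():
        raise ValueError("inconsistent bin sizes in structure file")
    bins = (df["start"] // bin_size).to_numpy(dtype=np.int64)
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return Structure(str(chroms[0]), bin_size, bins, coords)


def write_track(track: CompartmentTrack, path) -> None:
    """Write a compartment score track as bedGraph-style TSV (chrom start end score)."""
    starts = track.bins * track.bin_size
    pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": starts,
            "end": starts + track.bin_size,
            "score": track.score,
        }
    ).to_csv(path, sep="\t", index=False, header=False, float_format="%.17g")


def write_profile(profile: RelocProfile, path, axes: np.ndarray | None = None) -> None:
    """Write a relocalization profile as BED-like TSV (chrom, start, end, magnitude).

    If ``axes`` (3x3, rows = axis directions) is given, per-axis displacement
    components are appended as extra columns.
    """
    starts = profile.bins * profile.bin_size
    cols = {
        "chrom": profile.chrom,
        "start": starts,
        "end": starts + profile.bin_size,
        "magnitude": profile.magnitude,
    }
    if axes is not None:
        comp = profile.displacement @ np.asarray(axes, dtype=float).T
        for k, name in enumerate(("axis1", "axis2", "axis3")):
            cols[name] = comp[:, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_peaks(profile: RelocProfile, path) -> None:
    """Write called peaks as BED-like TSV (chrom, start, end, magnitude, width)."""
    rows = []
    for p in profile.peaks:
        start = int(profile.bins[p.index]) * profile.bin_size
        rows.append(
            (profile.chrom, start, start + profile.bin_size,
             profile.magnitude[p.index], p.width)
        )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "magnitude", "width"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
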