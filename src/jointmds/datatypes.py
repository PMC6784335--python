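"""Core containers for binned Hi-C contact data and 3D chromosome structures.

All genomic coordinates are 0-based, half-open: a bin covers
``[start, start + bin_size)`` and its integer index is ``start // bin_size``.
Matrices are dense internally (chromosome-at-a-time working scale) but the
contact container keeps the sparse-text semantics of the input: absent pairs
are zero, and zero means "missing" wherever a distance is derived from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class JointMDSWarning(UserWarning):
    """Non-fatal data anomalies (duplicate records, clamped values, ties)."""


@dataclass(frozen=True)
class Locus:
    """A single genomic bin: the unit of the contact matrix."""

    chrom: str
    start: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if self.start < 0:
            raise ValueError(f"start must be non-negative, got {self.start}")
        if self.start % self.bin_size != 0:
            raise ValueError(
                f"start {self.start} is not a multiple of bin_size {self.bin_size}"
            )

    @property
    def end(self) -> int:
        return self.start + self.bin_size

    @property
    def bin_index(self) -> int:
        return self.start // self.bin_size


def _check_bins(bins: np.ndarray) -> np.ndarray:
    bins = np.asarray(bins, dtype=np.int64)
    if bins.ndim != 1:
        raise ValueError("bins must be a 1-D array of bin indices")
    if bins.size and (np.any(np.diff(bins) <= 0) or bins[0] < 0):
        raise ValueError("bins must be sorted, unique and non-negative")
    return bins


def _check_square(mat: np.ndarray, n: int, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (n, n):
        raise ValueError(f"{name} must have shape ({n}, {n}), got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError(f"{name} must be symmetric")
    return mat


@dataclass
class SparseContacts:
    """Binned, intrachromosomal contact frequencies for one chromosome.

    ``bins`` are the retained bin indices (sorted, unique); ``matrix`` is the
    symmetric contact matrix over those bins with zero diagonal. Absent pairs
    are stored as zero.
    """

    chrom: str
    bin_size: int
    bins: np.ndarray
    matrix: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bins = _check_bins(self.bins)
        self.matrix = _check_square(self.matrix, self.bins.size, "matrix")
        if np.any(self.matrix < 0):
            raise ValueError("contact frequencies must be non-negative")

    @property
    def n_loci(self) -> int:
        return self.bins.size

    @property
    def loci(self) -> list[Locus]:
        return [Locus(self.chrom, int(b) * self.bin_size, self.bin_size) for b in self.bins]

    def nonzero_values(self) -> np.ndarray:
        """Stored (off-diagonal, upper-triangle) nonzero contact frequencies."""
        iu = np.triu_indices(self.n_loci, k=1)
        vals = self.matrix[iu]
        return vals[vals > 0]

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def copy(self) -> "SparseContacts":
        return SparseContacts(
            self.chrom, self.bin_size, self.bins.copy(), self.matrix.copy(), self.normalized
        )


@dataclass
class DistMatrix:
    """Symmetric target-distance matrix; zeros mark missing pairs (ignored by MDS)."""

    chrom: str
    bin_size: int
    bins: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.bins = _check_bins(self.bins)
        self.delta = _check_square(self.delta, self.bins.size, "delta")
        if np.any(self.delta < 0):
            raise ValueError("target distances must be non-negative")
        if np.any(np.diag(self.delta) != 0):
            raise ValueError("delta must have a zero diagonal")

    @property
    def n_loci(self) -> int:
        return self.bins.size

    @property
    def loci(self) -> list[Locus]:
        return [Locus(self.chrom, int(b) * self.bin_size, self.bin_size) for b in self.bins]

    def same_loci(self, other: "DistMatrix") -> bool:
        return (
            self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and np.array_equal(self.bins, other.bins)
        )


@dataclass
class Structure:
    """Ordered loci with 3D coordinates; NaN rows mark absent loci."""

    chrom: str
    bin_size: int
    bins: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.bins = _check_bins(self.bins)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.bins.size, 3):
            raise ValueError(
                f"coords must have shape ({self.bins.size}, 3), got {self.coords.shape}"
            )

    @property
    def n_loci(self) -> int:
        return self.bins.size

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.coords).any(axis=1)

    @property
    def present_coords(self) -> np.ndarray:
        return self.coords[self.present]

    @property
    def loci(self) -> list[Locus]:
        return [Locus(self.chrom, int(b) * self.bin_size, self.bin_size) for b in self.bins]

    def centered(self) -> "Structure":
        coords = self.coords - np.nanmean(self.coords, axis=0)
        return Structure(self.chrom, self.bin_size, self.bins.copy(), coords)

    def copy(self) -> "Structure":
        return Structure(self.chrom, self.bin_size, self.bins.copy(), self.coords.copy())


def _same_locus_set(a: Structure, b: Structure) -> None:
    if (
        a.chrom != b.chrom
        or a.bin_size != b.bin_size
        or not np.array_equal(a.bins, b.bins)
    ):
        raise ValueError("structures must share an identical locus set")


@dataclass
class AlignedPair:
    """Two structures over an identical locus set in a common frame."""

    x1: Structure
    x2: Structure
    weight: float = 0.0

    def __post_init__(self) -> None:
        _same_locus_set(self.x1, self.x2)
        if self.weight < 0:
            raise ValueError("similarity weight must be non-negative")


@dataclass
class JointFit:
    """Result of a joint embedding: the aligned pair plus optimizer diagnostics."""

    pair: AlignedPair
    final_stress: float
    n_iterations: int
    converged: bool
    seed: int
    stress_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class RigidTransform:
    """Proper rotation (det +1) plus translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class CompartmentTrack:
    """Per-locus A/B compartment score in [-1, 1] (PC1 of the Hi-C correlation matrix)."""

    chrom: str
    bin_size: int
    bins: np.ndarray
    score: np.ndarray
    pc1_variance_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.bins = _check_bins(self.bins)
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (self.bins.size,):
            raise ValueError("score must be one value per locus")

    @property
    def n_loci(self) -> int:
        return self.bins.size

    def copy(self) -> "CompartmentTrack":
        return CompartmentTrack(
            self.chrom, self.bin_size, self.bins.copy(), self.score.copy(),
            self.pc1_variance_fraction,
        )


@dataclass
class AxisFit:
    """A 3D axis that best predicts compartment scores, with fit quality and extent."""

    direction: np.ndarray
    r2: float
    axis_length: float

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (3,):
            raise ValueError("direction must be a 3-vector")
        if not np.isclose(np.linalg.norm(self.direction), 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")
        if self.axis_length <= 0:
            raise ValueError("axis_length must be positive")


@dataclass
class AxisDecomposition:
    """Per-locus relocalization split along the compartment axis and its orthogonal complement."""

    bins: np.ndarray
    axes: np.ndarray                 # (3, 3): rows = compartment axis, ortho1, ortho2
    axis_lengths: np.ndarray         # (3,)
    components: np.ndarray           # (n, 3) signed displacement along each axis
    fractions: np.ndarray            # (n, 3) |component| / magnitude (NaN where magnitude 0)
    normalized_fractions: np.ndarray  # fractions / axis_lengths
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class Peak:
    """A called relocalization peak: locus position within the profile plus width class."""

    index: int
    width: int


@dataclass
class RelocProfile:
    """Per-locus 3D displacement between two aligned structures."""

    chrom: str
    bin_size: int
    bins: np.ndarray
    displacement: np.ndarray
    magnitude: np.ndarray
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bins = _check_bins(self.bins)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        n = self.bins.size
        if self.displacement.shape != (n, 3) or self.magnitude.shape != (n,):
            raise ValueError("displacement must be (n, 3) and magnitude (n,)")
        if not np.allclose(
            self.magnitude, np.linalg.norm(self.displacement, axis=1), atol=1e-12
        ):
            raise ValueError("magnitude must equal the displacement norm")
        for p in self.peaks:
            if not 0 <= p.index < n:
                raise ValueError(f"peak index {p.index} out of range")

    @property
    def n_loci(self) -> int:
        return self.bins.size
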