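"""Ground-truth fixtures: structures and contact matrices with planted differences.

Everything here is a pure function of its parameters and seed. The
generators emulate, at the contact-matrix level, the experimental designs
the package is meant to detect: a single relocated locus, a shifted
interaction-domain boundary between two otherwise identical datasets, and
a two-compartment checkerboard in which a block of loci switches
compartment. Contacts follow the c = d^-4 power law that the distance
conversion inverts, so noiseless fixtures make the full pipeline an exact
inverse problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import SparseContacts, Structure

__all__ = [
    "FixtureSpec",
    "make_structure",
    "structure_to_contacts",
    "make_boundary_pair",
    "make_compartment_pair",
]

FIXTURE_CHROM = "chrSim"
FIXTURE_BIN_SIZE = 100_000

HELIX_RADIUS = 1.0
HELIX_STEP_ANGLE = 0.4   # radians between consecutive loci
HELIX_RISE = 0.1         # embedding units of rise per locus


@dataclass
class FixtureSpec:
    """Recipe for a synthetic ground-truth structure."""

    n_loci: int
    base_geometry: str = "helix"
    noise_sd: float = 0.0
    displacements: dict[int, np.ndarray] = field(default_factory=dict)
    seed: int = 0


def make_structure(spec: FixtureSpec) -> Structure:
    """Deterministic ground-truth structure from a fixture spec.

    The helix has fixed radius and rise, so consecutive-locus distances are
    all equal; the random walk takes unit steps in uniformly random
    directions. Gaussian jitter of ``noise_sd`` is added to every
    coordinate, then the planted per-locus displacements are applied.
    """
    n = spec.n_loci
    if n < 10:
        raise ValueError("fixtures need at least 10 loci")
    rng = np.random.default_rng(spec.seed)
    if spec.base_geometry == "helix":
        t = np.arange(n) * HELIX_STEP_ANGLE
        coords = np.column_stack(
            [HELIX_RADIUS * np.cos(t), HELIX_RADIUS * np.sin(t), HELIX_RISE * np.arange(n)]
        )
    elif spec.base_geometry == "random_walk":
        steps = rng.normal(size=(n - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    else:
        raise ValueError(f"unknown base geometry {spec.base_geometry!r}")
    if spec.noise_sd > 0:
        coords = coords + rng.normal(scale=spec.noise_sd, size=coords.shape)
    for idx, vec in spec.displacements.items():
        if not 0 <= idx < n:
            raise ValueError(f"displacement locus {idx} outside [0, {n})")
        coords[idx] = coords[idx] + np.asarray(vec, dtype=float)
    return Structure(FIXTURE_CHROM, FIXTURE_BIN_SIZE, np.arange(n, dtype=np.int64), coords)


def structure_to_contacts(
    x: Structure,
    contact_exponent: float = -4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SparseContacts:
    """Contacts implied by a structure: c_ij = d_ij ** contact_exponent.

    The default exponent -4 is the inverse of the d = c^(-1/4) conversion,
    so with ``noise_sd = 0`` the pipeline recovers the structure's distances
    exactly. Multiplicative log-normal noise exp(N(0, noise_sd^2)) keeps
    contacts positive.
    """
    d = squareform(pdist(x.coords))
    n = x.n_loci
    iu = np.triu_indices(n, k=1)
    if np.any(d[iu] == 0):
        raise ValueError("coincident points: pairwise distances must be positive")
    c = d[iu] ** contact_exponent
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c = c * np.exp(rng.normal(0.0, noise_sd, size=c.shape))
    mat = np.zeros((n, n))
    mat[iu] = c
    mat = mat + mat.T
    return SparseContacts(x.chrom, x.bin_size, x.bins.copy(), mat, normalized=False)


def _decay(n: int) -> np.ndarray:
    s = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    base = 1.0 / (1.0 + s.astype(float))
    np.fill_diagonal(base, 0.0)
    return base


def make_boundary_pair(
    n_loci: int = 200,
    boundary_a: int = 95,
    boundary_b: int = 105,
    within_enrich: float = 3.0,
    depth: float = 200.0,
    seed: int = 0,
    noise: str = "poisson",
) -> tuple[SparseContacts, SparseContacts]:
    """Two block-model contact matrices differing only in a domain boundary.

    Both matrices share a power-law distance-decay baseline; pairs inside
    the same domain are enriched ``within_enrich``-fold. The first matrix
    puts the boundary at bin ``boundary_a``, the second at ``boundary_b``;
    only the loci between the two boundaries switch domains, which is the
    planted differential signal. Noise is Poisson resampling of the
    expected counts at the given sequencing ``depth`` (or multiplicative
    log-normal with sd 0.2 for ``noise="lognormal"``).
    """
    for b in (boundary_a, boundary_b):
        if not 0 < b < n_loci:
            raise ValueError(f"boundary {b} must be interior to [0, {n_loci})")
    if boundary_a == boundary_b:
        pass  # identical generative model: a valid null fixture
    rng = np.random.default_rng(seed)
    base = _decay(n_loci)
    out = []
    for boundary in (boundary_a, boundary_b):
        domain = (np.arange(n_loci) < boundary).astype(int)
        same = domain[:, None] == domain[None, :]
        expect = base * np.where(same, within_enrich, 1.0)
        np.fill_diagonal(expect, 0.0)
        iu = np.triu_indices(n_loci, k=1)
        if noise == "poisson":
            counts = rng.poisson(expect[iu] * depth).astype(float)
        elif noise == "lognormal":
            counts = expect[iu] * depth * np.exp(rng.normal(0.0, 0.2, size=iu[0].shape))
        else:
            raise ValueError(f"unknown noise model {noise!r}")
        mat = np.zeros((n_loci, n_loci))
        mat[iu] = counts
        mat = mat + mat.T
        out.append(
            SparseContacts(
                FIXTURE_CHROM, FIXTURE_BIN_SIZE,
                np.arange(n_loci, dtype=np.int64), mat,
            )
        )
    return out[0], out[1]


def make_compartment_pair(
    n_loci: int = 100,
    flip_block: tuple[int, int] = (45, 55),
    block_size: int = 10,
    amplitude: float = 0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[SparseContacts, SparseContacts, tuple[np.ndarray, np.ndarray]]:
    """Two-compartment checkerboard pair with a planted compartment flip.

    Compartment labels alternate in blocks of ``block_size`` bins
    (checkerboard plaid); same-compartment pairs are enriched by
    ``1 + amplitude`` and cross-compartment pairs depleted by
    ``1 - amplitude`` over the shared distance decay. In the second
    condition the loci in ``flip_block`` (half-open bin interval) switch
    compartment. Returns the two matrices plus the per-condition truth
    labels (+1 / -1).
    """
    lo, hi = flip_block
    if not (0 <= lo <= hi <= n_loci):
        raise ValueError("flip_block must be an interval inside the matrix")
    if hi - lo >= n_loci:
        raise ValueError("flip_block must not cover the whole matrix")
    if not 0 < amplitude < 1:
        raise ValueError("amplitude must be in (0, 1)")
    labels_a = np.where((np.arange(n_loci) // block_size) % 2 == 0, 1, -1)
    labels_b = labels_a.copy()
    labels_b[lo:hi] = -labels_b[lo:hi]
    rng = np.random.default_rng(seed)
    base = _decay(n_loci)
    out = []
    for labels in (labels_a, labels_b):
        same = labels[:, None] == labels[None, :]
        expect = base * np.where(same, 1.0 + amplitude, 1.0 - amplitude)
        np.fill_diagonal(expect, 0.0)
        iu = np.triu_indices(n_loci, k=1)
        c = expect[iu]
        if noise_sd > 0:
            c = c * np.exp(rng.normal(0.0, noise_sd, size=c.shape))
        mat = np.zeros((n_loci, n_loci))
        mat[iu] = c
        mat = mat + mat.T
        out.append(
            SparseContacts(
                FIXTURE_CHROM, FIXTURE_BIN_SIZE,
                np.arange(n_loci, dtype=np.int64), mat,
            )
        )
    return out[0], out[1], (labels_a, labels_b)
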