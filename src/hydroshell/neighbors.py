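"""Periodic neighbour search, rank statistics, RDF and coordination numbers.

Neighbours are defined oxygen-to-oxygen throughout: the coordination shells
of water and its pair correlations are conventionally described by g_OO(r),
and the rank-k neighbour distances (including d5, the fifth) are O–O
distances.  Hydrogens are never used in this module.

All distances use the minimum-image convention in an orthorhombic box,
valid for separations up to half the smallest box edge.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .frames import BoxedFrame

logger = logging.getLogger(__name__)

__all__ = [
    "minimum_image_distance",
    "oo_distance_matrix",
    "NeighborTable",
    "build_neighbor_table",
    "RankDistribution",
    "rank_distribution",
    "RDFResult",
    "rdf",
    "coordination_number",
    "coordination_count",
]


def minimum_image_distance(a, b, box) -> float | np.ndarray:
    """Smallest |a − b + n·box| over integer image shifts n (orthorhombic box).

    Broadcasts over leading axes; the last axis is the Cartesian component.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    d = a - b
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=-1)
    return float(r) if r.ndim == 0 else r


def oo_distance_matrix(frame: BoxedFrame) -> np.ndarray:
    """(N, N) oxygen–oxygen minimum-image distance matrix."""
    o = frame.oxygen_positions
    d = o[:, None, :] - o[None, :, :]
    d -= frame.box * np.round(d / frame.box)
    return np.linalg.norm(d, axis=-1)


@dataclasses.dataclass
class NeighborTable:
    """Distance-sorted O–O neighbour lists, one row per molecule.

    ``distances[i, k]`` is molecule i's rank-(k+1) neighbour distance and
    ``indices[i, k]`` the neighbour's molecule index.  Rows are ascending in
    distance; ties are broken by ascending molecule index, so tables are
    deterministic.  Self is excluded.
    """

    distances: np.ndarray  # (N, max_rank) Å
    indices: np.ndarray  # (N, max_rank) int
    max_rank: int

    @property
    def n_molecules(self) -> int:
        return self.distances.shape[0]

    def rank(self, k: int) -> np.ndarray:
        """Per-molecule distance to the rank-k neighbour (k is 1-based)."""
        if not 1 <= k <= self.max_rank:
            raise ValueError(f"rank {k} outside table (max_rank={self.max_rank})")
        return self.distances[:, k - 1]


def build_neighbor_table(frame: BoxedFrame, max_rank: int) -> NeighborTable:
    """Sorted neighbour table truncated at ``max_rank`` neighbours per molecule."""
    n = frame.n_molecules
    if max_rank >= n:
        raise ValueError(f"max_rank={max_rank} must be < molecule count {n}")
    dist = oo_distance_matrix(frame)
    np.fill_diagonal(dist, np.inf)
    # Stable sort ⇒ ties resolved by ascending molecule index.
    order = np.argsort(dist, axis=1, kind="stable")[:, :max_rank]
    rows = np.arange(n)[:, None]
    return NeighborTable(distances=dist[rows, order], indices=order, max_rank=max_rank)


@dataclasses.dataclass
class RankDistribution:
    """Pooled histogram of the rank-k neighbour distance (unit total mass)."""

    k: int
    bin_edges: np.ndarray  # Å
    probabilities: np.ndarray  # sums to 1 with the overflow mass included
    overflow: float  # probability mass beyond the last edge
    n_samples: int


def rank_distribution(
    frames: Sequence[BoxedFrame], k: int, bins: np.ndarray
) -> RankDistribution:
    """Histogram of the rank-k O–O distance pooled over molecules and frames.

    Distances beyond the last bin edge are counted in a flagged overflow
    bucket (and logged) rather than silently dropped.
    """
    if k < 1:
        raise ValueError("rank k must be >= 1")
    if not len(frames):
        raise ValueError("frames must be non-empty")
    bins = np.asarray(bins, dtype=float)
    samples = np.concatenate(
        [build_neighbor_table(f, max_rank=k).rank(k) for f in frames]
    )
    counts, _ = np.histogram(samples, bins=bins)
    n_over = int(np.count_nonzero(samples >= bins[-1]))
    if n_over:
        logger.warning(
            "rank_distribution: %d of %d rank-%d distances exceed the last "
            "bin edge %.3f Å (overflow bucket)", n_over, samples.size, k, bins[-1]
        )
    total = samples.size
    return RankDistribution(
        k=k,
        bin_edges=bins,
        probabilities=counts / total,
        overflow=n_over / total,
        n_samples=total,
    )


@dataclasses.dataclass
class RDFResult:
    """Oxygen–oxygen radial distribution function averaged over frames."""

    bin_edges: np.ndarray  # Å, uniform width
    g: np.ndarray  # dimensionless, one value per bin
    number_density: float  # Å⁻³, frame average
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def rdf(
    frames: Sequence[BoxedFrame], bin_width: float = 0.05, r_max: float | None = None
) -> RDFResult:
    """Pair-count g_OO(r) estimator normalised by the ideal-gas shell count.

    ``r_max`` defaults to half the smallest box edge and may not exceed it
    (the minimum-image convention counts each image pair once only below
    L/2).  Shell volumes are exact, (4π/3)(r₊³ − r₋³).
    """
    if not len(frames):
        raise ValueError("frames must be non-empty")
    min_edge = min(float(np.min(f.box)) for f in frames)
    if r_max is None:
        r_max = min_edge / 2.0
    if r_max > min_edge / 2.0 + 1e-12:
        raise ValueError(
            f"r_max={r_max} exceeds half the smallest box edge ({min_edge / 2}); "
            "image pairs would be double counted"
        )
    n_bins = int(np.ceil(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    g_acc = np.zeros(n_bins)
    rho_acc = 0.0
    shell_vol = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    for frame in frames:
        n = frame.n_molecules
        dist = oo_distance_matrix(frame)
        iu = np.triu_indices(n, k=1)
        counts, _ = np.histogram(dist[iu], bins=edges)
        rho = frame.number_density
        # 2 * unordered pairs / (N molecules * ideal shell occupancy)
        g_acc += 2.0 * counts / (n * rho * shell_vol)
        rho_acc += rho
    return RDFResult(
        bin_edges=edges,
        g=g_acc / len(frames),
        number_density=rho_acc / len(frames),
        n_frames=len(frames),
    )


def coordination_number(rdf_result: RDFResult, r_cut: float) -> float:
    """Running coordination number n(r_cut) = 4πρ ∫₀^{r_cut} g(r) r² dr.

    Trapezoidal integration over bin centres (with n(0) = 0 anchored);
    ``r_cut`` may fall between centres and is linearly interpolated.
    """
    if r_cut < 0 or r_cut > rdf_result.bin_edges[-1]:
        raise ValueError(f"r_cut={r_cut} outside the RDF range")
    r = np.concatenate([[0.0], rdf_result.bin_centers])
    integrand = np.concatenate([[0.0], rdf_result.g * rdf_result.bin_centers**2])
    from scipy.integrate import cumulative_trapezoid

    cum = 4.0 * np.pi * rdf_result.number_density * cumulative_trapezoid(
        integrand, r, initial=0.0
    )
    return float(np.interp(r_cut, r, cum))


def coordination_count(frames: Sequence[BoxedFrame], r_cut: float) -> float:
    """Direct coordination number: mean O neighbours within ``r_cut`` Å.

    The reference implementation against which the RDF integral is checked.
    """
    if not len(frames):
        raise ValueError("frames must be non-empty")
    total = 0.0
    for frame in frames:
        dist = oo_distance_matrix(frame)
        np.fill_diagonal(dist, np.inf)
        total += np.count_nonzero(dist < r_cut) / frame.n_molecules
    return total / len(frames)
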