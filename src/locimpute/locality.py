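"""Covering windows, genotype encoding, and windowed sample distances.

The locality assumption: recombination is rare, so only SNP loci within a
genetic distance ``delta`` (cM) of the target locus carry information about
it.  A *covering window* is the set of such loci; samples restricted to a
window are compared by (weighted) Hamming distance over the orthogonal
3-bit-per-locus encoding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List

import numpy as np

from .genetic_map import GeneticMap
from .genotype_model import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Below this many flanking loci on a side, windows give weak support.
MIN_SIDE_LOCI = 3


@dataclass(frozen=True)
class Window:
    """The covering window of a target locus.

    ``left`` holds in-window locus indices ``i-L .. i-1`` and ``right`` holds
    ``i+1 .. i+R``, both in positional order.  ``L + R == 0`` means the
    target is windowless (no informative neighbors at this ``delta``).
    """

    target_locus: int
    left: tuple
    right: tuple
    delta_cM: float

    @property
    def n_left(self) -> int:
        return len(self.left)

    @property
    def n_right(self) -> int:
        return len(self.right)

    @property
    def size(self) -> int:
        return len(self.left) + len(self.right)

    @property
    def loci(self) -> tuple:
        """All in-window loci, left block then right block."""
        return self.left + self.right


@dataclass
class EncodedPanel:
    """Orthogonally encoded window genotypes, one binary row per sample.

    Each in-window locus occupies a 3-bit block: code 0 -> (1,0,0),
    1 -> (0,1,0), 2 -> (0,0,1), missing -> (0,0,0).
    """

    vectors: np.ndarray  # (m, 3 * window.size) uint8
    locus_order: tuple


@dataclass
class LocusWeights:
    """Per-window-locus weights, scaled so the maximum equals 100."""

    weights: np.ndarray  # aligned to Window.loci


# 3-bit orthogonal blocks indexed by code (+1 shifts MISSING=-1 to row 0).
_ORTHO_BLOCKS = np.array(
    [
        [0, 0, 0],  # MISSING
        [1, 0, 0],  # code 0
        [0, 1, 0],  # code 1
        [0, 0, 1],  # code 2
    ],
    dtype=np.uint8,
)


def covering_window(
    gmap: GeneticMap, i: int, delta_cM: float, *, warn: bool = True
) -> Window:
    """Loci within ``delta_cM`` of locus ``i`` on each side, same chromosome.

    Logs a warning when a side has fewer than 3 loci, where imputation
    support becomes unreliable.
    """
    if delta_cM <= 0:
        raise ValueError("delta_cM must be positive")
    n = len(gmap)
    if not 0 <= i < n:
        raise IndexError(f"locus index {i} out of range for {n} loci")
    pos = gmap.positions_cM
    chrom = gmap.chromosomes
    center = pos[i]

    left: List[int] = []
    k = i - 1
    while k >= 0 and chrom[k] == chrom[i] and center - pos[k] <= delta_cM:
        left.append(k)
        k -= 1
    left.reverse()

    right: List[int] = []
    k = i + 1
    while k < n and chrom[k] == chrom[i] and pos[k] - center <= delta_cM:
        right.append(k)
        k += 1

    if warn and (len(left) < MIN_SIDE_LOCI or len(right) < MIN_SIDE_LOCI):
        logger.warning(
            "locus %d: covering window has L=%d, R=%d flanking loci "
            "(fewer than %d on a side)",
            i, len(left), len(right), MIN_SIDE_LOCI,
        )
    return Window(
        target_locus=i, left=tuple(left), right=tuple(right), delta_cM=delta_cM
    )


def encode_orthogonal(matrix: GenotypeMatrix, window: Window) -> EncodedPanel:
    """One-hot 3-bit-per-locus encoding of every sample over the window."""
    loci = window.loci
    if not loci:
        return EncodedPanel(
            vectors=np.zeros((matrix.n_samples, 0), dtype=np.uint8),
            locus_order=(),
        )
    codes = matrix.values[list(loci), :].T  # (m, L+R)
    vectors = _ORTHO_BLOCKS[codes + 1].reshape(matrix.n_samples, -1)
    return EncodedPanel(vectors=vectors, locus_order=loci)


def encode_additive(matrix: GenotypeMatrix, window: Window):
    """Additive (allele-count) encoding of the window: 0/1/2, MISSING kept.

    Provided for experimentation; the imputers use the orthogonal encoding.
    Missing entries keep the :data:`MISSING` marker and must be excluded
    from any distance term by the consumer.
    """
    loci = window.loci
    if not loci:
        return np.zeros((matrix.n_samples, 0), dtype=np.int8)
    return matrix.values[list(loci), :].T.copy()


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Number of differing bit positions between two encoded vectors.

    Per locus this yields 2 for two different known genotypes, 1 for
    known-vs-missing, and 0 for missing-vs-missing.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


#: A co-located locus (zero genetic distance) gets this multiple of the
#: largest finite reciprocal weight in the window.
ZERO_DISTANCE_CAP_FACTOR = 10.0


def locus_weights(gmap: GeneticMap, window: Window) -> LocusWeights:
    """Reciprocal-distance weights for the window loci, scaled into [0, 100].

    Raw weight of in-window locus ``i'`` is ``1 / |cM(i') - cM(i)|``; a locus
    at zero genetic distance gets ten times the largest finite raw weight so
    it dominates without becoming infinite.  Weights are then scaled so the
    maximum equals 100, preserving ratios.
    """
    if window.size < 1:
        raise ValueError("window has no loci to weight")
    pos = gmap.positions_cM
    d = np.abs(pos[list(window.loci)] - pos[window.target_locus])
    raw = np.empty_like(d)
    finite = d > 0
    raw[finite] = 1.0 / d[finite]
    if finite.any():
        raw[~finite] = raw[finite].max() * ZERO_DISTANCE_CAP_FACTOR
    else:
        raw[:] = 1.0  # all co-located: uniform weights
    return LocusWeights(weights=raw * (100.0 / raw.max()))


def weighted_hamming(
    a: np.ndarray, b: np.ndarray, weights: LocusWeights
) -> float:
    """Weighted Hamming distance: each locus's 3 bits carry its weight."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    w = np.asarray(weights.weights, dtype=np.float64)
    if 3 * len(w) != a.shape[-1]:
        raise ValueError(
            f"{len(w)} locus weights do not cover {a.shape[-1]} bits"
        )
    bit_w = np.repeat(w, 3)
    return float(bit_w[a != b].sum())


def pairwise_hamming(panel: EncodedPanel, target: int) -> np.ndarray:
    """Hamming distance from sample ``target`` to every sample (vectorised)."""
    diff = panel.vectors != panel.vectors[target]
    return diff.sum(axis=1).astype(np.int64)


def pairwise_weighted_hamming(
    panel: EncodedPanel, target: int, weights: LocusWeights
) -> np.ndarray:
    """Weighted Hamming distance from sample ``target`` to every sample."""
    bit_w = np.repeat(np.asarray(weights.weights, dtype=np.float64), 3)
    diff = panel.vectors != panel.vectors[target]
    return diff @ bit_w


def tier_equal(d1: float, d2: float, rel_tol: float = 1e-9) -> bool:
    """Whether two weighted distances fall in the same nearest-neighbor tier."""
    return math.isclose(d1, d2, rel_tol=rel_tol, abs_tol=1e-12)
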