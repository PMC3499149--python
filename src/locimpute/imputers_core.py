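"""BaseLine majority voting and the (weighted) nearest-neighbor imputers.

NN ranks training samples by Hamming distance over the target's covering
window and takes the majority genotype among all closest samples; while the
vote is tied it recruits the next-closest tier, and a tie that survives all
tiers is broken deterministically by the lowest genotype code.  WNN is the
same scheme with reciprocal-genetic-distance locus weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genetic_map import GeneticMap
from .genotype_model import MISSING, GenotypeMatrix
from .locality import (
    LocusWeights,
    Window,
    covering_window,
    encode_orthogonal,
    locus_weights,
    pairwise_hamming,
    pairwise_weighted_hamming,
    tier_equal,
)

#: Relative tolerance for grouping weighted distances into equal tiers.
TIER_REL_TOL = 1e-9


@dataclass(frozen=True)
class ImputeDecision:
    """Outcome of imputing one missing entry.

    ``value`` is a genotype code, or ``None`` when the entry is excluded
    (windowless target, or no training sample carries a known value).
    ``support`` counts the training samples behind the final vote;
    ``tiers_used`` counts distance tiers recruited (nearest-neighbor family).
    """

    value: Optional[int]
    support: int = 0
    tiers_used: int = 0

    @property
    def excluded(self) -> bool:
        return self.value is None


EXCLUDED = ImputeDecision(value=None)


def _majority(counts: np.ndarray) -> tuple:
    """(winner or None-if-tied, top count). Ties leave winner None."""
    top = counts.max()
    winners = np.flatnonzero(counts == top)
    return (int(winners[0]) if len(winners) == 1 else None), int(top)


def baseline_impute(matrix: GenotypeMatrix, i: int, j: int) -> ImputeDecision:
    """Majority vote over the known genotypes at locus ``i`` (samples != j).

    Ties are broken by the lowest genotype code.  Excluded only when no
    other sample has a known value at the locus.
    """
    row = matrix.values[i]
    known = np.flatnonzero(row != MISSING)
    known = known[known != j]
    if len(known) == 0:
        return EXCLUDED
    counts = np.bincount(row[known], minlength=3)
    winner, top = _majority(counts)
    if winner is None:
        winner = int(np.flatnonzero(counts == top)[0])  # lowest code
    return ImputeDecision(value=winner, support=int(counts.sum()), tiers_used=1)


def tiered_vote(
    labels: Sequence[int],
    distances: np.ndarray,
    weighted: bool = False,
) -> ImputeDecision:
    """Expanding-tier majority vote over training samples.

    Samples are grouped into tiers of equal distance (exact for integer
    Hamming distances; relative tolerance ``1e-9`` for weighted ones).
    Starting from the nearest tier, the majority genotype among all
    recruited samples wins; a tied vote recruits the next tier.  A tie that
    survives every tier resolves to the lowest genotype code.
    """
    labels = np.asarray(labels)
    distances = np.asarray(distances)
    order = np.argsort(distances, kind="stable")
    counts = np.zeros(3, dtype=np.int64)
    tiers = 0
    k = 0
    n = len(order)
    while k < n:
        # recruit one full tier of equal distance
        tier_rep = distances[order[k]]
        while k < n and (
            tier_equal(float(distances[order[k]]), float(tier_rep), TIER_REL_TOL)
            if weighted
            else distances[order[k]] == tier_rep
        ):
            counts[labels[order[k]]] += 1
            k += 1
        tiers += 1
        winner, top = _majority(counts)
        if winner is not None:
            return ImputeDecision(
                value=winner, support=int(counts.sum()), tiers_used=tiers
            )
    # all tiers recruited and still tied: lowest code among the top counts
    top = counts.max()
    winner = int(np.flatnonzero(counts == top)[0])
    return ImputeDecision(value=winner, support=int(counts.sum()), tiers_used=tiers)


def _training_samples(matrix: GenotypeMatrix, i: int, j: int) -> np.ndarray:
    """Samples other than ``j`` with a known genotype at locus ``i``."""
    known = np.flatnonzero(matrix.values[i] != MISSING)
    return known[known != j]


def nn_impute(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    i: int,
    j: int,
    delta_cM: float,
    *,
    window: Optional[Window] = None,
) -> ImputeDecision:
    """Nearest-neighbor imputation of the missing entry ``(i, j)``.

    Returns an excluded decision when the covering window is empty or no
    training sample has a known value at the locus.
    """
    if window is None:
        window = covering_window(gmap, i, delta_cM, warn=False)
    if window.size == 0:
        return EXCLUDED
    train = _training_samples(matrix, i, j)
    if len(train) == 0:
        return EXCLUDED
    panel = encode_orthogonal(matrix, window)
    dists = pairwise_hamming(panel, j)[train]
    return tiered_vote(matrix.values[i, train], dists, weighted=False)


def wnn_impute(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    i: int,
    j: int,
    delta_cM: float,
    *,
    window: Optional[Window] = None,
    weights: Optional[LocusWeights] = None,
) -> ImputeDecision:
    """Weighted nearest-neighbor imputation of the missing entry ``(i, j)``."""
    if window is None:
        window = covering_window(gmap, i, delta_cM, warn=False)
    if window.size == 0:
        return EXCLUDED
    train = _training_samples(matrix, i, j)
    if len(train) == 0:
        return EXCLUDED
    if weights is None:
        weights = locus_weights(gmap, window)
    panel = encode_orthogonal(matrix, window)
    dists = pairwise_weighted_hamming(panel, j, weights)[train]
    return tiered_vote(matrix.values[i, train], dists, weighted=True)
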