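"""Genetic (centi-Morgan) coordinates per locus.

Windows are defined in genetic distance, so every locus needs a cumulative cM
position.  These come either from a HapMap-style genetic map file (bp,
rate cM/Mb, cumulative cM) via linear interpolation, or from the rough
physical fallback of one million basepairs per centi-Morgan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_model import LocusInfo

#: Fallback scale: one centi-Morgan per million basepairs.
BP_PER_CM: float = 1_000_000.0


class GeneticMapError(ValueError):
    """Raised when a genetic map file violates its constraints."""


@dataclass
class GeneticMap:
    """Per-locus cumulative genetic positions, aligned to a locus order.

    ``positions_cM`` is non-decreasing along the locus order within each
    chromosome; ``chromosomes`` carries the per-locus chromosome label so
    that covering windows never span a chromosome boundary.
    """

    positions_cM: np.ndarray
    source: str  # "file" or "fallback"
    chromosomes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions_cM = np.asarray(self.positions_cM, dtype=np.float64)
        if self.chromosomes is None:
            self.chromosomes = np.zeros(len(self.positions_cM), dtype=np.int64)
        else:
            self.chromosomes = np.asarray(self.chromosomes)
        if len(self.chromosomes) != len(self.positions_cM):
            raise ValueError("chromosomes and positions_cM length mismatch")
        for chrom in np.unique(self.chromosomes):
            pos = self.positions_cM[self.chromosomes == chrom]
            if np.any(np.diff(pos) < 0):
                raise GeneticMapError(
                    f"cM positions decrease along chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.positions_cM)


def read_hapmap_genetic_map(path) -> np.ndarray:
    """Read HapMap genetic-map text into an array of (bp, cM) anchors.

    The file has one header line and three numeric columns: position (bp),
    recombination rate (cM/Mb), and cumulative map position (cM).  The rate
    column is ignored; interpolation works from the cumulative column.
    """
    anchors: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 3:
                raise GeneticMapError(
                    f"{path}: line {lineno}: expected 3 columns"
                )
            try:
                bp, _rate, cm = float(fields[0]), float(fields[1]), float(fields[2])
            except ValueError as exc:
                raise GeneticMapError(
                    f"{path}: line {lineno}: non-numeric field"
                ) from exc
            anchors.append((bp, cm))
    if len(anchors) < 2:
        raise GeneticMapError(f"{path}: need at least 2 anchor rows")
    table = np.asarray(anchors, dtype=np.float64)
    if np.any(np.diff(table[:, 0]) <= 0):
        raise GeneticMapError(f"{path}: bp positions not strictly increasing")
    if np.any(np.diff(table[:, 1]) < 0):
        raise GeneticMapError(f"{path}: cumulative cM not non-decreasing")
    return table


def interpolate_map(anchors: np.ndarray, loci: Sequence[LocusInfo]) -> GeneticMap:
    """Per-locus cM by piecewise-linear interpolation between anchors.

    Loci outside the anchored range are extrapolated with the slope of the
    nearest anchor interval, then clamped to be non-decreasing along the
    locus order.
    """
    anchors = np.asarray(anchors, dtype=np.float64)
    if anchors.ndim != 2 or anchors.shape[0] < 1:
        raise ValueError("anchors must be a non-empty (k, 2) table")
    bp = np.array([l.position_bp for l in loci], dtype=np.float64)
    a_bp, a_cm = anchors[:, 0], anchors[:, 1]

    cm = np.interp(bp, a_bp, a_cm)
    if anchors.shape[0] >= 2:
        lo_slope = (a_cm[1] - a_cm[0]) / (a_bp[1] - a_bp[0])
        hi_slope = (a_cm[-1] - a_cm[-2]) / (a_bp[-1] - a_bp[-2])
        below = bp < a_bp[0]
        above = bp > a_bp[-1]
        cm[below] = a_cm[0] + (bp[below] - a_bp[0]) * lo_slope
        cm[above] = a_cm[-1] + (bp[above] - a_bp[-1]) * hi_slope
    cm = np.maximum.accumulate(cm)  # clamp extrapolation to non-decreasing

    chroms = _chromosome_codes(loci)
    return GeneticMap(positions_cM=cm, source="file", chromosomes=chroms)


def fallback_map(loci: Sequence[LocusInfo]) -> GeneticMap:
    """The 1 Mbp/cM physical fallback: cM = bp / 1e6, per locus."""
    bp = np.array([l.position_bp for l in loci], dtype=np.float64)
    return GeneticMap(
        positions_cM=bp / BP_PER_CM,
        source="fallback",
        chromosomes=_chromosome_codes(loci),
    )


def _chromosome_codes(loci: Sequence[LocusInfo]) -> np.ndarray:
    """Integer chromosome labels in order of first appearance."""
    rank: dict[str, int] = {}
    out = np.empty(len(loci), dtype=np.int64)
    for k, l in enumerate(loci):
        if l.chromosome not in rank:
            rank[l.chromosome] = len(rank)
        out[k] = rank[l.chromosome]
    return out
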