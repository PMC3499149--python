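"""Canonical genotype data model and text-format readers/writers.

A panel of ``m`` samples genotyped at ``n`` bi-allelic SNP loci is held as an
``n x m`` matrix of genotype codes: ``0`` and ``2`` for the two homozygotes,
``1`` for the heterozygote, and :data:`MISSING` (``-1``) for a no-call.
Inbred (effectively haploid) panels are representable with codes ``{0, 2}``
only, which is how haplotype-allele imputation is run.

Two text dialects are supported: HapMap Phase I genotype dumps (two-letter
genotypes, ``NN`` for missing) and a plain TSV matrix with cells in
``{0, 1, 2, ?}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing (no-call) value.
MISSING: int = -1

#: The three observable genotype classes.
VALID_CODES: Tuple[int, int, int] = (0, 1, 2)

# Number of metadata columns before the per-sample genotype columns in a
# HapMap Phase I genotype dump (rs#, alleles, chrom, pos, strand, assembly#,
# center, protLSID, assayLSID, panelLSID, QCcode).
_HAPMAP_META_COLS = 11


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


class GenotypeDataError(ValueError):
    """Raised when a genotype file parses but violates a data constraint."""


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for a single SNP locus.

    ``alleles``, when present, is the unordered pair of allele letters from
    letter-coded input, ordered so the first element is the code-0 allele.
    """

    marker_id: str
    chromosome: str
    position_bp: int
    alleles: Optional[Tuple[str, str]] = None


class GenotypeMatrix:
    """An ``n x m`` grid of unphased genotype codes with locus/sample metadata.

    Parameters
    ----------
    loci:
        Per-row :class:`LocusInfo`, one per SNP locus.
    samples:
        Ordered sample identifiers (columns).
    values:
        ``n x m`` integer array with entries in ``{0, 1, 2, MISSING}``.

    Loci are kept sorted by physical position within each chromosome; input
    that is out of order is stably sorted with a logged warning. Duplicate
    positions on a chromosome are rejected.
    """

    def __init__(
        self,
        loci: Sequence[LocusInfo],
        samples: Sequence[str],
        values: np.ndarray,
    ) -> None:
        values = np.asarray(values, dtype=np.int8)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape[0] != len(loci):
            raise ValueError(
                f"{len(loci)} loci but {values.shape[0]} value rows"
            )
        if values.shape[1] != len(samples):
            raise ValueError(
                f"{len(samples)} samples but {values.shape[1]} value columns"
            )
        bad = ~np.isin(values, (*VALID_CODES, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeDataError(
                f"invalid genotype code {values[i, j]} at locus row {i}, "
                f"sample column {j}"
            )

        loci = list(loci)
        order = _position_sort_order(loci)
        if order is not None:
            logger.warning("input loci not sorted by position; sorting on load")
            loci = [loci[k] for k in order]
            values = values[order]
        _check_unique_positions(loci)

        self.loci: list[LocusInfo] = loci
        self.samples: list[str] = list(samples)
        self.values: np.ndarray = values

    # -- basic introspection -------------------------------------------------

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def positions_bp(self) -> np.ndarray:
        return np.array([l.position_bp for l in self.loci], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([l.chromosome for l in self.loci])

    def is_missing(self) -> np.ndarray:
        """Boolean mask of missing entries."""
        return self.values == MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.loci, self.samples, self.values.copy())

    def subset_loci(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(indices), dtype=np.int64)
        return GenotypeMatrix(
            [self.loci[k] for k in idx], self.samples, self.values[idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.samples == other.samples
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix(n_loci={self.n_loci}, n_samples={self.n_samples})"
        )


def _position_sort_order(loci: Sequence[LocusInfo]) -> Optional[np.ndarray]:
    """Stable sort order by (chromosome block, position), or None if sorted.

    Chromosomes keep their order of first appearance; positions sort within
    each chromosome.
    """
    chrom_rank: dict[str, int] = {}
    for l in loci:
        if l.chromosome not in chrom_rank:
            chrom_rank[l.chromosome] = len(chrom_rank)
    keys = [(chrom_rank[l.chromosome], l.position_bp) for l in loci]
    if all(keys[k] <= keys[k + 1] for k in range(len(keys) - 1)):
        return None
    return np.array(
        sorted(range(len(loci)), key=lambda k: keys[k]), dtype=np.int64
    )


def _check_unique_positions(loci: Sequence[LocusInfo]) -> None:
    for a, b in zip(loci, loci[1:]):
        if a.chromosome == b.chromosome and a.position_bp == b.position_bp:
            raise GenotypeDataError(
                f"duplicate position {a.position_bp} on chromosome "
                f"{a.chromosome} (markers {a.marker_id}, {b.marker_id})"
            )


# ---------------------------------------------------------------------------
# HapMap genotype text
# ---------------------------------------------------------------------------

def read_hapmap_genotypes(path) -> GenotypeMatrix:
    """Read a HapMap Phase I genotype dump into a :class:`GenotypeMatrix`.

    Each data row carries 11 metadata columns followed by one two-letter
    genotype per sample (``NN`` = missing).  Letter genotypes are mapped to
    codes by allele frequency at that locus: the more frequent allele's
    homozygote becomes code 0, the heterozygote (either letter order) code 1,
    the rarer homozygote code 2.  Frequency ties are broken alphabetically
    (the alphabetically first allele becomes the code-0 allele).
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise GenotypeParseError(f"{path}: empty file")
        header_fields = header.split()
        if len(header_fields) <= _HAPMAP_META_COLS:
            raise GenotypeParseError(
                f"{path}: header has no sample columns"
            )
        samples = header_fields[_HAPMAP_META_COLS:]
        n_cols = len(header_fields)

        loci: list[LocusInfo] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != n_cols:
                raise GenotypeParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(fields)}"
                )
            marker_id, _alleles, chrom, pos = fields[0], fields[1], fields[2], fields[3]
            genotypes = fields[_HAPMAP_META_COLS:]
            codes, allele_pair = _code_letter_genotypes(marker_id, genotypes)
            loci.append(
                LocusInfo(
                    marker_id=marker_id,
                    chromosome=chrom,
                    position_bp=int(pos),
                    alleles=allele_pair,
                )
            )
            rows.append(codes)

    if not rows:
        raise GenotypeParseError(f"{path}: no data rows")
    return GenotypeMatrix(loci, samples, np.vstack(rows))


def _code_letter_genotypes(
    marker_id: str, genotypes: Sequence[str]
) -> Tuple[np.ndarray, Optional[Tuple[str, str]]]:
    """Map two-letter genotypes at one locus to codes {0,1,2,MISSING}."""
    counts: dict[str, int] = {}
    for g in genotypes:
        if g == "NN":
            continue
        if len(g) != 2:
            raise GenotypeParseError(
                f"marker {marker_id}: malformed genotype {g!r}"
            )
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    if len(counts) > 2:
        raise GenotypeDataError(
            f"marker {marker_id}: more than two alleles observed "
            f"({sorted(counts)})"
        )
    if not counts:  # all NN
        return np.full(len(genotypes), MISSING, dtype=np.int8), None

    # More frequent allele first; alphabetical on ties.
    alleles = sorted(counts, key=lambda a: (-counts[a], a))
    major = alleles[0]
    minor = alleles[1] if len(alleles) > 1 else None

    codes = np.empty(len(genotypes), dtype=np.int8)
    for k, g in enumerate(genotypes):
        if g == "NN":
            codes[k] = MISSING
        elif g == major + major:
            codes[k] = 0
        elif minor is not None and g == minor + minor:
            codes[k] = 2
        elif set(g) == set(alleles):
            codes[k] = 1
        else:
            raise GenotypeDataError(
                f"marker {marker_id}: genotype {g!r} uses alleles outside "
                f"{alleles}"
            )
    pair = (major, minor) if minor is not None else (major, major)
    return codes, pair


# ---------------------------------------------------------------------------
# Canonical TSV matrix dialect
# ---------------------------------------------------------------------------

_TSV_CODE = {"0": 0, "1": 1, "2": 2, "?": MISSING}
_CODE_TSV = {0: "0", 1: "1", 2: "2", MISSING: "?"}


def read_tsv_genotypes(path) -> GenotypeMatrix:
    """Read the canonical TSV dialect.

    Header: ``marker_id<TAB>chrom<TAB>pos<TAB><sample1>...``; body cells in
    ``{0, 1, 2, ?}`` with ``?`` mapping to :data:`MISSING`.
    """
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        header = fh.readline().rstrip("\r\n")
        if not header:
            raise GenotypeParseError(f"{path}: empty file")
        fields = header.split("\t")
        if fields[:3] != ["marker_id", "chrom", "pos"]:
            raise GenotypeParseError(
                f"{path}: header must start with marker_id, chrom, pos"
            )
        samples = fields[3:]
        n_cols = len(fields)

        loci: list[LocusInfo] = []
        rows: list[np.ndarray] = []
        seen_ids: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != n_cols:
                raise GenotypeParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(cells)}"
                )
            marker_id, chrom, pos = cells[0], cells[1], cells[2]
            if marker_id in seen_ids:
                raise GenotypeDataError(
                    f"{path}: duplicate marker_id {marker_id!r}"
                )
            seen_ids.add(marker_id)
            codes = np.empty(n_cols - 3, dtype=np.int8)
            for col, cell in enumerate(cells[3:]):
                cell = cell.strip()
                if cell not in _TSV_CODE:
                    raise GenotypeParseError(
                        f"{path}: line {lineno}, column {col + 4}: "
                        f"invalid cell {cell!r} (expected 0, 1, 2 or ?)"
                    )
                codes[col] = _TSV_CODE[cell]
            loci.append(LocusInfo(marker_id, chrom, int(pos)))
            rows.append(codes)

    if not rows:
        raise GenotypeParseError(f"{path}: no data rows")
    return GenotypeMatrix(loci, samples, np.vstack(rows))


def write_tsv_genotypes(matrix: GenotypeMatrix, path) -> None:
    """Write ``matrix`` in the canonical TSV dialect (``?`` for missing)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["marker_id", "chrom", "pos", *matrix.samples]))
        fh.write("\n")
        for locus, row in zip(matrix.loci, matrix.values):
            cells = [locus.marker_id, locus.chromosome, str(locus.position_bp)]
            cells.extend(_CODE_TSV[int(v)] for v in row)
            fh.write("\t".join(cells))
            fh.write("\n")
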