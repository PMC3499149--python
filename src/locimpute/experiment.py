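"""The simulation and evaluation protocol around the imputers.

The protocol: take a complete (or near-complete) genotype panel, optionally
*decimate* it to emulate a lower-density array, *mask* a fraction of the
known genotypes uniformly at random to create ground truth, run each
imputation method over a grid of genetic-distance thresholds, and score the
*accuracy* — correctly imputed over imputed, with windowless entries
excluded from the statistics for every method for fairness.

A founder-mosaic fixture generator provides panels whose samples share long
identical-by-descent haplotype stretches, the structure every local imputer
exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetic_map import BP_PER_CM, GeneticMap, fallback_map
from .genotype_model import MISSING, GenotypeMatrix, LocusInfo
from .imputers_core import (
    EXCLUDED,
    ImputeDecision,
    baseline_impute,
    nn_impute,
    wnn_impute,
)
from .imputers_model import (
    NeuralNetConfig,
    SvmConfig,
    calibrate_svm,
    mc_impute,
    neuralnet_impute,
    svm_impute,
)
from .locality import covering_window, locus_weights

logger = logging.getLogger(__name__)

#: Method names accepted by :func:`run_experiment` and the CLI.
METHOD_NAMES = ("baseline", "nn", "wnn", "mc", "svm", "neuralnet")

#: Missing rates used throughout the evaluation protocol.
STANDARD_RATES = (0.005, 0.01, 0.02, 0.05, 0.10, 0.20)


# ---------------------------------------------------------------------------
# Density decimation and threshold grid
# ---------------------------------------------------------------------------

def decimate(matrix: GenotypeMatrix, keep_every: int) -> GenotypeMatrix:
    """Retain loci 0, k, 2k, ... to simulate a lower-density array.

    The first marker is always retained, so ``ceil(n / k)`` loci survive.
    """
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if keep_every == 1:
        return matrix.copy()
    return matrix.subset_loci(range(0, matrix.n_loci, keep_every))


def threshold_grid(density: float) -> List[float]:
    """The genetic-distance threshold grid {0.01..0.05}/density cM."""
    if density <= 0:
        raise ValueError("density must be positive")
    return [round(0.01 * k / density, 12) for k in range(1, 6)]


# ---------------------------------------------------------------------------
# Random masking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskSpec:
    """Masking design: rate of known entries hidden, replicate count, seed."""

    rate: float
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rate < 1:
            raise ValueError("rate must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class MaskedDataset:
    """A masked matrix plus the ground truth for the hidden entries."""

    matrix: GenotypeMatrix
    truth: List[Tuple[int, int, int]]  # (locus, sample, true genotype)


def mask(matrix: GenotypeMatrix, spec: MaskSpec, replicate: int) -> MaskedDataset:
    """Hide ``round(rate x known entries)`` known genotypes uniformly.

    The RNG stream is derived from ``(spec.seed, replicate)`` so replicate
    masks are independent and reproducible.
    """
    known_flat = np.flatnonzero(matrix.values != MISSING)
    if len(known_flat) == 0:
        raise ValueError("matrix has no known entries to mask")
    k = int(round(spec.rate * len(known_flat)))
    if k == 0:
        raise ValueError(
            f"rate {spec.rate} masks 0 of {len(known_flat)} known entries"
        )
    rng = np.random.default_rng((spec.seed, replicate))
    picked = rng.choice(known_flat, size=k, replace=False)
    rows, cols = np.unravel_index(picked, matrix.values.shape)

    masked = matrix.copy()
    truth = []
    for i, j in zip(rows, cols):
        truth.append((int(i), int(j), int(masked.values[i, j])))
        masked.values[i, j] = MISSING
    truth.sort()
    return MaskedDataset(matrix=masked, truth=truth)


# ---------------------------------------------------------------------------
# Founder-mosaic fixture generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Design of a synthetic panel with identical-by-descent structure.

    Each sample haplotype is a mosaic of ``n_founders`` founder haplotypes;
    between adjacent loci the mosaic switches founder with probability
    ``recomb_prob_per_cM`` x the interval's genetic length (1 Mbp/cM
    fallback from ``bp_spacing``).  Two haplotypes combine into an unphased
    genotype, or one is duplicated for a homozygous-only (haplotype-allele)
    panel.  Each allele is flipped independently with ``error_rate``.
    """

    n_loci: int = 500
    m_samples: int = 30
    n_founders: int = 6
    bp_spacing: int = 2_500
    recomb_prob_per_cM: float = 1.0
    error_rate: float = 0.005
    homozygous_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0 <= self.recomb_prob_per_cM:
            raise ValueError("recomb_prob_per_cM must be non-negative")


def _founder_path(
    rng: np.random.Generator,
    switch_probs: np.ndarray,
    n_founders: int,
) -> np.ndarray:
    """One mosaic path over ``len(switch_probs) + 1`` loci.

    A switch event at an interval moves to a different founder chosen
    uniformly, so founder changes along the path count switch events.
    """
    n = len(switch_probs) + 1
    path = np.empty(n, dtype=np.int64)
    path[0] = rng.integers(n_founders)
    switches = rng.random(len(switch_probs)) < switch_probs
    for k in range(1, n):
        if switches[k - 1]:
            new = rng.integers(n_founders - 1)
            path[k] = new if new < path[k - 1] else new + 1
        else:
            path[k] = path[k - 1]
    return path


def generate_fixture(spec: FixtureSpec) -> Tuple[GenotypeMatrix, GeneticMap]:
    """Generate a founder-mosaic panel and its (fallback) genetic map."""
    rng = np.random.default_rng(spec.seed)
    positions = (np.arange(spec.n_loci, dtype=np.int64) + 1) * spec.bp_spacing
    interval_cM = np.diff(positions) / BP_PER_CM
    switch_probs = np.minimum(1.0, spec.recomb_prob_per_cM * interval_cM)

    founders = rng.integers(0, 2, size=(spec.n_founders, spec.n_loci))

    def haplotype() -> np.ndarray:
        path = _founder_path(rng, switch_probs, spec.n_founders)
        alleles = founders[path, np.arange(spec.n_loci)]
        if spec.error_rate > 0:
            flips = rng.random(spec.n_loci) < spec.error_rate
            alleles = np.where(flips, 1 - alleles, alleles)
        return alleles

    values = np.empty((spec.n_loci, spec.m_samples), dtype=np.int8)
    for j in range(spec.m_samples):
        h1 = haplotype()
        h2 = h1 if spec.homozygous_only else haplotype()
        values[:, j] = h1 + h2

    loci = [
        LocusInfo(marker_id=f"m{k:06d}", chromosome="1", position_bp=int(p))
        for k, p in enumerate(positions)
    ]
    samples = [f"s{j:04d}" for j in range(spec.m_samples)]
    matrix = GenotypeMatrix(loci, samples, values)
    return matrix, fallback_map(loci)


# ---------------------------------------------------------------------------
# Accuracy evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Accuracy bookkeeping for one (method, delta, replicate) cell."""

    imputed: int
    excluded: int
    correct: int

    @property
    def accuracy(self) -> Optional[float]:
        return self.correct / self.imputed if self.imputed else None


def evaluate(
    masked: MaskedDataset,
    decisions: Mapping[Tuple[int, int], ImputeDecision],
) -> EvalResult:
    """Score decisions against the ground truth.

    Excluded entries leave the denominator; accuracy is exact-match count
    over the imputed count, or undefined (None) when everything was
    excluded.
    """
    imputed = excluded = correct = 0
    for i, j, g in masked.truth:
        if (i, j) not in decisions:
            raise ValueError(f"no decision for masked entry ({i}, {j})")
        dec = decisions[(i, j)]
        if dec.excluded:
            excluded += 1
        else:
            imputed += 1
            if dec.value == g:
                correct += 1
    return EvalResult(imputed=imputed, excluded=excluded, correct=correct)


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

def run_experiment(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    methods: Sequence[str],
    rates: Sequence[float],
    replicates: int,
    grid: Sequence[float],
    seed: int,
    svm_config: Optional[SvmConfig] = None,
    neuralnet_config: Optional[NeuralNetConfig] = None,
) -> pd.DataFrame:
    """Run the full masking/imputation/accuracy protocol.

    For every (method, rate) all ``replicates x len(grid)`` cells are
    computed.  Masks depend only on ``(seed, replicate)``, so adding or
    removing methods never perturbs them.  BaseLine is threshold-free and
    imputed once per replicate, but windowless entries at each threshold
    are excluded from its statistics too, so its accuracy can still vary
    slightly with the threshold.

    Returns a tidy table with one row per (method, rate, delta, replicate).
    """
    methods = list(methods)
    for m in methods:
        if m not in METHOD_NAMES:
            raise ValueError(f"unknown method {m!r}; expected one of {METHOD_NAMES}")
    grid = list(grid)
    svm_cfg = svm_config or SvmConfig()
    nn_cfg = neuralnet_config or NeuralNetConfig()

    if "svm" in methods and (svm_cfg.c is None or svm_cfg.gamma is None):
        # One shared (c, gamma) per dataset, calibrated by cross-validation
        # on the first replicate's masked panel at the middle threshold.
        cal = mask(matrix, MaskSpec(rate=rates[0], replicates=replicates, seed=seed), 0)
        mid_delta = sorted(grid)[len(grid) // 2]
        svm_cfg = calibrate_svm(
            cal.matrix, gmap, mid_delta, svm_cfg,
            np.random.default_rng((seed, 777)),
        )

    rows: List[dict] = []
    for rate in rates:
        spec = MaskSpec(rate=rate, replicates=replicates, seed=seed)
        for rep in range(replicates):
            md = mask(matrix, spec, rep)
            mmat = md.matrix

            by_locus: Dict[int, List[Tuple[int, int]]] = {}
            for i, j, g in md.truth:
                by_locus.setdefault(i, []).append((j, g))

            base_dec: Dict[Tuple[int, int], ImputeDecision] = {}
            if "baseline" in methods:
                for i, targets in by_locus.items():
                    for j, _ in targets:
                        base_dec[(i, j)] = baseline_impute(mmat, i, j)

            for d_idx, delta in enumerate(grid):
                decisions: Dict[str, Dict[Tuple[int, int], ImputeDecision]] = {
                    m: {} for m in methods
                }
                for i, targets in by_locus.items():
                    window = covering_window(gmap, i, delta, warn=False)
                    if window.size == 0:
                        # windowless: excluded from statistics for all methods
                        for j, _ in targets:
                            for m in methods:
                                decisions[m][(i, j)] = EXCLUDED
                        continue
                    weights = (
                        locus_weights(gmap, window) if "wnn" in methods else None
                    )
                    for j, _ in targets:
                        for m in methods:
                            if m == "baseline":
                                dec = base_dec[(i, j)]
                            elif m == "nn":
                                dec = nn_impute(mmat, gmap, i, j, delta, window=window)
                            elif m == "wnn":
                                dec = wnn_impute(
                                    mmat, gmap, i, j, delta,
                                    window=window, weights=weights,
                                )
                            elif m == "mc":
                                dec = mc_impute(mmat, gmap, i, j, delta, window=window)
                            elif m == "svm":
                                dec = svm_impute(
                                    mmat, gmap, i, j, delta, svm_cfg, window=window
                                )
                            else:  # neuralnet
                                rng = np.random.default_rng(
                                    (seed, 9001, rep, d_idx, i, j)
                                )
                                dec = neuralnet_impute(
                                    mmat, gmap, i, j, delta, nn_cfg,
                                    window=window, rng=rng,
                                )
                            decisions[m][(i, j)] = dec

                for m in methods:
                    res = evaluate(md, decisions[m])
                    rows.append(
                        {
                            "method": m,
                            "rate": rate,
                            "delta_cM": delta,
                            "replicate": rep,
                            "n_masked": len(md.truth),
                            "imputed": res.imputed,
                            "excluded": res.excluded,
                            "correct": res.correct,
                            "accuracy": res.accuracy,
                        }
                    )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per (method, rate) over all replicate x threshold cells.

    Cells where every entry was excluded have undefined accuracy and are
    dropped from the mean with a logged warning.
    """
    na = results["accuracy"].isna()
    if na.any():
        logger.warning(
            "%d all-excluded cells dropped from summary means", int(na.sum())
        )
    out = (
        results.dropna(subset=["accuracy"])
        .groupby(["method", "rate"], as_index=False)
        .agg(
            mean_accuracy=("accuracy", "mean"),
            cells=("accuracy", "size"),
            total_imputed=("imputed", "sum"),
            total_excluded=("excluded", "sum"),
        )
    )
    return out
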