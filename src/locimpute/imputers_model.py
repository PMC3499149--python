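"""Model-based local imputers: Markov chains, SVM, and a neural network.

All three treat imputation of one missing entry as a 3-class classification
problem over the target's covering window:

* ``mc_impute`` — two first-order Markov chains, one running downstream from
  locus ``i-L`` to ``i`` and one upstream from ``i+R`` to ``i``, fitted with
  add-one smoothing; the product of the two chain probabilities scores each
  candidate genotype.
* ``svm_impute`` — a soft-margin SVM with RBF kernel on the orthogonal
  window encoding (one-vs-one multi-class), with ``(c, gamma)`` picked once
  per dataset by 10-fold cross-validation over a grid.
* ``neuralnet_impute`` — a three-layer feed-forward network (3(L+R) inputs,
  L+R logistic hidden units, 3 softmax outputs) trained by batch gradient
  descent with momentum on cross-entropy for exactly 20 epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .genetic_map import GeneticMap
from .genotype_model import MISSING, GenotypeMatrix
from .imputers_core import EXCLUDED, ImputeDecision, _training_samples
from .locality import Window, covering_window, encode_orthogonal

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# First-order Markov chains
# ---------------------------------------------------------------------------

@dataclass
class LocalMarkovChain:
    """A first-order genotype chain over one side of a covering window.

    ``loci`` lists the chain's loci in running order, ending at the target
    locus.  ``initial`` is the add-one-smoothed genotype distribution at the
    first locus; ``transitions[k]`` is the row-stochastic 3x3 matrix
    P(X at loci[k+1] | X at loci[k]).  Smoothing keeps every probability
    strictly positive.
    """

    direction: str  # "upstream" or "downstream"
    loci: Tuple[int, ...]
    initial: np.ndarray
    transitions: List[np.ndarray] = field(default_factory=list)


def _smoothed_frequencies(
    matrix: GenotypeMatrix, locus: int, train: np.ndarray
) -> np.ndarray:
    """Add-one-smoothed genotype frequencies at a locus: (c_g + 1)/(N + 3)."""
    vals = matrix.values[locus, train]
    vals = vals[vals != MISSING]
    counts = np.bincount(vals, minlength=3).astype(np.float64)
    return (counts + 1.0) / (len(vals) + 3.0)


def mc_fit(
    matrix: GenotypeMatrix,
    window: Window,
    direction: str,
    train: Sequence[int],
) -> LocalMarkovChain:
    """Fit one side's chain from the training samples.

    The upstream chain runs ``i-L, ..., i-1, i``; the downstream chain runs
    ``i+R, ..., i+1, i`` — both toward the target locus.  Transition rows use
    add-one smoothing over sample rows where both adjacent genotypes are
    known: P(b | a) = (count(a->b) + 1) / (count(a->.) + 3).
    """
    train = np.asarray(train)
    if direction == "upstream":
        if not window.left:
            raise ValueError("upstream chain requires L >= 1")
        loci = (*window.left, window.target_locus)
    elif direction == "downstream":
        if not window.right:
            raise ValueError("downstream chain requires R >= 1")
        loci = (*reversed(window.right), window.target_locus)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    initial = _smoothed_frequencies(matrix, loci[0], train)
    transitions: List[np.ndarray] = []
    for a_locus, b_locus in zip(loci, loci[1:]):
        a = matrix.values[a_locus, train]
        b = matrix.values[b_locus, train]
        ok = (a != MISSING) & (b != MISSING)
        counts = np.zeros((3, 3), dtype=np.float64)
        np.add.at(counts, (a[ok], b[ok]), 1.0)
        transitions.append(
            (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 3.0)
        )
    return LocalMarkovChain(
        direction=direction, loci=loci, initial=initial, transitions=transitions
    )


def _chain_probability(
    chain: LocalMarkovChain,
    matrix: GenotypeMatrix,
    j: int,
    train: np.ndarray,
) -> np.ndarray:
    """Forward sum of the chain for the target sample, per candidate genotype.

    Known target genotypes inside the window pin the chain state; missing
    ones are marginalised, each candidate value weighted by its smoothed
    training frequency at that locus.  The returned vector is indexed by the
    candidate genotype at the target locus (the chain's last locus), which
    carries no frequency weight of its own.
    """
    def obs_weight(locus: int) -> np.ndarray:
        g = matrix.values[locus, j]
        if g == MISSING:
            return _smoothed_frequencies(matrix, locus, train)
        w = np.zeros(3)
        w[g] = 1.0
        return w

    f = chain.initial * obs_weight(chain.loci[0])
    for step, next_locus in enumerate(chain.loci[1:]):
        f = f @ chain.transitions[step]
        if next_locus != chain.loci[-1]:  # target locus carries no weight
            f = f * obs_weight(next_locus)
    return f


def mc_likelihood(
    matrix: GenotypeMatrix,
    window: Window,
    j: int,
    train: Sequence[int],
) -> np.ndarray:
    """Per-candidate likelihood: upstream x downstream chain probability.

    A side with no loci contributes the smoothed marginal genotype
    frequency at the target locus instead of a chain.
    """
    train = np.asarray(train)
    marginal = _smoothed_frequencies(matrix, window.target_locus, train)
    if window.left:
        up = _chain_probability(
            mc_fit(matrix, window, "upstream", train), matrix, j, train
        )
    else:
        up = marginal
    if window.right:
        down = _chain_probability(
            mc_fit(matrix, window, "downstream", train), matrix, j, train
        )
    else:
        down = marginal
    return up * down


def mc_impute(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    i: int,
    j: int,
    delta_cM: float,
    *,
    window: Optional[Window] = None,
) -> ImputeDecision:
    """Dual-chain Markov imputation of the missing entry ``(i, j)``.

    The highest-likelihood genotype wins, ties resolving to the lowest
    code.
    """
    if window is None:
        window = covering_window(gmap, i, delta_cM, warn=False)
    if window.size == 0:
        return EXCLUDED
    train = _training_samples(matrix, i, j)
    if len(train) == 0:
        return EXCLUDED
    likelihood = mc_likelihood(matrix, window, j, train)
    value = int(np.argmax(likelihood))  # argmax takes the lowest code on ties
    return ImputeDecision(value=value, support=len(train), tiers_used=1)


# ---------------------------------------------------------------------------
# Support vector machine
# ---------------------------------------------------------------------------

def _pow2_grid(lo: int, hi: int, step: int = 2) -> Tuple[float, ...]:
    return tuple(float(2.0 ** e) for e in range(lo, hi + 1, step))


@dataclass
class SvmConfig:
    """RBF-SVM settings: the cross-validation grid and the chosen point.

    ``c`` and ``gamma`` are filled by :func:`calibrate_svm` (once per
    dataset); left unset, LIBSVM-style defaults are used (c = 1,
    gamma = 1 / n_features).
    """

    c_grid: Tuple[float, ...] = _pow2_grid(-5, 15)
    gamma_grid: Tuple[float, ...] = _pow2_grid(-15, 3)
    folds: int = 10
    calibration_loci: int = 20
    c: Optional[float] = None
    gamma: Optional[float] = None


def _cv_accuracy(X: np.ndarray, y: np.ndarray, c: float, gamma: float,
                 folds: int) -> float:
    """Mean cross-validated accuracy of an RBF SVC on one window panel."""
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or len(y) < 2:
        return np.nan
    n_splits = min(folds, int(class_counts.min()))
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits)
    else:
        cv = KFold(n_splits=min(folds, len(y)))
    clf = SVC(C=c, gamma=gamma, kernel="rbf")
    return float(np.mean(cross_val_score(clf, X, y, cv=cv)))


def calibrate_svm(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    delta_cM: float,
    config: SvmConfig,
    rng: np.random.Generator,
) -> SvmConfig:
    """Pick one shared ``(c, gamma)`` for a dataset by grid-searched CV.

    ``config.calibration_loci`` target loci are sampled at random among
    those with a non-empty window and at least two genotype classes; each
    grid point is scored by mean 10-fold cross-validation accuracy over the
    sampled window panels, and the best point (first in grid order on ties)
    is written back into a new config.
    """
    candidates = []
    for i in rng.permutation(matrix.n_loci):
        window = covering_window(gmap, int(i), delta_cM, warn=False)
        if window.size == 0:
            continue
        known = np.flatnonzero(matrix.values[i] != MISSING)
        y = matrix.values[i, known]
        if len(np.unique(y)) < 2:
            continue
        X = encode_orthogonal(matrix, window).vectors[known].astype(np.float64)
        candidates.append((X, y))
        if len(candidates) >= config.calibration_loci:
            break
    if not candidates:
        logger.warning("no calibratable loci; keeping SVM defaults")
        return config

    best = (-np.inf, config.c_grid[0], config.gamma_grid[0])
    for c in config.c_grid:
        for gamma in config.gamma_grid:
            accs = [
                _cv_accuracy(X, y, c, gamma, config.folds)
                for X, y in candidates
            ]
            score = float(np.nanmean(accs))
            if score > best[0]:
                best = (score, c, gamma)
    logger.info(
        "SVM calibration: c=%g gamma=%g (CV accuracy %.4f over %d windows)",
        best[1], best[2], best[0], len(candidates),
    )
    return SvmConfig(
        c_grid=config.c_grid,
        gamma_grid=config.gamma_grid,
        folds=config.folds,
        calibration_loci=config.calibration_loci,
        c=best[1],
        gamma=best[2],
    )


def svm_impute(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    i: int,
    j: int,
    delta_cM: float,
    config: Optional[SvmConfig] = None,
    *,
    window: Optional[Window] = None,
) -> ImputeDecision:
    """RBF-SVM imputation of the missing entry ``(i, j)``.

    With fewer than two classes among the training labels the decision
    falls back to the (single-class) majority vote.
    """
    config = config or SvmConfig()
    if window is None:
        window = covering_window(gmap, i, delta_cM, warn=False)
    if window.size == 0:
        return EXCLUDED
    train = _training_samples(matrix, i, j)
    if len(train) == 0:
        return EXCLUDED
    y = matrix.values[i, train]
    classes = np.unique(y)
    if len(classes) < 2:
        return ImputeDecision(value=int(classes[0]), support=len(train))

    panel = encode_orthogonal(matrix, window)
    X = panel.vectors[train].astype(np.float64)
    c = config.c if config.c is not None else 1.0
    gamma = config.gamma if config.gamma is not None else 1.0 / X.shape[1]
    clf = SVC(C=c, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
    clf.fit(X, y)
    pred = int(clf.predict(panel.vectors[[j]].astype(np.float64))[0])
    return ImputeDecision(value=pred, support=len(train))


# ---------------------------------------------------------------------------
# Feed-forward neural network
# ---------------------------------------------------------------------------

@dataclass
class NeuralNetConfig:
    """Three-layer network hyper-parameters.

    The hidden layer has L+R logistic units (one per in-window locus) unless
    overridden; training is batch gradient descent with momentum for exactly
    20 epochs, from weights drawn uniformly in (-0.1, 0.1).
    """

    hidden_units: Optional[int] = None  # None -> L + R
    epochs: int = 20
    learning_rate: float = 0.1
    momentum: float = 0.5
    seed: int = 0


def _softmax(t: np.ndarray) -> np.ndarray:
    t = t - t.max(axis=1, keepdims=True)
    e = np.exp(t)
    return e / e.sum(axis=1, keepdims=True)


class FeedForwardNet:
    """3(L+R) inputs -> L+R logistic hidden units -> 3 softmax outputs.

    Exposes ``loss`` and ``gradients`` separately so the analytic gradient
    can be verified against finite differences.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.A = rng.uniform(-0.1, 0.1, size=(n_hidden, n_in))
        self.a0 = rng.uniform(-0.1, 0.1, size=n_hidden)
        self.B = rng.uniform(-0.1, 0.1, size=(3, n_hidden))
        self.b0 = rng.uniform(-0.1, 0.1, size=3)

    def _forward(self, X: np.ndarray):
        H = X @ self.A.T + self.a0
        Z = 1.0 / (1.0 + np.exp(-H))
        T = Z @ self.B.T + self.b0
        return Z, T

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, T = self._forward(X)
        return _softmax(T)

    def loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        """Cross-entropy between softmax outputs and one-hot labels."""
        P = self.predict_proba(X)
        return float(-(Y * np.log(P)).sum())

    def gradients(self, X: np.ndarray, Y: np.ndarray) -> dict:
        Z, T = self._forward(X)
        P = _softmax(T)
        dT = P - Y
        dZ = dT @ self.B
        dH = dZ * Z * (1.0 - Z)
        return {
            "B": dT.T @ Z,
            "b0": dT.sum(axis=0),
            "A": dH.T @ X,
            "a0": dH.sum(axis=0),
        }

    def train(
        self, X: np.ndarray, Y: np.ndarray, epochs: int, lr: float, mu: float
    ) -> np.ndarray:
        """Batch gradient descent with momentum; returns the per-epoch loss."""
        velocity = {k: np.zeros_like(getattr(self, k)) for k in ("A", "a0", "B", "b0")}
        losses = np.empty(epochs)
        for epoch in range(epochs):
            grads = self.gradients(X, Y)
            for k, g in grads.items():
                velocity[k] = mu * velocity[k] - lr * g
                setattr(self, k, getattr(self, k) + velocity[k])
            losses[epoch] = self.loss(X, Y)
        return losses


def neuralnet_impute(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    i: int,
    j: int,
    delta_cM: float,
    config: Optional[NeuralNetConfig] = None,
    *,
    window: Optional[Window] = None,
    rng: Optional[np.random.Generator] = None,
) -> ImputeDecision:
    """Neural-network imputation of the missing entry ``(i, j)``.

    ``rng`` (or ``config.seed``) fixes the weight initialisation, making
    predictions reproducible.  The predicted class is the largest softmax
    output, ties resolving to the lowest code.
    """
    config = config or NeuralNetConfig()
    if window is None:
        window = covering_window(gmap, i, delta_cM, warn=False)
    if window.size == 0:
        return EXCLUDED
    train = _training_samples(matrix, i, j)
    if len(train) == 0:
        return EXCLUDED

    panel = encode_orthogonal(matrix, window)
    X = panel.vectors[train].astype(np.float64)
    Y = np.eye(3)[matrix.values[i, train]]
    hidden = config.hidden_units if config.hidden_units is not None else window.size
    if rng is None:
        rng = np.random.default_rng(config.seed)
    net = FeedForwardNet(X.shape[1], hidden, rng)
    net.train(X, Y, config.epochs, config.learning_rate, config.momentum)
    proba = net.predict_proba(panel.vectors[[j]].astype(np.float64))[0]
    return ImputeDecision(value=int(np.argmax(proba)), support=len(train))
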