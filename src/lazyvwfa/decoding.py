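"""Linear decoding of stimulus location from input or hidden patterns.

This is the model analogue of multivoxel pattern analysis: activation
patterns evoked by words at 6 eccentric probe locations per axis (the
central position is excluded) are collected, degraded with Gaussian noise
(the stand-in for measurement noise), and fed to a linear perceptron that
learns, by the delta rule, to classify them into L = 2 location categories
(left/right or up/down) or the L = 6 individual locations.  Generalization
accuracy on held-out patterns measures how much location information the
layer retains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .encoding import DEFAULT_GRID, GridSpec, encode
from .lexicon import Lexicon
from .metrics import AdjacencyReport, adjacency_report
from .mlp import Network, forward_batch_active

try:  # optional compiled inner loop; pure-numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

AXES = ("horizontal", "vertical")
LAYERS = ("input", "hidden")
PROBE_OFFSETS = (1, 2, 3, 5, 6, 7)  # probed coordinate values; centre 4 excluded


@dataclass(frozen=True)
class ClassifierConfig:
    """Perceptron and sampling parameters of one decoding battery.

    ``noise_sd`` is the amplitude (standard deviation) of the Gaussian
    measurement noise added to every pattern element.  ``epochs`` and
    ``init_range`` default to values at which the delta rule has reached
    its asymptotic generalization accuracy (see docs/methods.md); the
    learning rate is deliberately small, so undertraining — not
    overfitting — is the failure mode to guard against.
    """

    lr: float = 1e-4
    epochs: int = 2000
    init_range: float = 0.01
    noise_mean: float = 0.0
    noise_sd: float = 0.025
    n_runs: int = 10
    n_words: int = 40


def probe_locations(axis: str, spec: GridSpec = DEFAULT_GRID) -> list[tuple[int, int]]:
    """The 6 probed placements on one axis, ordered by coordinate."""
    cx, cy = spec.center
    if axis == "horizontal":
        return [(x, cy) for x in PROBE_OFFSETS]
    if axis == "vertical":
        return [(cx, y) for y in PROBE_OFFSETS]
    raise ValueError(f"unknown axis {axis!r}")


def class_of(location: tuple[int, int], axis: str, n_classes: int) -> int:
    """Class index (0-based) of a probe location.

    L=6 maps the ordered probe positions to 0..5; L=2 groups the first
    three (left/up) as 0 and the last three (right/down) as 1.
    """
    c = location[0] if axis == "horizontal" else location[1]
    if c not in PROBE_OFFSETS:
        raise ValueError(f"{location} is not a probe location on axis {axis}")
    k = PROBE_OFFSETS.index(c)
    if n_classes == 6:
        return k
    if n_classes == 2:
        return 0 if k < 3 else 1
    raise ValueError("n_classes must be 2 or 6")


@dataclass(frozen=True)
class PatternSet:
    """Labelled activation vectors collected for decoding."""

    X: np.ndarray  # (n, d) patterns
    words: tuple[str, ...]
    locations: np.ndarray  # (n, 2) placements
    axis: str
    layer: str

    def __len__(self) -> int:
        return self.X.shape[0]

    def classes(self, n_classes: int) -> np.ndarray:
        return np.array(
            [class_of(tuple(loc), self.axis, n_classes) for loc in self.locations],
            dtype=np.int64,
        )

    def subset(self, idx: np.ndarray) -> "PatternSet":
        return replace(
            self,
            X=self.X[idx],
            words=tuple(self.words[i] for i in idx),
            locations=self.locations[idx],
        )


def collect_patterns(
    net: Network,
    words,
    axis: str,
    layer: str,
    spec: GridSpec = DEFAULT_GRID,
) -> PatternSet:
    """Record one pattern per (word, probe location).

    ``layer='input'`` records the raw binary encoding; ``layer='hidden'``
    the 50-unit sigmoid activations produced by the network.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    locs = probe_locations(axis, spec)
    pairs = [(w, loc) for w in words for loc in locs]
    active = np.array(
        [encode(w, x, y, spec).active for w, (x, y) in pairs], dtype=np.int64
    )
    if layer == "input":
        X = np.zeros((len(pairs), spec.input_dim))
        np.put_along_axis(X, active, 1.0, axis=1)
    else:
        X, _ = forward_batch_active(net, active)
    return PatternSet(
        X=X,
        words=tuple(w for w, _ in pairs),
        locations=np.array([loc for _, loc in pairs]),
        axis=axis,
        layer=layer,
    )


def add_noise(
    ps: PatternSet, sd: float, rng: np.random.Generator, mean: float = 0.0
) -> PatternSet:
    """Element-wise i.i.d. Gaussian noise (fresh draw per pattern element)."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    if sd == 0 and mean == 0:
        return ps
    noise = rng.normal(mean, sd, size=ps.X.shape)
    return replace(ps, X=ps.X + noise)


def split_train_test(
    ps: PatternSet, n_classes: int, rng: np.random.Generator
) -> tuple[PatternSet, PatternSet]:
    """Hold out 6*L patterns, stratified equally over the L classes."""
    classes = ps.classes(n_classes)
    per_class = 6 * n_classes // n_classes  # 6 held-out items per class
    test_idx: list[int] = []
    for c in range(n_classes):
        members = np.flatnonzero(classes == c)
        if len(members) < per_class:
            raise ValueError(
                f"class {c} has {len(members)} patterns; need {per_class}"
            )
        test_idx.extend(rng.choice(members, size=per_class, replace=False))
    test_idx = np.sort(np.array(test_idx))
    train_idx = np.setdiff1d(np.arange(len(ps)), test_idx)
    if train_idx.size == 0:
        raise ValueError("holdout would leave no training patterns")
    return ps.subset(train_idx), ps.subset(test_idx)


def _delta_core_py(W, X, T, orders, lr):
    n_epochs, n = orders.shape
    L = W.shape[0]
    for e in range(n_epochs):
        for k in range(n):
            i = orders[e, k]
            x = X[i]
            err = T[i] - W @ x
            for l in range(L):
                W[l] += lr * err[l] * x
    return W


if _HAVE_NUMBA:
    _delta_core = njit(cache=False)(_delta_core_py)
else:  # pragma: no cover
    _delta_core = _delta_core_py


def train_perceptron(
    train: PatternSet,
    n_classes: int,
    cfg: ClassifierConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Delta-rule training of the linear location classifier.

    Weights (L, d) start uniform on [-init_range, init_range]; each of the
    ``cfg.epochs`` epochs presents every training pattern once in fresh
    random order and applies the online update dW = lr * (t - y) x^T with
    localist 0/1 targets and linear outputs.  Returns the weight matrix.
    """
    classes = train.classes(n_classes)
    n, d = train.X.shape
    W = rng.uniform(-cfg.init_range, cfg.init_range, size=(n_classes, d))
    T = np.zeros((n, n_classes))
    T[np.arange(n), classes] = 1.0
    orders = np.empty((cfg.epochs, n), dtype=np.int64)
    for e in range(cfg.epochs):
        orders[e] = rng.permutation(n)
    X = np.ascontiguousarray(train.X)
    return _delta_core(W, X, T, orders, cfg.lr)


def evaluate(
    W: np.ndarray, test: PatternSet, n_classes: int
) -> tuple[float, np.ndarray]:
    """Generalization accuracy and confusion counts on held-out patterns.

    Predictions are argmax of the linear outputs, ties to the lowest class
    index.  The confusion matrix has rows = true class, columns = guess.
    """
    classes = test.classes(n_classes)
    preds = np.argmax(test.X @ W.T, axis=1)
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (classes, preds), 1)
    return float(np.mean(preds == classes)), cm


@dataclass(frozen=True)
class DecodingResult:
    """Aggregated decoding performance for one condition.

    ``accuracies`` holds one generalization accuracy per run; ``confusion``
    sums the held-out confusion counts over runs.
    """

    axis: str
    layer: str
    n_classes: int
    accuracies: np.ndarray
    confusion: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sem_accuracy(self) -> float:
        n = len(self.accuracies)
        if n < 2:
            return float("nan")
        return float(np.std(self.accuracies, ddof=1) / np.sqrt(n))

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes

    @property
    def report(self) -> AdjacencyReport:
        return adjacency_report(self.confusion)

    def summary(self) -> pd.DataFrame:
        rep = self.report
        return pd.DataFrame(
            {
                "axis": [self.axis],
                "layer": [self.layer],
                "n_classes": [self.n_classes],
                "mean_accuracy": [self.mean_accuracy],
                "sem_accuracy": [self.sem_accuracy],
                "chance": [self.chance],
                "adjacent_pct": [rep.adjacent_pct],
                "adjacency_index": [rep.ai],
            }
        )


def run_decoding(
    net: Network,
    lexicon: Lexicon,
    axis: str,
    layer: str,
    n_classes: int,
    cfg: ClassifierConfig = ClassifierConfig(),
    seed: int | np.random.Generator = 0,
    words=None,
    spec: GridSpec = DEFAULT_GRID,
) -> DecodingResult:
    """Full decoding battery for one (axis, layer, L) condition.

    Each of ``cfg.n_runs`` runs independently resamples the probed words,
    the measurement noise, the stratified train/test split and the
    classifier's initial weights.  ``words`` restricts the sampling pool
    (e.g. to anagram items only); by default all lexicon words are used.
    Untrained networks are accepted (used to probe pre-learning layers).
    """
    rng = np.random.default_rng(seed)
    pool = list(words) if words is not None else list(lexicon.words)
    n_words = min(cfg.n_words, len(pool))
    accs = np.empty(cfg.n_runs)
    cm_total = np.zeros((n_classes, n_classes), dtype=np.int64)
    for r in range(cfg.n_runs):
        chosen = [pool[i] for i in rng.choice(len(pool), size=n_words, replace=False)]
        ps = collect_patterns(net, chosen, axis, layer, spec)
        ps = add_noise(ps, cfg.noise_sd, rng, cfg.noise_mean)
        train, test = split_train_test(ps, n_classes, rng)
        W = train_perceptron(train, n_classes, cfg, rng)
        accs[r], cm = evaluate(W, test, n_classes)
        cm_total += cm
    return DecodingResult(
        axis=axis,
        layer=layer,
        n_classes=n_classes,
        accuracies=accs,
        confusion=cm_total,
    )
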