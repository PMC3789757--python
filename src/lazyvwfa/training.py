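"""Stochastic-location training of the word-recognition network.

Each word is assigned a grid location drawn from a rounded, truncated 2-D
Gaussian centred on the middle of the placement grid (4, 4) with a larger
horizontal (sigma = 2.5) than vertical (sigma = 1.5) spread, mimicking the
distribution of eye fixations while reading.  Locations are redrawn every 5
epochs.  One epoch presents every word exactly once, in random order.
Training stops when the network recognises every word presented at the
central location ("the network reads perfectly at fixation").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import DEFAULT_GRID, GridSpec, encode
from .lexicon import Lexicon
from .mlp import Network, backprop_step, forward_batch_active, init_network, one_hot


@dataclass(frozen=True)
class RegimeConfig:
    """Training-regime parameters (grid units, epochs)."""

    sigma_x: float = 2.5
    sigma_y: float = 1.5
    center: tuple[int, int] = (4, 4)
    relocation_period: int = 5
    lr: float = 2.0
    max_epochs: int = 20000
    n_milestones: int = 20
    criterion: str = "center"  # or "radius1": centre plus 4-neighbours

    def __post_init__(self) -> None:
        if not (self.sigma_x > self.sigma_y > 0):
            raise ValueError("need sigma_x > sigma_y > 0")
        if self.criterion not in ("center", "radius1"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


class ConvergenceError(RuntimeError):
    """Training hit ``max_epochs`` before reaching criterion.

    Carries the partial :class:`TrainingTrace` as ``.trace``.
    """

    def __init__(self, message: str, trace: "TrainingTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass
class TrainingTrace:
    """Bookkeeping of one training run.

    ``exposure[x-1, y-1]`` counts word presentations at placement (x, y) and
    sums to ``epochs_to_criterion * len(lexicon)``.
    """

    network: Network
    epochs_to_criterion: int
    exposure: np.ndarray  # (7, 7) int counts
    mean_sse: list[float] = field(default_factory=list)
    central_accuracy: list[float] = field(default_factory=list)
    snapshots: list[tuple[int, Network]] = field(default_factory=list)

    def save(self, out_dir, stem: str = "training") -> None:
        """Persist the trace: per-epoch curve CSV, exposure-map CSV, and
        the final network checkpoint (``<stem>.npz`` + ``<stem>.json``)."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"{stem}_trace.csv", "w", newline="\n") as fh:
            fh.write("epoch,mean_sse,central_accuracy\n")
            for e, (sse, acc) in enumerate(
                zip(self.mean_sse, self.central_accuracy), start=1
            ):
                fh.write(f"{e},{sse:.6f},{acc:.4f}\n")
        with open(out / f"{stem}_exposure.csv", "w", newline="\n") as fh:
            for row in self.exposure:
                fh.write(",".join(str(int(c)) for c in row) + "\n")
        self.network.save(
            out / stem, epochs_to_criterion=self.epochs_to_criterion
        )

    def milestones(self, n: int | None = None) -> list[tuple[int, Network]]:
        """``n`` snapshots at (approximately) evenly spaced epochs.

        Snapshots are retained on a thinned epoch grid during training; the
        requested milestones (epoch 0 through the final epoch inclusive) are
        mapped to the nearest retained epoch.
        """
        if not self.snapshots:
            raise ValueError("training was run without store_snapshots")
        n = n or 20
        total = self.epochs_to_criterion
        epochs = np.array([e for e, _ in self.snapshots])
        out: list[tuple[int, Network]] = []
        for j in range(n):
            want = round(j * total / (n - 1)) if n > 1 else 0
            k = int(np.argmin(np.abs(epochs - want)))
            out.append(self.snapshots[k])
        return out


def sample_location(
    cfg: RegimeConfig, rng: np.random.Generator, spec: GridSpec = DEFAULT_GRID
) -> tuple[int, int]:
    """Draw one placement: rounded 2-D normal, rejected until on the grid."""
    n = spec.n_positions
    cx, cy = cfg.center
    while True:
        x = int(np.rint(rng.normal(cx, cfg.sigma_x)))
        y = int(np.rint(rng.normal(cy, cfg.sigma_y)))
        if 1 <= x <= n and 1 <= y <= n:
            return x, y


def _center_active(lexicon: Lexicon, spec: GridSpec, cfg: RegimeConfig) -> np.ndarray:
    cx, cy = cfg.center
    return np.array(
        [encode(w, cx, cy, spec).active for w in lexicon.words], dtype=np.int64
    )


def _criterion_placements(cfg: RegimeConfig, spec: GridSpec) -> list[tuple[int, int]]:
    cx, cy = cfg.center
    if cfg.criterion == "center":
        return [(cx, cy)]
    n = spec.n_positions
    cells = [(cx, cy), (cx - 1, cy), (cx + 1, cy), (cx, cy - 1), (cx, cy + 1)]
    return [(x, y) for x, y in cells if 1 <= x <= n and 1 <= y <= n]


def recognition_accuracy(
    net: Network, lexicon: Lexicon, x: int, y: int, spec: GridSpec = DEFAULT_GRID
) -> float:
    """Fraction of words whose output unit wins when presented at (x, y)."""
    active = np.array(
        [encode(w, x, y, spec).active for w in lexicon.words], dtype=np.int64
    )
    _, o = forward_batch_active(net, active)
    return float(np.mean(np.argmax(o, axis=1) == np.arange(len(lexicon))))


def converged(
    net: Network,
    lexicon: Lexicon,
    spec: GridSpec = DEFAULT_GRID,
    cfg: RegimeConfig = RegimeConfig(),
) -> bool:
    """True iff every word is recognised at every criterion placement."""
    return all(
        recognition_accuracy(net, lexicon, x, y, spec) == 1.0
        for x, y in _criterion_placements(cfg, spec)
    )


def run_epoch(
    net: Network,
    lexicon: Lexicon,
    placements: dict[str, tuple[int, int]],
    lr: float,
    rng: np.random.Generator | None = None,
    spec: GridSpec = DEFAULT_GRID,
) -> float:
    """Present every word once (shuffled) at its assigned placement.

    Returns the mean per-pattern squared error E = sum((t-o)^2)/2, measured
    before each update.  Updates ``net`` in place.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = len(lexicon)
    order = rng.permutation(n)
    total = 0.0
    words = lexicon.words
    for i in order:
        w = words[i]
        x, y = placements[w]
        total += backprop_step(net, encode(w, x, y, spec), one_hot(i, n), lr)
    return total / n


def train_to_criterion(
    lexicon: Lexicon,
    cfg: RegimeConfig = RegimeConfig(),
    seed: int | np.random.Generator = 0,
    spec: GridSpec = DEFAULT_GRID,
    store_snapshots: bool = False,
    net: Network | None = None,
) -> TrainingTrace:
    """Train a fresh network until criterion; fully seeded and deterministic.

    Word locations are redrawn every ``cfg.relocation_period`` epochs; the
    criterion is evaluated after every epoch.  When ``store_snapshots`` is
    on, weight copies are retained on an adaptively thinned epoch grid (the
    grid step doubles whenever more than 64 snapshots are held) from which
    :meth:`TrainingTrace.milestones` later selects evenly spaced epochs.
    """
    rng = np.random.default_rng(seed)
    if net is None:
        net = init_network(len(lexicon), rng, spec)
    n = len(lexicon)
    n_side = spec.n_positions
    exposure = np.zeros((n_side, n_side), dtype=np.int64)
    trace = TrainingTrace(network=net, epochs_to_criterion=0, exposure=exposure)

    snap_step = 1
    if store_snapshots:
        trace.snapshots.append((0, net.copy()))

    words = lexicon.words
    targets = np.eye(n)
    placements: dict[str, tuple[int, int]] = {}
    encoded: list = []

    for epoch in range(cfg.max_epochs):
        if epoch % cfg.relocation_period == 0:
            placements = {w: sample_location(cfg, rng, spec) for w in words}
            encoded = [encode(w, *placements[w], spec) for w in words]
        order = rng.permutation(n)
        total = 0.0
        for i in order:
            total += backprop_step(net, encoded[i], targets[i], cfg.lr)
        for w in words:
            x, y = placements[w]
            exposure[x - 1, y - 1] += 1
        trace.mean_sse.append(total / n)
        cx, cy = cfg.center
        acc = recognition_accuracy(net, lexicon, cx, cy, spec)
        trace.central_accuracy.append(acc)
        trace.epochs_to_criterion = epoch + 1
        done = converged(net, lexicon, spec, cfg) if (
            acc == 1.0 or cfg.criterion != "center"
        ) else False
        if store_snapshots:
            e = epoch + 1
            if e % snap_step == 0:
                trace.snapshots.append((e, net.copy()))
            if len(trace.snapshots) > 64:
                trace.snapshots = [
                    (ep, s) for ep, s in trace.snapshots if ep % (snap_step * 2) == 0
                ]
                snap_step *= 2
            if done and trace.snapshots[-1][0] != e:
                trace.snapshots.append((e, net.copy()))
        if done:
            return trace
    raise ConvergenceError(
        f"no convergence within {cfg.max_epochs} epochs", trace
    )


def accuracy_map(
    net: Network, lexicon: Lexicon, spec: GridSpec = DEFAULT_GRID
) -> np.ndarray:
    """Recognition accuracy at every placement; ``out[x-1, y-1]``."""
    n = spec.n_positions
    out = np.zeros((n, n))
    for x in range(1, n + 1):
        for y in range(1, n + 1):
            out[x - 1, y - 1] = recognition_accuracy(net, lexicon, x, y, spec)
    return out
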