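"""Three-layer feedforward word-recognition network.

1820 binary input units (location-specific letter banks) -> 50 sigmoid
hidden units -> N sigmoid output units, one per word (localist output
coding).  Trained online by backpropagation of the squared error
E = sum((t - o)^2) / 2.  Initial weights and biases are i.i.d. uniform on
[-0.5, 0.5].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoding import DEFAULT_GRID, GridSpec, StimulusEncoding

N_HIDDEN = 50
INIT_HALF_WIDTH = 0.5


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class Activations:
    hidden: np.ndarray  # (50,) in (0,1)
    output: np.ndarray  # (N,) in (0,1)


@dataclass
class Network:
    """Weights and biases; arrays are (out, in) shaped."""

    W_ih: np.ndarray  # (50, input_dim)
    b_h: np.ndarray  # (50,)
    W_ho: np.ndarray  # (N, 50)
    b_o: np.ndarray  # (N,)
    spec: GridSpec = DEFAULT_GRID

    @property
    def n_words(self) -> int:
        return self.W_ho.shape[0]

    def copy(self) -> "Network":
        return Network(
            self.W_ih.copy(), self.b_h.copy(), self.W_ho.copy(), self.b_o.copy(),
            self.spec,
        )

    # -- persistence ----------------------------------------------------
    def save(self, path, **metadata) -> None:
        """Write weights to ``<path>.npz`` and metadata to ``<path>.json``."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), W_ih=self.W_ih, b_h=self.b_h,
                 W_ho=self.W_ho, b_o=self.b_o)
        meta = {"n_words": self.n_words, "n_hidden": N_HIDDEN,
                "input_dim": self.spec.input_dim, **metadata}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path, spec: GridSpec = DEFAULT_GRID) -> "Network":
        arrays = np.load(Path(path).with_suffix(".npz"))
        return cls(arrays["W_ih"], arrays["b_h"], arrays["W_ho"], arrays["b_o"], spec)


def init_network(
    n_words: int, seed: int | np.random.Generator = 0, spec: GridSpec = DEFAULT_GRID
) -> Network:
    """Fresh network with all weights/biases uniform on [-0.5, 0.5]."""
    if n_words < 1:
        raise ValueError("need at least one output word unit")
    rng = np.random.default_rng(seed)
    u = lambda *shape: rng.uniform(-INIT_HALF_WIDTH, INIT_HALF_WIDTH, size=shape)
    return Network(
        W_ih=u(N_HIDDEN, spec.input_dim),
        b_h=u(N_HIDDEN),
        W_ho=u(n_words, N_HIDDEN),
        b_o=u(n_words),
        spec=spec,
    )


def _forward_active(net: Network, active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = sigmoid(net.W_ih[:, active].sum(axis=1) + net.b_h)
    o = sigmoid(net.W_ho @ h + net.b_o)
    return h, o


def forward(net: Network, stim: StimulusEncoding) -> Activations:
    """Propagate one stimulus; returns hidden and output activations."""
    h, o = _forward_active(net, np.asarray(stim.active))
    return Activations(hidden=h, output=o)


def one_hot(index: int, n: int) -> np.ndarray:
    t = np.zeros(n)
    t[index] = 1.0
    return t


def backprop_step(
    net: Network, stim: StimulusEncoding, target: np.ndarray, lr: float
) -> float:
    """One online gradient step on E = sum((t - o)^2)/2; returns pre-update E.

    Updates ``net`` in place.  The input is binary so only the four active
    columns of ``W_ih`` receive non-zero gradient.
    """
    active = np.asarray(stim.active)
    h, o = _forward_active(net, active)
    err = target - o
    sse = 0.5 * float(err @ err)
    delta_o = -err * o * (1.0 - o)  # dE/dnet_o
    delta_h = (net.W_ho.T @ delta_o) * h * (1.0 - h)
    net.W_ho -= lr * np.outer(delta_o, h)
    net.b_o -= lr * delta_o
    net.W_ih[:, active] -= lr * delta_h[:, None]
    net.b_h -= lr * delta_h
    return sse


def recognize(net: Network, stim: StimulusEncoding) -> int:
    """Index of the most active output unit (ties -> lowest index)."""
    _, o = _forward_active(net, np.asarray(stim.active))
    return int(np.argmax(o))


def forward_batch_active(net: Network, active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised forward pass over a batch of stimuli.

    ``active`` is an (n, 4) index array; returns hidden (n, 50) and output
    (n, N) activation matrices.
    """
    h = sigmoid(net.W_ih.T[active].sum(axis=1) + net.b_h)
    o = sigmoid(h @ net.W_ho.T + net.b_o)
    return h, o
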