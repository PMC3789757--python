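"""Retinotopic letter-bank encoding of a word at a grid location.

The input layer is a bank of localist letter detectors: 10 horizontal x 7
vertical letter slots x 26 letters = 1820 binary units.  A four-letter word
placed with its leftmost letter at grid coordinate (x, y), x and y in 1..7,
activates the four units coding its letters at horizontal slots x..x+3 of
vertical slot y.  Placements thus form a 7 x 7 grid while letter slots span
10 columns.

Unit indexing is slot-major then letter:
``index = ((h_slot - 1) * v_slots + (v_slot - 1)) * 26 + (letter - 'a')``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WORD_LEN = 4


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the input layer and of the placement grid."""

    h_slots: int = 10
    v_slots: int = 7
    alphabet_size: int = 26
    center: tuple[int, int] = (4, 4)

    @property
    def input_dim(self) -> int:
        return self.h_slots * self.v_slots * self.alphabet_size

    @property
    def n_positions(self) -> int:
        """Side length of the (square) grid of leftmost-letter placements."""
        return self.h_slots - WORD_LEN + 1

    def unit_index(self, h_slot: int, v_slot: int, letter: str) -> int:
        return ((h_slot - 1) * self.v_slots + (v_slot - 1)) * self.alphabet_size + (
            ord(letter) - ord("a")
        )

    def placements(self) -> list[tuple[int, int]]:
        n = self.n_positions
        return [(x, y) for x in range(1, n + 1) for y in range(1, n + 1)]


DEFAULT_GRID = GridSpec()


@dataclass(frozen=True)
class StimulusEncoding:
    """A word clamped onto the letter banks at one placement.

    ``active`` holds the four indices of the units set to 1; ``vector``
    materialises the full binary input vector on demand.
    """

    word: str
    x: int
    y: int
    active: tuple[int, int, int, int]
    spec: GridSpec = field(default=DEFAULT_GRID, repr=False)

    @property
    def vector(self) -> np.ndarray:
        v = np.zeros(self.spec.input_dim)
        v[list(self.active)] = 1.0
        return v


def encode(word: str, x: int, y: int, spec: GridSpec = DEFAULT_GRID) -> StimulusEncoding:
    """Encode ``word`` with its leftmost letter at placement ``(x, y)``."""
    if len(word) != WORD_LEN or not word.isascii() or not word.islower():
        raise ValueError(f"invalid word {word!r}")
    n = spec.n_positions
    if not (1 <= x <= n and 1 <= y <= n):
        raise ValueError(f"placement ({x},{y}) outside the {n}x{n} grid")
    active = tuple(
        spec.unit_index(x + k, y, word[k]) for k in range(WORD_LEN)
    )
    return StimulusEncoding(word=word, x=x, y=y, active=active, spec=spec)


def encode_active(word: str, x: int, y: int, spec: GridSpec = DEFAULT_GRID) -> np.ndarray:
    """Active unit indices only, as an int array (fast path for training)."""
    return np.array(encode(word, x, y, spec).active, dtype=np.int64)
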