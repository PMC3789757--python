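"""Model/Results facade over the simulation pipeline.

:class:`WordRecognitionModel` bundles a lexicon with a training regime the
way a statsmodels model bundles data with a specification; ``fit`` trains
the feedforward network to the central-location recognition criterion and
returns a :class:`WordRecognitionResults` carrying the trained network,
convergence diagnostics, exposure bookkeeping, and the decoding analyses
that hang off it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decoding import AXES, ClassifierConfig, DecodingResult, run_decoding
from .encoding import DEFAULT_GRID, GridSpec
from .lexicon import Lexicon, generate_lexicon, load_lexicon
from .training import (
    RegimeConfig,
    TrainingTrace,
    accuracy_map,
    train_to_criterion,
)


@dataclass
class WordRecognitionModel:
    """A vocabulary plus the stochastic-location training regime."""

    lexicon: Lexicon
    regime: RegimeConfig = field(default_factory=RegimeConfig)
    grid: GridSpec = DEFAULT_GRID

    @classmethod
    def from_word_list(cls, path, **kwargs) -> "WordRecognitionModel":
        """Build from a plain-text word list (one word per line)."""
        return cls(lexicon=load_lexicon(path), **kwargs)

    @classmethod
    def from_synthetic(
        cls,
        n_words: int = 100,
        n_anagram_words: int = 0,
        seed: int = 0,
        **kwargs,
    ) -> "WordRecognitionModel":
        """Build from a generated vocabulary (the study's default stimuli)."""
        return cls(
            lexicon=generate_lexicon(n_words, n_anagram_words, seed), **kwargs
        )

    def fit(
        self, seed: int | np.random.Generator = 0, store_snapshots: bool = False
    ) -> "WordRecognitionResults":
        """Train one network to criterion; deterministic given ``seed``."""
        trace = train_to_criterion(
            self.lexicon,
            self.regime,
            seed=seed,
            spec=self.grid,
            store_snapshots=store_snapshots,
        )
        return WordRecognitionResults(model=self, trace=trace)


@dataclass
class WordRecognitionResults:
    """A trained network with its training trace and analyses."""

    model: WordRecognitionModel
    trace: TrainingTrace

    @property
    def network(self):
        return self.trace.network

    @property
    def epochs_to_criterion(self) -> int:
        return self.trace.epochs_to_criterion

    @property
    def exposure(self) -> np.ndarray:
        """7x7 presentation counts, ``exposure[x-1, y-1]``."""
        return self.trace.exposure

    def accuracy_map(self) -> np.ndarray:
        """Recognition accuracy at every placement (7x7)."""
        return accuracy_map(self.network, self.model.lexicon, self.model.grid)

    def decode(
        self,
        axis: str,
        layer: str,
        n_classes: int,
        cfg: ClassifierConfig = ClassifierConfig(),
        seed: int | np.random.Generator = 0,
        words=None,
    ) -> DecodingResult:
        """Location-decoding battery on this network (see ``run_decoding``)."""
        return run_decoding(
            self.network,
            self.model.lexicon,
            axis,
            layer,
            n_classes,
            cfg,
            seed=seed,
            words=words,
            spec=self.model.grid,
        )

    def decoding_table(
        self,
        layers=("input", "hidden"),
        n_classes=(2, 6),
        cfg: ClassifierConfig = ClassifierConfig(),
        seed: int = 0,
    ) -> pd.DataFrame:
        """All (layer, axis, L) decoding conditions as one tidy frame."""
        rows = []
        ss = np.random.SeedSequence(_as_seed(seed))
        children = iter(ss.spawn(len(layers) * len(AXES) * len(n_classes)))
        for layer in layers:
            for axis in AXES:
                for L in n_classes:
                    res = self.decode(
                        axis, layer, L, cfg, seed=np.random.default_rng(next(children))
                    )
                    rows.append(res.summary())
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        amap = self.accuracy_map()
        cx, cy = self.model.grid.center
        return pd.DataFrame(
            {
                "n_words": [len(self.model.lexicon)],
                "epochs_to_criterion": [self.epochs_to_criterion],
                "final_mean_sse": [self.trace.mean_sse[-1]],
                "central_accuracy": [amap[cx - 1, cy - 1]],
                "mean_accuracy_all_locations": [amap.mean()],
                "total_exposures": [int(self.exposure.sum())],
            }
        )

    def save(self, path, **metadata) -> None:
        path = Path(path)
        self.network.save(
            path, epochs_to_criterion=self.epochs_to_criterion, **metadata
        )


def _as_seed(seed) -> int:
    return int(seed) if not isinstance(seed, np.random.SeedSequence) else seed
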