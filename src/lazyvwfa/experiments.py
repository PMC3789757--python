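"""The four simulation experiments, end to end.

Each experiment trains freshly initialised networks under a master seed and
runs the location-decoding batteries of interest, returning tidy data
frames (and optionally writing them, plus confusion matrices, as CSV).
Every random draw — lexicon, weight init, word locations, probed words,
noise, splits, classifier init — derives from the master seed through
spawned substreams, so results are reproducible end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decoding import AXES, ClassifierConfig, run_decoding
from .encoding import DEFAULT_GRID, GridSpec
from .lexicon import Lexicon, generate_lexicon
from .metrics import adjacency_report
from .training import ConvergenceError, RegimeConfig, train_to_criterion

VOCAB_SIZES = (50, 100, 150, 200, 250)


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared experiment parameters; defaults reproduce the study's scale."""

    n_networks: int = 10
    vocab_size: int = 100
    vocab_sizes: tuple[int, ...] = VOCAB_SIZES
    n_anagram_words: int = 50
    regime: RegimeConfig = field(default_factory=RegimeConfig)
    # mixed anagram lexicons need a gentler learning rate to settle at
    # criterion (anagram pairs can cycle indefinitely at the default rate)
    anagram_regime: RegimeConfig = field(
        default_factory=lambda: RegimeConfig(lr=0.5)
    )
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0
    out_dir: str | None = None
    grid: GridSpec = DEFAULT_GRID


def _rng_stream(seed: int):
    """Infinite deterministic stream of child generators."""
    ss = np.random.SeedSequence(seed)
    while True:
        yield np.random.default_rng(ss.spawn(1)[0])


def _write(df: pd.DataFrame, out_dir, name: str) -> None:
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / name, index=False, float_format="%.6f")


def _write_cm(cm: np.ndarray, out_dir, name: str) -> None:
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            cm,
            index=[f"true_{i+1}" for i in range(cm.shape[0])],
            columns=[f"guess_{j+1}" for j in range(cm.shape[1])],
        ).to_csv(Path(out_dir) / name)


def _train_networks(
    lexicon: Lexicon, cfg: ExperimentConfig, rngs, n=None, regime=None
):
    """Train ``n`` networks to criterion.

    A weight initialisation that cycles without reaching criterion within
    the epoch budget (rare, essentially only for anagram-heavy lexicons)
    is discarded and replaced by a fresh one, up to two replacements per
    network.
    """
    regime = regime or cfg.regime
    traces = []
    for _ in range(n or cfg.n_networks):
        for attempt in range(3):
            try:
                traces.append(
                    train_to_criterion(
                        lexicon, regime, seed=next(rngs), spec=cfg.grid
                    )
                )
                break
            except ConvergenceError:
                if attempt == 2:
                    raise
                warnings.warn(
                    "initialisation failed to reach criterion within "
                    f"{regime.max_epochs} epochs; retrying with a fresh one",
                    stacklevel=2,
                )
    return traces


def _decode_battery(
    nets, lexicon, cfg: ExperimentConfig, rngs, layers=("input", "hidden"),
    n_classes=(2, 6), words=None, tag=None,
):
    """Run all requested conditions on all networks; tidy rows + confusions."""
    rows = []
    cms: dict[tuple, np.ndarray] = {}
    for layer in layers:
        for axis in AXES:
            for L in n_classes:
                for i, net in enumerate(nets):
                    res = run_decoding(
                        net, lexicon, axis, layer, L, cfg.classifier,
                        seed=next(rngs), words=words, spec=cfg.grid,
                    )
                    key = (layer, axis, L)
                    cms[key] = cms.get(key, 0) + res.confusion
                    for r, acc in enumerate(res.accuracies):
                        rows.append(
                            {
                                "item_set": tag or "all",
                                "network": i,
                                "layer": layer,
                                "axis": axis,
                                "n_classes": L,
                                "run": r,
                                "accuracy": acc,
                            }
                        )
    return pd.DataFrame(rows), cms


def summarize_decoding(tidy: pd.DataFrame, cms=None) -> pd.DataFrame:
    """Per-condition mean and SEM (over network means), plus adjacency stats."""
    keys = ["item_set", "layer", "axis", "n_classes"]
    net_means = (
        tidy.groupby(keys + ["network"])["accuracy"].mean().reset_index()
    )
    out = (
        net_means.groupby(keys)["accuracy"]
        .agg(mean_accuracy="mean", sem_accuracy="sem")
        .reset_index()
    )
    out["chance"] = 1.0 / out["n_classes"]
    if cms:
        adj, ai = [], []
        for _, row in out.iterrows():
            key = (row["layer"], row["axis"], row["n_classes"])
            if row["n_classes"] == 6 and key in cms:
                rep = adjacency_report(cms[key])
                adj.append(rep.adjacent_pct)
                ai.append(rep.ai)
            else:
                adj.append(np.nan)
                ai.append(np.nan)
        out["adjacent_pct"] = adj
        out["adjacency_index"] = ai
    return out


def experiment_mature(cfg: ExperimentConfig = ExperimentConfig()):
    """Decoding of mature (trained-to-criterion) word representations.

    Trains ``n_networks`` networks on a shared ``vocab_size``-word lexicon
    and decodes input and hidden patterns along both axes into 2 and 6
    location classes.  Returns (tidy per-run frame, summary table,
    confusion matrices).
    """
    rngs = _rng_stream(cfg.seed)
    lexicon = generate_lexicon(cfg.vocab_size, 0, next(rngs))
    traces = _train_networks(lexicon, cfg, rngs)
    tidy, cms = _decode_battery([t.network for t in traces], lexicon, cfg, rngs)
    summary = summarize_decoding(tidy, cms)
    _write(tidy, cfg.out_dir, "mature_runs.csv")
    _write(summary, cfg.out_dir, "mature_summary.csv")
    for (layer, axis, L), cm in cms.items():
        if L == 6:
            _write_cm(cm, cfg.out_dir, f"mature_confusion_{layer}_{axis}.csv")
    return tidy, summary, cms


def experiment_timecourse(
    cfg: ExperimentConfig = ExperimentConfig(), n_steps: int = 20
):
    """Location sensitivity of hidden patterns across training.

    Each network is snapshotted during training; at ``n_steps`` milestone
    epochs (step 0 = untrained through the final epoch) hidden patterns are
    decoded and central recognition accuracy recorded.
    """
    from .training import recognition_accuracy

    rngs = _rng_stream(cfg.seed)
    lexicon = generate_lexicon(cfg.vocab_size, 0, next(rngs))
    rows = []
    for i in range(cfg.n_networks):
        trace = train_to_criterion(
            lexicon, cfg.regime, seed=next(rngs), spec=cfg.grid,
            store_snapshots=True,
        )
        for step, (epoch, net) in enumerate(trace.milestones(n_steps)):
            cx, cy = cfg.grid.center
            rec = recognition_accuracy(net, lexicon, cx, cy, cfg.grid)
            for axis in AXES:
                for L in (2, 6):
                    res = run_decoding(
                        net, lexicon, axis, "hidden", L, cfg.classifier,
                        seed=next(rngs), spec=cfg.grid,
                    )
                    rows.append(
                        {
                            "network": i,
                            "step": step,
                            "epoch": epoch,
                            "recognition_accuracy": rec,
                            "axis": axis,
                            "n_classes": L,
                            "accuracy": res.mean_accuracy,
                        }
                    )
    tidy = pd.DataFrame(rows)
    summary = (
        tidy.groupby(["step", "axis", "n_classes"])
        .agg(
            epoch=("epoch", "mean"),
            recognition_accuracy=("recognition_accuracy", "mean"),
            mean_accuracy=("accuracy", "mean"),
            sem_accuracy=("accuracy", "sem"),
        )
        .reset_index()
    )
    _write(tidy, cfg.out_dir, "timecourse_runs.csv")
    _write(summary, cfg.out_dir, "timecourse_summary.csv")
    return tidy, summary


def experiment_vocab_size(cfg: ExperimentConfig = ExperimentConfig()):
    """Hidden-layer location sensitivity as a function of vocabulary size.

    ``n_networks`` fresh networks per vocabulary size, each size with its
    own generated lexicon; hidden patterns decoded along both axes into 2
    and 6 classes.
    """
    rngs = _rng_stream(cfg.seed)
    frames = []
    for n_words in cfg.vocab_sizes:
        lexicon = generate_lexicon(n_words, 0, next(rngs))
        traces = _train_networks(lexicon, cfg, rngs)
        tidy, _ = _decode_battery(
            [t.network for t in traces], lexicon, cfg, rngs, layers=("hidden",)
        )
        tidy.insert(0, "vocab_size", n_words)
        frames.append(tidy)
    tidy = pd.concat(frames, ignore_index=True)
    net_means = (
        tidy.groupby(["vocab_size", "axis", "n_classes", "network"])["accuracy"]
        .mean()
        .reset_index()
    )
    summary = (
        net_means.groupby(["vocab_size", "axis", "n_classes"])["accuracy"]
        .agg(mean_accuracy="mean", sem_accuracy="sem")
        .reset_index()
    )
    _write(tidy, cfg.out_dir, "vocab_size_runs.csv")
    _write(summary, cfg.out_dir, "vocab_size_summary.csv")
    return tidy, summary


def experiment_anagram(cfg: ExperimentConfig = ExperimentConfig()):
    """Item-level location sensitivity: anagram vs normal words.

    Networks are trained on a mixed lexicon (``vocab_size`` words of which
    ``n_anagram_words`` form disjoint anagram pairs); separate classifiers
    decode hidden patterns of anagram and of normal words.
    """
    rngs = _rng_stream(cfg.seed)
    lexicon = generate_lexicon(cfg.vocab_size, cfg.n_anagram_words, next(rngs))
    traces = _train_networks(lexicon, cfg, rngs, regime=cfg.anagram_regime)
    nets = [t.network for t in traces]
    frames = []
    all_cms = {}
    for tag, words in (
        ("normal", lexicon.normal_words),
        ("anagram", lexicon.anagram_words),
    ):
        tidy, cms = _decode_battery(
            nets, lexicon, cfg, rngs, layers=("hidden",), words=words, tag=tag
        )
        frames.append(tidy)
        for key, cm in cms.items():
            all_cms[(tag,) + key] = cm
    tidy = pd.concat(frames, ignore_index=True)
    summary = summarize_decoding(tidy)
    adj, ai = [], []
    for _, row in summary.iterrows():
        key = (row["item_set"], row["layer"], row["axis"], row["n_classes"])
        if row["n_classes"] == 6 and key in all_cms:
            rep = adjacency_report(all_cms[key])
            adj.append(rep.adjacent_pct)
            ai.append(rep.ai)
        else:
            adj.append(np.nan)
            ai.append(np.nan)
    summary["adjacent_pct"] = adj
    summary["adjacency_index"] = ai
    _write(tidy, cfg.out_dir, "anagram_runs.csv")
    _write(summary, cfg.out_dir, "anagram_summary.csv")
    return tidy, summary


EXPERIMENTS = {
    "mature": experiment_mature,
    "timecourse": experiment_timecourse,
    "vocab": experiment_vocab_size,
    "anagram": experiment_anagram,
}
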