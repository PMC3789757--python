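"""Stochastic-location regime, convergence criterion, trace bookkeeping."""

import numpy as np
import pytest
import scipy.stats

from lazyvwfa.encoding import DEFAULT_GRID
from lazyvwfa.lexicon import Lexicon, generate_lexicon
from lazyvwfa.mlp import init_network
from lazyvwfa.training import (
    ConvergenceError,
    RegimeConfig,
    accuracy_map,
    converged,
    recognition_accuracy,
    run_epoch,
    sample_location,
    train_to_criterion,
)


def test_regime_config_validates_spreads():
    with pytest.raises(ValueError):
        RegimeConfig(sigma_x=1.0, sigma_y=2.0)
    with pytest.raises(ValueError):
        RegimeConfig(criterion="everywhere")


def test_sample_location_degenerate_spread_hits_center(rng):
    cfg = RegimeConfig(sigma_x=1e-9, sigma_y=5e-10)
    assert all(sample_location(cfg, rng) == (4, 4) for _ in range(50))


def test_sample_location_horizontal_spread_exceeds_vertical(rng):
    cfg = RegimeConfig()
    draws = np.array([sample_location(cfg, rng) for _ in range(10_000)])
    assert draws.min() >= 1 and draws.max() <= 7
    assert draws[:, 0].std() > draws[:, 1].std()


def test_sample_location_matches_truncated_rounded_normal(rng):
    """Chi-square against cell probabilities obtained by integrating the
    normal density over each coordinate's rounding bin (the oracle)."""
    cfg = RegimeConfig()
    n = 100_000
    draws = np.array([sample_location(cfg, rng) for _ in range(n)])
    obs = np.zeros((7, 7))
    for x, y in draws:
        obs[x - 1, y - 1] += 1

    def bin_probs(sigma):
        edges = np.arange(0.5, 8.5)  # value k covered by [k-.5, k+.5]
        cdf = scipy.stats.norm.cdf(edges, loc=4, scale=sigma)
        p = np.diff(cdf)
        return p / p.sum()

    expected = n * np.outer(bin_probs(cfg.sigma_x), bin_probs(cfg.sigma_y))
    chi2 = ((obs - expected) ** 2 / expected).sum()
    crit = scipy.stats.chi2.ppf(0.99, df=49 - 1)
    assert chi2 < crit


def test_run_epoch_single_word_single_update():
    lex = Lexicon(words=("life",))
    net = init_network(1, seed=0)
    ref = net.copy()
    sse = run_epoch(net, lex, {"life": (4, 4)}, lr=0.5, rng=np.random.default_rng(0))
    assert sse > 0
    # exactly the 4 active input columns changed
    changed = np.flatnonzero(np.any(net.W_ih != ref.W_ih, axis=0))
    assert changed.size == 4


def test_run_epoch_reduces_error_on_toy_problem():
    lex = generate_lexicon(10, 0, seed=0)
    net = init_network(10, seed=1)
    placements = {w: (4, 4) for w in lex.words}
    rng = np.random.default_rng(2)
    sses = [run_epoch(net, lex, placements, lr=1.0, rng=rng) for _ in range(10)]
    assert sses[-1] < sses[0]


def test_converged_false_for_untrained_network():
    lex = generate_lexicon(100, 0, seed=3)
    net = init_network(100, seed=3)
    assert not converged(net, lex)


def test_converged_single_word_after_training():
    lex = Lexicon(words=("life",))
    net = init_network(1, seed=0)
    # one output unit: argmax is trivially correct
    assert converged(net, lex)


def test_train_to_criterion_small_lexicon(trained_small, lex20):
    assert trained_small.epochs_to_criterion > 0
    assert converged(trained_small.network, lex20)
    assert recognition_accuracy(trained_small.network, lex20, 4, 4) == 1.0
    # exposure bookkeeping
    assert trained_small.exposure.sum() == trained_small.epochs_to_criterion * 20


def test_training_is_deterministic(lex20):
    cfg = RegimeConfig()
    a = train_to_criterion(lex20, cfg, seed=11)
    b = train_to_criterion(lex20, cfg, seed=11)
    assert a.epochs_to_criterion == b.epochs_to_criterion
    assert np.array_equal(a.network.W_ih, b.network.W_ih)
    assert np.array_equal(a.exposure, b.exposure)


def test_non_convergence_raises_with_partial_trace(lex20):
    with pytest.raises(ConvergenceError) as excinfo:
        train_to_criterion(lex20, RegimeConfig(max_epochs=2), seed=0)
    assert excinfo.value.trace.epochs_to_criterion == 2


def test_milestones_span_training(lex20):
    trace = train_to_criterion(lex20, RegimeConfig(), seed=5, store_snapshots=True)
    ms = trace.milestones(20)
    assert len(ms) == 20
    assert ms[0][0] == 0
    assert ms[-1][0] == trace.epochs_to_criterion
    epochs = [e for e, _ in ms]
    assert epochs == sorted(epochs)
    # step-0 snapshot is the freshly initialised network
    rng = np.random.default_rng(5)
    net0 = init_network(20, rng)
    assert np.array_equal(ms[0][1].W_ih, net0.W_ih)


def test_accuracy_map_chance_for_untrained_and_perfect_center(trained_small, lex20):
    untrained = init_network(100, seed=8)
    lex100 = generate_lexicon(100, 0, seed=8)
    amap = accuracy_map(untrained, lex100)
    assert abs(amap.mean() - 0.01) < 0.01
    amap_t = accuracy_map(trained_small.network, lex20)
    assert amap_t[3, 3] == 1.0


def test_trace_persistence(trained_small, tmp_path):
    trained_small.save(tmp_path, stem="run0")
    lines = (tmp_path / "run0_trace.csv").read_text().splitlines()
    assert lines[0] == "epoch,mean_sse,central_accuracy"
    assert len(lines) == trained_small.epochs_to_criterion + 1
    exposure = np.loadtxt(tmp_path / "run0_exposure.csv", delimiter=",")
    assert np.array_equal(exposure, trained_small.exposure)
    assert (tmp_path / "run0.npz").exists()


def test_exposure_accuracy_positive_correlation(trained_small, lex20):
    """Recognition accuracy tracks cumulated exposure across locations."""
    amap = accuracy_map(trained_small.network, lex20)
    rho = scipy.stats.spearmanr(
        trained_small.exposure.ravel(), amap.ravel()
    ).statistic
    assert rho > 0.3
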