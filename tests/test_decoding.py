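"""Pattern collection, noise, splits, delta-rule classifier, batteries."""

import numpy as np
import pytest

from lazyvwfa.decoding import (
    ClassifierConfig,
    PatternSet,
    add_noise,
    class_of,
    collect_patterns,
    evaluate,
    probe_locations,
    run_decoding,
    split_train_test,
    train_perceptron,
)
from lazyvwfa.mlp import init_network


def test_probe_locations_exclude_center():
    horiz = probe_locations("horizontal")
    vert = probe_locations("vertical")
    assert horiz == [(x, 4) for x in (1, 2, 3, 5, 6, 7)]
    assert vert == [(4, y) for y in (1, 2, 3, 5, 6, 7)]
    assert len(set(horiz) | set(vert)) == 12
    with pytest.raises(ValueError):
        probe_locations("diagonal")


@pytest.mark.parametrize(
    "loc,axis,L,expected",
    [
        ((1, 4), "horizontal", 2, 0),
        ((5, 4), "horizontal", 2, 1),
        ((4, 7), "vertical", 6, 5),
        ((4, 1), "vertical", 2, 0),
        ((7, 4), "horizontal", 6, 5),
        ((3, 4), "horizontal", 6, 2),
    ],
)
def test_class_of(loc, axis, L, expected):
    assert class_of(loc, axis, L) == expected


def test_class_of_rejects_center():
    with pytest.raises(ValueError):
        class_of((4, 4), "horizontal", 2)


def test_collect_patterns_shapes_and_ranges(lex20):
    net = init_network(20, seed=0)
    words = lex20.words[:10]
    inp = collect_patterns(net, words, "horizontal", "input")
    assert inp.X.shape == (60, 1820)
    assert np.array_equal(np.unique(inp.X), [0.0, 1.0])
    assert np.all(inp.X.sum(axis=1) == 4)
    hid = collect_patterns(net, words, "vertical", "hidden")
    assert hid.X.shape == (60, 50)
    assert np.all((hid.X > 0) & (hid.X < 1))


def test_collect_patterns_standard_count(lex20, trained_small):
    # 40 words x 6 locations = 240 patterns in the standard battery
    words = [f"{a}{b}cd" for a in "abcdefgh" for b in "aeiou"]
    ps = collect_patterns(trained_small.network, words, "horizontal", "input")
    assert len(ps) == 240


def test_add_noise_moments(rng):
    ps = PatternSet(
        X=np.zeros((100, 1000)),
        words=("life",) * 100,
        locations=np.tile([1, 4], (100, 1)),
        axis="horizontal",
        layer="input",
    )
    noisy = add_noise(ps, 0.025, rng)
    vals = noisy.X.ravel()
    se_mean = 0.025 / np.sqrt(vals.size)
    assert abs(vals.mean()) < 3 * se_mean
    assert vals.std() == pytest.approx(0.025, rel=0.02)
    same = add_noise(ps, 0.0, rng)
    assert np.array_equal(same.X, ps.X)


@pytest.mark.parametrize("L,n_test", [(2, 12), (6, 36)])
def test_split_sizes_and_stratification(lex20, L, n_test, rng):
    words = [f"{a}{b}cd" for a in "abcdefgh" for b in "aeiou"]
    net = init_network(20, seed=0)
    ps = collect_patterns(net, words, "horizontal", "input")
    train, test = split_train_test(ps, L, rng)
    assert len(test) == n_test and len(train) == 240 - n_test
    counts = np.bincount(test.classes(L), minlength=L)
    assert np.all(counts == n_test // L)
    # disjoint, exhaustive
    key = lambda p: {(w, tuple(l)) for w, l in zip(p.words, p.locations.tolist())}
    assert key(train) | key(test) == key(ps)
    assert not (key(train) & key(test))


def test_perceptron_zero_error_means_zero_update():
    # unit-vector patterns and a weight matrix that reproduces every target
    # exactly: the delta update is proportional to the error, so W is fixed
    from lazyvwfa.decoding import _delta_core_py

    X = np.eye(4)
    classes = np.array([0, 1, 0, 1])
    W0 = np.zeros((2, 4))
    W0[classes, np.arange(4)] = 1.0
    orders = np.tile(np.arange(4), (50, 1))
    T = np.eye(2)[classes]
    W_after = _delta_core_py(W0.copy(), X, T, orders, lr=0.5)
    assert np.array_equal(W_after, W0)


def test_perceptron_solves_separable_toy_problem(rng):
    pts = np.vstack([rng.normal((2, 2), 0.3, (20, 2)), rng.normal((-2, -2), 0.3, (20, 2))])
    ps = PatternSet(
        X=pts,
        words=("life",) * 40,
        locations=np.array([[1, 4]] * 20 + [[5, 4]] * 20),
        axis="horizontal",
        layer="input",
    )
    cfg = ClassifierConfig(lr=0.01, epochs=200, init_range=0.01)
    W = train_perceptron(ps, 2, cfg, rng)
    acc, cm = evaluate(W, ps, 2)
    assert acc == 1.0
    assert np.array_equal(cm, np.diag([20, 20]))


def test_perceptron_deterministic_given_rng(lex20):
    net = init_network(20, seed=0)
    ps = collect_patterns(net, lex20.words, "horizontal", "hidden")
    cfg = ClassifierConfig(epochs=20)
    W1 = train_perceptron(ps, 2, cfg, np.random.default_rng(7))
    W2 = train_perceptron(ps, 2, cfg, np.random.default_rng(7))
    assert np.array_equal(W1, W2)


def test_evaluate_accuracy_is_trace_over_total(rng):
    X = rng.normal(size=(30, 5))
    locs = np.array([probe_locations("horizontal")[i % 6] for i in range(30)])
    ps = PatternSet(X=X, words=("life",) * 30, locations=locs,
                    axis="horizontal", layer="hidden")
    W = rng.normal(size=(6, 5))
    acc, cm = evaluate(W, ps, 6)
    assert cm.sum() == 30
    assert acc == pytest.approx(np.trace(cm) / cm.sum())


def test_uninformative_patterns_decode_at_chance(rng):
    """Permutation-style null: patterns carry no location information, so
    held-out accuracy must sit at chance (1/6)."""
    accs = []
    for _ in range(5):
        X = rng.normal(size=(240, 50))
        locs = np.array(
            [probe_locations("horizontal")[i % 6] for i in range(240)]
        )
        ps = PatternSet(X=X, words=("life",) * 240, locations=locs,
                        axis="horizontal", layer="hidden")
        train, test = split_train_test(ps, 6, rng)
        W = train_perceptron(train, 6, ClassifierConfig(epochs=100), rng)
        accs.append(evaluate(W, test, 6)[0])
    assert abs(np.mean(accs) - 1 / 6) < 0.1


def test_run_decoding_aggregates_runs(trained_small, lex20):
    cfg = ClassifierConfig(n_runs=3, epochs=100, n_words=12)
    res = run_decoding(trained_small.network, lex20, "horizontal", "hidden", 2,
                       cfg, seed=0)
    assert res.accuracies.shape == (3,)
    assert res.confusion.sum() == 3 * 12
    assert 0 <= res.mean_accuracy <= 1
    res2 = run_decoding(trained_small.network, lex20, "horizontal", "hidden", 2,
                        cfg, seed=0)
    assert np.array_equal(res.accuracies, res2.accuracies)
    tab = res.summary()
    assert tab.loc[0, "mean_accuracy"] == pytest.approx(res.mean_accuracy)


def test_untrained_network_decodes_location_above_chance(lex20):
    """Random connectivity propagates the retinotopic input, so hidden
    patterns are location-classifiable before any learning."""
    net = init_network(20, seed=5)
    cfg = ClassifierConfig(n_runs=3, epochs=500)
    res = run_decoding(net, lex20, "vertical", "hidden", 6, cfg, seed=1)
    assert res.mean_accuracy > 2 * (1 / 6)
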