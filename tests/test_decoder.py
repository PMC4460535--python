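"""Feed-forward net decoder and baseline classifiers."""

import numpy as np
import pytest

from blockdecode import (TrainedNet, baseline_classifiers, predict,
                         predict_labels, train_nn)
from blockdecode.dataset import ExampleSet
from blockdecode.nnet import DEFAULT_N_RESTARTS
from tests.conftest import random_net


def _gaussian_set(rng, n_per_class=100, sep=6.0, n_classes=2):
    """Well-separated Gaussian blobs in 2-D, with 4-frame pseudo-blocks."""
    X, y = [], []
    for c in range(n_classes):
        mu = np.array([c * sep, 0.0])
        X.append(rng.normal(mu, 1.0, size=(n_per_class, 2)))
        y.append(np.full(n_per_class, c))
    X, y = np.vstack(X), np.concatenate(y)
    block = np.arange(len(y)) // 4
    block = block * n_classes + y        # keep blocks label-pure
    return ExampleSet(X, y, block, np.zeros(len(y), int))


def test_default_restarts_is_20():
    assert DEFAULT_N_RESTARTS == 20


def test_training_is_deterministic_given_seed():
    ex = _gaussian_set(np.random.default_rng(0))
    a = train_nn(ex, hidden_grid=(3,), n_restarts=2, seed=5, max_epochs=100)
    b = train_nn(ex, hidden_grid=(3,), n_restarts=2, seed=5, max_epochs=100)
    assert np.array_equal(a.V, b.V) and np.array_equal(a.W, b.W)


def test_separated_gaussians_validation_accuracy_high():
    ex = _gaussian_set(np.random.default_rng(1))
    net = train_nn(ex, hidden_grid=(2, 4), n_restarts=3, seed=0, max_epochs=200)
    acc = np.mean(predict_labels(net, ex.X) == ex.y)
    assert acc >= 0.95


def test_posteriors_sum_to_one_and_confidence_matches():
    rng = np.random.default_rng(2)
    net = random_net(rng)
    frames = predict(net, rng.standard_normal((20, 7)))
    for f in frames:
        assert f.posteriors.sum() == pytest.approx(1.0, abs=1e-12)
        assert f.confidence == pytest.approx(f.posteriors.max())
        assert f.label == net.class_order[np.argmax(f.posteriors)]


def test_uniform_posteriors_when_raw_outputs_all_zero():
    net = TrainedNet(V=np.zeros((2, 3)), hidden_bias=np.zeros(2),
                     W=np.zeros((4, 2)), output_bias=np.full(4, -50.0),
                     hidden_activation="tanh", output_activation="identity")
    f = predict(net, np.ones((1, 3)))[0]
    assert np.allclose(f.posteriors, 0.25)
    assert f.confidence == pytest.approx(0.25)


def test_forward_pass_closed_form_with_identity_activations():
    rng = np.random.default_rng(3)
    net = TrainedNet(V=rng.standard_normal((4, 6)),
                     hidden_bias=rng.standard_normal(4),
                     W=rng.standard_normal((3, 4)),
                     output_bias=rng.standard_normal(3),
                     hidden_activation="identity", output_activation="identity")
    X = rng.standard_normal((5, 6))
    expected = (X @ net.V.T + net.hidden_bias) @ net.W.T + net.output_bias
    assert np.allclose(net.raw_outputs(X), expected)


def test_non_finite_input_rejected():
    net = random_net(np.random.default_rng(4))
    bad = np.ones((1, 7))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        predict(net, bad)


def test_class_needs_two_blocks_for_validation_split():
    X = np.random.default_rng(5).standard_normal((8, 2))
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    ex = ExampleSet(X, y, np.array([0, 0, 0, 0, 1, 1, 1, 1]), np.zeros(8, int))
    with pytest.raises(ValueError):
        train_nn(ex, hidden_grid=(2,), n_restarts=1)


def test_restart_selection_reduces_performance_variance():
    """The best-of-restarts net varies less across seeds than a
    single-restart net (the stated purpose of the restart phase)."""
    ex = _gaussian_set(np.random.default_rng(6), n_per_class=60, sep=1.5,
                       n_classes=3)
    hold_rng = np.random.default_rng(7)
    Xh = np.vstack([hold_rng.normal([c * 1.5, 0.0], 1.0, size=(40, 2))
                    for c in range(3)])
    yh = np.repeat(np.arange(3), 40)

    def accs(n_restarts):
        out = []
        for seed in range(10):
            net = train_nn(ex, hidden_grid=(4,), n_restarts=n_restarts,
                           seed=seed, max_epochs=150)
            out.append(np.mean(predict_labels(net, Xh) == yh))
        return np.var(out)

    assert accs(8) <= accs(1) + 1e-9


def test_serialization_round_trip(tmp_path):
    net = random_net(np.random.default_rng(8))
    path = tmp_path / "net.json"
    net.to_json(path)
    back = TrainedNet.from_json(path)
    X = np.random.default_rng(9).standard_normal((4, 7))
    assert np.allclose(net.raw_outputs(X), back.raw_outputs(X))


# -- baselines ------------------------------------------------------------

def test_knn_k1_perfect_on_training_set():
    rng = np.random.default_rng(10)
    ex = _gaussian_set(rng, n_per_class=20, sep=2.0)
    clf = baseline_classifiers("knn", {"k": 1}).fit(ex)
    assert np.mean(clf.predict(ex.X) == ex.y) == 1.0


def test_gnb_symmetric_decision_boundary_at_zero():
    X = np.array([[-2.0], [-1.0], [-1.5], [2.0], [1.0], [1.5]])
    y = np.array([0, 0, 0, 1, 1, 1])
    ex = ExampleSet(X, y, np.arange(6), np.zeros(6, int))
    clf = baseline_classifiers("gnb").fit(ex)
    assert clf.predict(np.array([[-0.1]]))[0] == 0
    assert clf.predict(np.array([[0.1]]))[0] == 1


def test_svm_separable_toy_zero_training_errors():
    rng = np.random.default_rng(11)
    ex = _gaussian_set(rng, n_per_class=10, sep=8.0)
    clf = baseline_classifiers("svm_linear").fit(ex)
    assert np.mean(clf.predict(ex.X) == ex.y) == 1.0


def test_unknown_baseline_rejected():
    with pytest.raises(ValueError):
        baseline_classifiers("random_forest")


def test_session_confidence_tracks_session_accuracy():
    """Across sessions of increasing noise, the session-mean confidence of
    the network decoder is positively rank-correlated with its
    cross-validated accuracy."""
    from scipy.stats import spearmanr

    from blockdecode import cross_validate
    from tests.conftest import NN_SPEC, make_session

    accs, confs = [], []
    for i, wsd in enumerate([0.5, 1.0, 1.6, 2.4]):
        examples, _, _ = make_session(50 + i, effect_scale=1.4, white_sd=wsd)
        res = cross_validate(examples, "block", classifier_spec=NN_SPEC,
                             seed=i)
        accs.append(res.mean_accuracy)
        confs.append(np.mean([c for _, _, c in res.per_frame_records]))
    rho = spearmanr(confs, accs).statistic
    assert rho > 0
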