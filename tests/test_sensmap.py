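"""Sensitivity analysis: Jacobian oracle, ensemble aggregation, RFE."""

import numpy as np
import pytest

from blockdecode import (TrainedNet, aggregate_sensitivity, rfe,
                         sensitivity_matrix, train_ensemble)
from tests.conftest import make_session, random_net

RFE_CV = {"k": 4, "classifier_spec": {"name": "nn", "hidden_grid": [8],
                                      "n_restarts": 1, "max_epochs": 150}}
RFE_TRAIN = {"hidden_grid": (8,), "n_restarts": 1, "max_epochs": 150}


def _finite_difference(net, x, h=1e-5):
    """Independent central-finite-difference Jacobian in standardized space."""
    z = net.standardize(x).ravel()
    S = np.zeros((net.n_outputs, net.n_inputs))
    for i in range(len(z)):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        S[:, i] = (net.forward(zp[None])[1] - net.forward(zm[None])[1]).ravel() / (2 * h)
    return S


def test_sensitivity_matches_finite_differences_on_random_nets():
    rng = np.random.default_rng(0)
    for _ in range(20):
        net = random_net(rng)
        for _ in range(10):
            x = rng.standard_normal(net.n_inputs)
            S = sensitivity_matrix(net, x)
            assert np.abs(S - _finite_difference(net, x)).max() < 1e-5


def test_linear_activation_sensitivity_is_w_times_v():
    rng = np.random.default_rng(1)
    net = TrainedNet(V=rng.standard_normal((4, 6)),
                     hidden_bias=rng.standard_normal(4),
                     W=rng.standard_normal((3, 4)),
                     output_bias=rng.standard_normal(3),
                     hidden_activation="identity", output_activation="identity")
    for _ in range(5):
        x = rng.standard_normal(6)
        assert np.allclose(sensitivity_matrix(net, x), net.W @ net.V)


def test_zero_input_weights_give_zero_sensitivity():
    net = TrainedNet(V=np.zeros((3, 5)), hidden_bias=np.ones(3),
                     W=np.ones((2, 3)), output_bias=np.zeros(2))
    assert np.all(sensitivity_matrix(net, np.ones(5)) == 0)


def test_sensitivity_respects_input_scaling():
    """Scaling a standardized column by c scales that sensitivity column by
    the chain-rule factor (checked against the finite-difference oracle)."""
    rng = np.random.default_rng(2)
    net = random_net(rng)
    x = rng.standard_normal(net.n_inputs)
    scale = np.ones(net.n_inputs)
    scale[3] = 2.0
    scaled = TrainedNet(V=net.V, hidden_bias=net.hidden_bias, W=net.W,
                        output_bias=net.output_bias,
                        input_scaler=(np.zeros(net.n_inputs), scale))
    S = sensitivity_matrix(scaled, x)
    assert np.abs(S - _finite_difference(scaled, x)).max() < 1e-5


def test_aggregate_single_linear_net_rms_is_abs_wv():
    rng = np.random.default_rng(3)
    net = TrainedNet(V=rng.standard_normal((4, 6)),
                     hidden_bias=np.zeros(4),
                     W=rng.standard_normal((3, 4)), output_bias=np.zeros(3),
                     hidden_activation="identity", output_activation="identity")
    X = rng.standard_normal((10, 6))
    res = aggregate_sensitivity([net], X)
    assert np.allclose(res.S_rms, np.abs(net.W @ net.V))
    assert np.allclose(res.phi, np.abs(net.W @ net.V).max(axis=0))


def test_phi_is_max_over_classes_and_nonnegative():
    rng = np.random.default_rng(4)
    nets = [random_net(rng) for _ in range(3)]
    X = rng.standard_normal((6, 7))
    res = aggregate_sensitivity(nets, X)
    assert np.all(res.S_rms >= 0)
    assert np.allclose(res.phi, res.S_rms.max(axis=0))
    assert res.n_nets == 3 and res.n_inputs_used == 6


def test_symmetric_duplicated_columns_get_equal_phi():
    """A net whose weights are symmetric in two duplicated input columns
    assigns them identical sensitivity."""
    rng = np.random.default_rng(5)
    V = rng.standard_normal((4, 6))
    V[:, 5] = V[:, 4]                      # symmetric weights for the pair
    net = TrainedNet(V=V, hidden_bias=rng.standard_normal(4),
                     W=rng.standard_normal((3, 4)),
                     output_bias=rng.standard_normal(3))
    X = rng.standard_normal((8, 6))
    X[:, 5] = X[:, 4]                      # duplicated voxel time series
    res = aggregate_sensitivity([net], X)
    assert np.allclose(res.phi[4], res.phi[5], atol=1e-12)


def test_mismatched_net_shapes_rejected():
    rng = np.random.default_rng(6)
    with pytest.raises(ValueError):
        aggregate_sensitivity([random_net(rng, n_in=7), random_net(rng, n_in=5)],
                              np.ones((2, 7)))


def test_ensemble_is_seeded_and_distinct():
    examples, _, _ = make_session(0)
    nets = train_ensemble(examples, 3, seed=1, hidden_grid=(4,), n_restarts=1,
                          max_epochs=50)
    nets2 = train_ensemble(examples, 3, seed=1, hidden_grid=(4,), n_restarts=1,
                           max_epochs=50)
    assert np.array_equal(nets[0].V, nets2[0].V)
    assert not np.array_equal(nets[0].V, nets[1].V)


def test_rfe_zero_threshold_removes_one_feature_per_iteration():
    examples, _, _ = make_session(1, effect_scale=2.5, n_voxels=30,
                                  n_informative=5)
    traj = rfe(examples, threshold=0.0, cv_args=RFE_CV, max_iter=4, seed=0,
               n_nets=2, train_kw=RFE_TRAIN)
    n0 = examples.n_features
    sizes = [len(s) for s in traj.surviving_indices]
    assert sizes == [n0, n0 - 1, n0 - 2, n0 - 3]


def test_rfe_surviving_sets_are_nested_and_fractions_decrease():
    examples, _, _ = make_session(2, effect_scale=2.5, n_voxels=40,
                                  n_informative=8)
    traj = rfe(examples, cv_args=RFE_CV, max_iter=6, seed=1, n_nets=2,
               train_kw=RFE_TRAIN)
    for a, b in zip(traj.surviving_indices, traj.surviving_indices[1:]):
        assert set(b) <= set(a)
    assert all(x > y for x, y in zip(traj.fraction_remaining,
                                     traj.fraction_remaining[1:]))


def test_rfe_keeps_planted_voxels_at_peak():
    examples, truth, _ = make_session(3, effect_scale=2.5, n_voxels=60,
                                      n_informative=6)
    traj = rfe(examples, cv_args=RFE_CV, max_iter=12, seed=2, n_nets=3,
               train_kw=RFE_TRAIN)
    surviving = traj.surviving_indices[traj.peak_iteration]
    assert np.isin(truth.informative_voxels, surviving).all()
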