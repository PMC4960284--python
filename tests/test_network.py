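"""Unit and property tests for the feedforward core."""

import math
from pathlib import Path

import numpy as np
import pytest

from gonogonet.network import (
    Network,
    TrainingConfig,
    analytic_gradients,
    backprop_step,
    compute_rms,
    finite_difference_gradients,
    forward,
    forward_batch,
    gradient_check,
    init_network,
    load_weights,
    save_weights,
    train_to_criterion,
)


# ---------------------------------------------------------------------------
# configuration and initialization

@pytest.mark.parametrize(
    "kw",
    [
        {"learning_rate": 0.0},
        {"momentum": -0.1},
        {"rms_threshold": 0.0},
        {"max_epochs": 0},
        {"init_low": 1.0, "init_high": 1.0},
        {"init_low": 2.0, "init_high": 1.0},
        {"criterion_metric": "mad"},
        {"update_mode": "minibatch"},
        {"steepness": -1.0},
    ],
)
def test_invalid_config_rejected(kw):
    with pytest.raises(ValueError):
        TrainingConfig(**kw)


@pytest.mark.parametrize("n_in,n_hid", [(0, 3), (3, 0), (-1, 2)])
def test_init_rejects_nonpositive_layer_sizes(n_in, n_hid):
    with pytest.raises(ValueError):
        init_network(n_in, n_hid)


def test_init_is_deterministic_given_seed():
    a = init_network(9, 4, rng=77)
    b = init_network(9, 4, rng=77)
    assert np.array_equal(a.w_ih, b.w_ih)
    assert np.array_equal(a.w_ho, b.w_ho)


def test_init_uniform_mean_matches_law_of_large_numbers(rng):
    # U(0,1): mean 1/2, sd sqrt(1/12); check the empirical mean of ~10^4
    # weights to three standard errors.
    nets = [init_network(20, 24, rng=rng) for _ in range(20)]
    weights = np.concatenate([n.w_ih.ravel() for n in nets])
    assert weights.size >= 10_000
    se = math.sqrt(1 / 12) / math.sqrt(weights.size)
    assert abs(weights.mean() - 0.5) < 3 * se
    assert weights.min() >= 0.0 and weights.max() < 1.0


def test_network_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        Network(np.zeros((4, 3)), np.zeros(3))  # w_ho needs n_hidden+1 = 4
    with pytest.raises(ValueError):
        Network(np.full((4, 3), np.nan), np.zeros(4))


# ---------------------------------------------------------------------------
# forward pass

def test_forward_zero_weights_gives_half():
    net = Network(np.zeros((4, 2)), np.zeros(3))
    assert forward(net, [1, 0, 1]) == pytest.approx(0.5)


def test_forward_matches_hand_computed_two_input_net():
    # 2 inputs, 1 hidden unit, explicit weights; expectation written out as
    # sigma(w_ho * sigma(w1*x1 + w2*x2 + b_h) + b_o) with math.exp.
    w_ih = np.array([[0.5], [-0.3], [0.1]])  # rows: x1, x2, bias
    w_ho = np.array([0.8, -0.2])  # hidden, bias
    net = Network(w_ih, w_ho)
    h = 1 / (1 + math.exp(-(0.5 * 1 + -0.3 * 1 + 0.1)))
    expected = 1 / (1 + math.exp(-(0.8 * h - 0.2)))
    assert forward(net, [1, 1]) == pytest.approx(expected, rel=1e-12)


def test_forward_output_always_in_open_unit_interval(rng):
    for _ in range(200):
        net = init_network(5, 3, TrainingConfig(init_low=-8, init_high=8), rng)
        x = rng.integers(0, 2, size=5)
        y = forward(net, x)
        assert 0.0 < y < 1.0


def test_forward_rejects_length_mismatch():
    net = init_network(4, 2, rng=0)
    with pytest.raises(ValueError):
        forward(net, [1, 0, 1])


def test_forward_batch_agrees_with_forward(rng):
    net = init_network(6, 3, rng=rng)
    X = rng.integers(0, 2, size=(7, 6)).astype(float)
    batch = forward_batch(net, X)
    single = [forward(net, x) for x in X]
    assert batch == pytest.approx(single, rel=1e-12)


# ---------------------------------------------------------------------------
# backpropagation

def test_backprop_gradients_match_finite_differences():
    assert gradient_check(n_triples=100, seed=0) < 1e-5


def test_backprop_zero_error_is_fixed_point(rng):
    net = init_network(4, 3, rng=rng)
    x = np.array([1.0, 0, 1, 0])
    y = forward(net, x)
    w_ih, w_ho = net.w_ih.copy(), net.w_ho.copy()
    backprop_step(net, x, y, TrainingConfig())
    assert np.array_equal(net.w_ih, w_ih)
    assert np.array_equal(net.w_ho, w_ho)


def test_repeated_steps_drive_output_to_target(rng):
    net = init_network(5, 3, rng=rng)
    x = np.array([1.0, 1, 0, 0, 1])
    cfg = TrainingConfig(learning_rate=0.1)
    errors = []
    for _ in range(300):
        errors.append(abs(forward(net, x) - 1.0))
        backprop_step(net, x, 1.0, cfg)
    diffs = np.diff(errors)
    assert np.all(diffs <= 1e-12)
    assert errors[-1] < errors[0] / 2


def test_backprop_rejects_out_of_range_target(rng):
    net = init_network(3, 2, rng=rng)
    with pytest.raises(ValueError):
        backprop_step(net, [1.0, 0, 0], 1.5, TrainingConfig())


def test_momentum_accumulates_previous_update(rng):
    # With momentum alpha, the second update equals -lr*g2 + alpha*dw1.
    x = np.array([1.0, 0, 1])
    cfg = TrainingConfig(learning_rate=0.2, momentum=0.9)
    net = init_network(3, 2, rng=42)
    plain = init_network(3, 2, rng=42)
    g1_ih, _ = analytic_gradients(plain, x, 1.0)
    backprop_step(net, x, 1.0, cfg)
    dw1 = -0.2 * g1_ih
    g2_ih, _ = analytic_gradients(net, x, 1.0)
    w_before = net.w_ih.copy()
    backprop_step(net, x, 1.0, cfg)
    assert net.w_ih == pytest.approx(w_before + (-0.2 * g2_ih + 0.9 * dw1), rel=1e-10)


# ---------------------------------------------------------------------------
# error metric

def test_rms_single_halfway_trial_is_half():
    net = Network(np.zeros((3, 2)), np.zeros(3))  # outputs 0.5 everywhere
    assert compute_rms(net, [[1, 0]], [1.0]) == pytest.approx(0.5)


def test_rms_zero_when_outputs_equal_targets():
    net = Network(np.zeros((3, 2)), np.zeros(3))
    assert compute_rms(net, [[1, 0], [0, 1]], [0.5, 0.5]) == pytest.approx(0.0)


def test_rms_matches_elementwise_aggregation_oracle(rng):
    net = init_network(9, 3, rng=rng)
    X = rng.integers(0, 2, size=(11, 9)).astype(float)
    t = rng.integers(0, 2, size=11).astype(float)
    expected = math.sqrt(sum((forward(net, x) - ti) ** 2 for x, ti in zip(X, t)) / 11)
    assert compute_rms(net, X, t) == pytest.approx(expected, rel=1e-12)
    assert compute_rms(net, X, t, "mse") == pytest.approx(expected**2, rel=1e-12)


def test_rms_rejects_empty_trial_set(rng):
    net = init_network(3, 2, rng=rng)
    with pytest.raises(ValueError):
        compute_rms(net, np.empty((0, 3)), np.empty(0))


# ---------------------------------------------------------------------------
# training loop

XOR_X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
XOR_T = np.array([0.0, 1, 1, 0])


def test_training_reaches_criterion_and_trace_is_consistent(quick_config):
    net = init_network(2, 3, quick_config, rng=3)
    cfg = TrainingConfig(rms_threshold=0.01, max_epochs=20_000, learning_rate=0.5)
    trace = train_to_criterion(net, XOR_X, XOR_T, cfg)
    assert trace.converged
    assert trace.iterations_to_criterion == trace.epochs_to_criterion * 4
    assert trace.rms_history[-1] <= cfg.rms_threshold
    assert compute_rms(net, XOR_X, XOR_T, cfg.criterion_metric) <= cfg.rms_threshold


def test_pretrained_network_needs_zero_epochs(quick_config):
    cfg = TrainingConfig(rms_threshold=0.01, max_epochs=20_000, learning_rate=0.5)
    net = init_network(2, 3, cfg, rng=3)
    train_to_criterion(net, XOR_X, XOR_T, cfg)
    again = train_to_criterion(net, XOR_X, XOR_T, cfg)
    assert again.converged
    assert again.epochs_to_criterion == 0
    assert again.iterations_to_criterion == 0


def test_nonconvergence_is_flagged_not_raised():
    net = init_network(2, 2, rng=0)
    trace = train_to_criterion(net, XOR_X, XOR_T, TrainingConfig(max_epochs=3))
    assert not trace.converged
    assert trace.epochs_to_criterion == -1
    assert len(trace.rms_history) == 3


def test_training_is_bit_deterministic_given_seed():
    def one():
        cfg = TrainingConfig(max_epochs=200, shuffle_each_epoch=True)
        net = init_network(2, 3, cfg, rng=11)
        trace = train_to_criterion(net, XOR_X, XOR_T, cfg, rng=12)
        return net, trace

    n1, t1 = one()
    n2, t2 = one()
    assert np.array_equal(n1.w_ih, n2.w_ih)
    assert np.array_equal(n1.w_ho, n2.w_ho)
    assert t1 == t2


def test_one_training_epoch_equals_manual_backprop_sequence():
    # The fast inlined epoch loop must be arithmetically identical to a
    # sequence of public backprop_step calls.
    cfg = TrainingConfig(max_epochs=1, momentum=0.5)
    fast = init_network(2, 3, cfg, rng=5)
    manual = fast.copy()
    train_to_criterion(fast, XOR_X, XOR_T, cfg)
    for x, t in zip(XOR_X, XOR_T):
        backprop_step(manual, x, t, cfg)
    assert fast.w_ih == pytest.approx(manual.w_ih, rel=1e-12, abs=1e-15)
    assert fast.w_ho == pytest.approx(manual.w_ho, rel=1e-12, abs=1e-15)


def test_batch_mode_applies_one_summed_update_per_epoch():
    cfg = TrainingConfig(max_epochs=1, update_mode="batch", learning_rate=0.2)
    net = init_network(2, 2, cfg, rng=9)
    ref = net.copy()
    g_ih = np.zeros_like(net.w_ih)
    g_ho = np.zeros_like(net.w_ho)
    for x, t in zip(XOR_X, XOR_T):
        gi, go = analytic_gradients(ref, x, t)
        g_ih += gi
        g_ho += go
    train_to_criterion(net, XOR_X, XOR_T, cfg)
    assert net.w_ih == pytest.approx(ref.w_ih - 0.2 * g_ih, rel=1e-12)
    assert net.w_ho == pytest.approx(ref.w_ho - 0.2 * g_ho, rel=1e-12)


def test_bias_disabled_keeps_bias_weights_zero():
    cfg = TrainingConfig(use_bias=False, max_epochs=50)
    net = init_network(2, 3, cfg, rng=4)
    assert np.all(net.w_ih[-1] == 0) and net.w_ho[-1] == 0
    train_to_criterion(net, XOR_X, XOR_T, cfg)
    assert np.all(net.w_ih[-1] == 0) and net.w_ho[-1] == 0


# ---------------------------------------------------------------------------
# gradient oracle internals and persistence

def test_finite_difference_oracle_is_exact_on_linear_region(rng):
    # Single random spot check that the two gradient routes agree entry-wise.
    net = init_network(4, 3, TrainingConfig(init_low=-1, init_high=1), rng)
    x = np.array([1.0, 0, 1, 1])
    a_ih, a_ho = analytic_gradients(net, x, 0.0)
    f_ih, f_ho = finite_difference_gradients(net, x, 0.0)
    assert a_ih == pytest.approx(f_ih, rel=1e-5, abs=1e-9)
    assert a_ho == pytest.approx(f_ho, rel=1e-5, abs=1e-9)


def test_weight_snapshot_round_trip(tmp_path, rng):
    net = init_network(5, 4, rng=rng)
    path = tmp_path / "weights.txt"
    save_weights(net, path)
    back = load_weights(path)
    assert np.array_equal(net.w_ih, back.w_ih)
    assert np.array_equal(net.w_ho, back.w_ho)
    assert back.use_bias == net.use_bias


def test_core_module_is_encoding_blind():
    # The network layer must not know about stimuli or the protocol module.
    import gonogonet.network as nw

    src = Path(nw.__file__).read_text()
    assert "from .protocol" not in src and "import protocol" not in src
    assert "Stimulus" not in src and "Compound" not in src
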