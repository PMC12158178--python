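"""Equation-level contracts of the autoencoder: gating, forward pass,
weighted loss, weight schedule, and gradient correctness."""

import numpy as np
import pytest
from scipy.special import expit

from gatewave.gates import GateMask, generate_gate_sequence, make_gate_mask
from gatewave.model import (
    WGLAE,
    WeightSchedule,
    _forward_flat,
    _loss_and_grads,
    gate_input,
    weighted_loss,
    weights_at_epoch,
)


def mask_for(labels, dv):
    theta = np.array([0 if l in dv else 1 for l in labels], dtype=np.int8)
    return GateMask(theta=theta, dv_labels=tuple(dv), labels=tuple(labels))


class TestGateInput:
    def test_masking_zeroes_dv_channels(self):
        mask = mask_for(("a", "b"), ("b",))
        out = gate_input(np.array([[0.2], [0.5]]), mask)
        assert out.tolist() == [[0.2], [0.0]]

    def test_identity_mask_is_noop(self):
        mask = mask_for(("a", "b", "c"), ())
        x = np.random.default_rng(0).random((5, 3, 4))
        assert np.array_equal(gate_input(x, mask), x)

    def test_three_channel_example(self):
        mask = mask_for(("a", "b", "c"), ("a", "c"))
        out = gate_input(np.array([0.3, 0.7, 0.1]), mask)
        assert np.allclose(out, [0.0, 0.7, 0.0])

    def test_channel_mismatch_rejected(self):
        mask = mask_for(("a", "b"), ("a",))
        with pytest.raises(ValueError, match="channel axis"):
            gate_input(np.zeros((4, 3, 5)), mask)


class TestForward:
    def test_zero_weights_give_half(self):
        h, y = _forward_flat(np.zeros((1, 4)), np.zeros((4, 2)), np.zeros(2),
                             np.zeros((2, 4)), np.zeros(4))
        assert np.allclose(y, 0.5)

    def test_matches_hand_computed_composition(self):
        # fixture model 2 -> 1 -> 2
        W1 = np.array([[0.5], [-0.25]])
        b1 = np.array([0.1])
        W2 = np.array([[1.0, -2.0]])
        b2 = np.array([0.0, 0.3])
        x = np.array([[0.4, 0.8]])
        h_expect = expit(0.4 * 0.5 + 0.8 * -0.25 + 0.1)
        y_expect = expit(np.array([h_expect * 1.0, h_expect * -2.0 + 0.3]))
        _, y = _forward_flat(x, W1, b1, W2, b2)
        assert np.allclose(y[0], y_expect)
        assert ((y > 0) & (y < 1)).all()

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        W1, b1 = rng.normal(size=(6, 3)), rng.normal(size=3)
        W2, b2 = rng.normal(size=(3, 6)), rng.normal(size=6)
        x = rng.random((4, 6))
        _, y1 = _forward_flat(x, W1, b1, W2, b2)
        _, y2 = _forward_flat(x, W1, b1, W2, b2)
        assert np.array_equal(y1, y2)


class TestWeightedLoss:
    def test_uniform_weights_reduce_to_mse(self):
        rng = np.random.default_rng(1)
        x, xh = rng.random((6, 10)), rng.random((6, 10))
        assert weighted_loss(x, xh, np.ones(10)) == pytest.approx(
            float(((xh - x) ** 2).mean())
        )

    def test_perfect_reconstruction_is_zero(self):
        x = np.random.default_rng(2).random((3, 5))
        assert weighted_loss(x, x, np.full(5, 2.0)) == 0.0

    def test_hand_arithmetic_example(self):
        # (2*0.25 + 0*0.25) / 2 = 0.25
        assert weighted_loss([0.0, 1.0], [0.5, 0.5], [2.0, 0.0]) == pytest.approx(0.25)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            weighted_loss([0.0], [0.1], [-1.0])


class TestWeightSchedule:
    def test_epoch_zero_gives_initial(self):
        sched = WeightSchedule(dv_weight_initial=3.0, decay_time_constant=10.0)
        mask = mask_for(("a", "b"), ("a",))
        w = weights_at_epoch(sched, mask, 0)
        assert w[0] == pytest.approx(3.0)
        assert w[1] == pytest.approx(1.0)

    def test_decay_value_at_tau(self):
        sched = WeightSchedule(dv_weight_initial=3.0, decay_time_constant=10.0,
                               floor_weight=1.0)
        mask = mask_for(("a",), ("a",))
        w = weights_at_epoch(sched, mask, 10)
        assert w[0] == pytest.approx(1.0 + 2.0 * np.exp(-1.0))

    def test_limit_is_floor(self):
        sched = WeightSchedule(dv_weight_initial=5.0, decay_time_constant=3.0)
        mask = mask_for(("a",), ("a",))
        assert weights_at_epoch(sched, mask, 10_000)[0] == pytest.approx(1.0)

    def test_monotone_non_increasing(self):
        sched = WeightSchedule(dv_weight_initial=2.0, decay_time_constant=7.0)
        mask = mask_for(("a",), ("a",))
        values = [weights_at_epoch(sched, mask, e)[0] for e in range(50)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Central finite differences vs backprop, relative error < 1e-5."""
        rng = np.random.default_rng(7)
        nf, hid, n = 10, 4, 6
        params = [rng.normal(scale=0.5, size=(nf, hid)), rng.normal(size=hid),
                  rng.normal(scale=0.5, size=(hid, nf)), rng.normal(size=nf)]
        x = rng.random((n, nf))
        theta = np.ones(nf)
        theta[[2, 3]] = 0.0
        omega = np.where(theta == 0, 2.0, 1.0)
        xg = x * theta
        _, grads = _loss_and_grads(params, x, xg, omega)
        eps = 1e-6
        for pi in range(4):
            flat = params[pi].ravel()
            idx = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for k in idx:
                orig = flat[k]
                flat[k] = orig + eps
                lp, _ = _loss_and_grads(params, x, xg, omega)
                flat[k] = orig - eps
                lm, _ = _loss_and_grads(params, x, xg, omega)
                flat[k] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[pi].ravel()[k]
                denom = max(abs(numeric), abs(analytic), 1e-8)
                assert abs(numeric - analytic) / denom < 1e-5


class TestEstimatorSurface:
    def test_sklearn_params_roundtrip(self):
        model = WGLAE(mechanism="order", n_dv=3, epochs=5)
        params = model.get_params()
        assert params["mechanism"] == "order"
        clone = WGLAE(**params)
        assert clone.get_params() == params
        model.set_params(n_dv=4)
        assert model.n_dv == 4

    def test_unfitted_reconstruct_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            WGLAE().reconstruct(np.zeros((1, 19, 8)))

    def test_dv_output_independent_of_blocked_input(self, montage4):
        rng = np.random.default_rng(5)
        data = rng.random((30, 4, 6))
        model = WGLAE(montage=montage4, mechanism="partition", n_dv=1,
                      epochs=3, learning_rate=1e-3, batch_size=16,
                      random_state=0)
        model.fit(data)
        a = data.copy()
        b = data.copy()
        b[:, 0, :] = rng.random((30, 6))  # only the blocked channel differs
        ra = model.reconstruct(a, missing=[model.labels_[0]])
        rb = model.reconstruct(b, missing=[model.labels_[0]])
        assert np.allclose(ra, rb)

    def test_reconstruct_equals_forward_of_zero_filled(self, montage4):
        rng = np.random.default_rng(6)
        data = rng.random((20, 4, 6))
        model = WGLAE(montage=montage4, mechanism="partition", n_dv=1,
                      epochs=3, learning_rate=1e-3, batch_size=16,
                      random_state=0, normalize=False)
        model.fit(data)
        blocked = model.labels_[2]
        i = model.labels_.index(blocked)
        zeroed = data.copy()
        zeroed[:, i, :] = 0.0
        from gatewave.model import forward

        direct = forward(model, zeroed.reshape(20, -1)).reshape(20, 4, 6)
        assert np.allclose(model.reconstruct(data, missing=[blocked]), direct)


from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(deadline=None, max_examples=30, derandomize=True)
@given(hnp.arrays(np.float64, (3, 6), elements=st.floats(0, 1)),
       hnp.arrays(np.float64, (3, 6), elements=st.floats(0, 1)),
       hnp.arrays(np.float64, (6,), elements=st.floats(0, 5)))
def test_property_weighted_loss_bounds(x, xh, omega):
    """Non-negative, zero iff weighted residuals vanish, and bounded above
    by max-weight times plain MSE."""
    loss = weighted_loss(x, xh, omega)
    assert loss >= 0.0
    mse = float(((xh - x) ** 2).mean())
    assert loss <= omega.max() * mse + 1e-12
    if loss == 0.0:
        assert np.all((omega * (xh - x) ** 2) == 0)
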