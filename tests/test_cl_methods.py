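"""LwF distillation, EWC Fisher, MAS importance, and the quadratic anchors."""

import numpy as np
import pytest

from clms import autodiff as ad, nn
from clms.autodiff import Tensor
from clms.cl_methods import (MethodState, distill, distillation_ce,
                             empirical_fisher, ewc_penalty, lwf_loss,
                             mas_importance, mas_penalty, penalty_gradient)


# ---------------------------------------------------------------------------
# distillation
# ---------------------------------------------------------------------------

def test_distill_identity_at_unit_temperature():
    assert np.allclose(distill([0.9, 0.1], 1.0), [0.9, 0.1])


def test_distill_closed_form_at_t2():
    # p^(1/2) renormalized: sqrt(0.9) : sqrt(0.1) = 3 : 1
    assert np.allclose(distill([0.9, 0.1], 2.0), [0.75, 0.25])


def test_distill_limit_is_uniform():
    out = distill([0.97, 0.02, 0.01], 1e6)
    assert np.allclose(out, [1 / 3] * 3, atol=1e-3)


def test_distill_rejects_zero_vector_and_bad_temperature():
    with pytest.raises(ValueError):
        distill([0.0, 0.0], 2.0)
    with pytest.raises(ValueError):
        distill([0.5, 0.5], 0.0)


def test_lwf_loss_reduces_to_new_task_loss_at_lambda_zero():
    assert lwf_loss(1.234, [[0.7, 0.3]], [[0.2, 0.8]], lam=0.0, temperature=2.0) == 1.234


def test_lwf_penalty_is_entropy_for_identical_uniform_outputs():
    total = lwf_loss(0.0, [[0.5, 0.5]], [[0.5, 0.5]], lam=1.0, temperature=1.0)
    assert np.isclose(total, np.log(2), atol=1e-9)


def test_lwf_penalty_hand_value_at_t2():
    # distill([0.9, 0.1], 2) = [0.75, 0.25]; penalty = entropy of that vector
    total = lwf_loss(0.0, [[0.9, 0.1]], [[0.9, 0.1]], lam=1.0, temperature=2.0)
    expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
    assert np.isclose(total, expected, atol=1e-6)
    assert np.isclose(expected, 0.5623, atol=1e-4)


def test_lwf_loss_rejects_mismatched_batches():
    with pytest.raises(ValueError):
        lwf_loss(0.0, [[0.5, 0.5]], [[0.5, 0.5], [0.4, 0.6]], 1.0, 1.0)


# ---------------------------------------------------------------------------
# Fisher estimation
# ---------------------------------------------------------------------------

def test_fisher_single_parameter_logistic_hand_value():
    theta = nn.Parameter(np.array([0.0]))
    # p(1|x) = sigmoid(theta * x), expressed as the two-class logits [0, theta*x]
    apply_fn = lambda x: ad.concat([Tensor([[0.0]]),
                                    ad.reshape(theta * Tensor(float(x)), (1, 1))], axis=1)
    f = empirical_fisher(apply_fn, [theta], [1.0], [1])
    assert np.allclose(f, [(1 - 0.5) ** 2]) and np.isclose(f[0], 0.25)


def test_fisher_of_unreachable_parameter_is_zero():
    used = nn.Parameter(np.array([0.3]))
    unused = nn.Parameter(np.array([1.7]))
    apply_fn = lambda x: ad.reshape(ad.concat([used * Tensor(x), -used * Tensor(x)]), (1, 2))
    f = empirical_fisher(apply_fn, [used, unused], [np.array([1.0])], [0])
    assert f[1] == 0.0 and f[0] > 0.0


def _toy_mlp(rng):
    lin1 = nn.Linear(2, 2, rng=rng)  # 6 params
    lin2 = nn.Linear(2, 2, rng=rng, bias=False)  # 4 params -> 10 total
    params = lin1.parameters() + lin2.parameters()
    apply_fn = lambda x: lin2(ad.tanh(lin1(Tensor(np.atleast_2d(x)))))
    return apply_fn, params


def _fd_logp_grad(apply_fn, params, x, y, eps=1e-6):
    def logp(flat):
        i = 0
        for p in params:
            p.data[...] = flat[i:i + p.data.size].reshape(p.data.shape)
            i += p.data.size
        with ad.no_grad():
            out = ad.log_softmax(apply_fn(x), axis=-1).data
        return out[0, y]
    flat0 = np.concatenate([p.data.ravel() for p in params])
    g = np.zeros_like(flat0)
    for i in range(flat0.size):
        up, dn = flat0.copy(), flat0.copy()
        up[i] += eps
        dn[i] -= eps
        g[i] = (logp(up) - logp(dn)) / (2 * eps)
    logp(flat0)  # restore
    return g


def test_fisher_matches_finite_difference_on_ten_parameter_toy():
    rng = np.random.default_rng(5)
    apply_fn, params = _toy_mlp(rng)
    xs = [rng.normal(size=2) for _ in range(4)]
    ys = [0, 1, 1, 0]
    f = empirical_fisher(apply_fn, params, xs, ys)
    expected = np.mean([_fd_logp_grad(apply_fn, params, x, y) ** 2
                        for x, y in zip(xs, ys)], axis=0)
    assert np.allclose(f, expected, rtol=1e-4, atol=1e-10)
    assert np.all(f >= 0)


# ---------------------------------------------------------------------------
# MAS importance
# ---------------------------------------------------------------------------

def test_mas_scalar_linear_toy_hand_value():
    theta = nn.Parameter(np.array([1.0]))
    apply_fn = lambda x: ad.reshape(theta * Tensor(float(x)), (1, 1))
    omega = mas_importance(apply_fn, [theta], [1.0, 2.0])
    assert np.isclose(omega[0], (abs(2 * 1.0) + abs(2 * 4.0)) / 2) and omega[0] == 5.0
    theta.data[...] = 0.0
    assert mas_importance(apply_fn, [theta], [1.0, 2.0])[0] == 0.0


def test_mas_matches_finite_difference_on_ten_parameter_toy():
    rng = np.random.default_rng(6)
    apply_fn, params = _toy_mlp(rng)
    xs = [rng.normal(size=2) for _ in range(4)]

    def fd_norm_grad(x, eps=1e-6):
        def norm2(flat):
            i = 0
            for p in params:
                p.data[...] = flat[i:i + p.data.size].reshape(p.data.shape)
                i += p.data.size
            with ad.no_grad():
                out = apply_fn(x).data
            return float((out ** 2).sum())
        flat0 = np.concatenate([p.data.ravel() for p in params])
        g = np.zeros_like(flat0)
        for i in range(flat0.size):
            up, dn = flat0.copy(), flat0.copy()
            up[i] += eps
            dn[i] -= eps
            g[i] = (norm2(up) - norm2(dn)) / (2 * eps)
        norm2(flat0)
        return g

    omega = mas_importance(apply_fn, params, xs)
    expected = np.mean([np.abs(fd_norm_grad(x)) for x in xs], axis=0)
    assert np.allclose(omega, expected, rtol=1e-4, atol=1e-10)


def test_importance_estimators_are_order_invariant():
    rng = np.random.default_rng(7)
    apply_fn, params = _toy_mlp(rng)
    xs = [rng.normal(size=2) for _ in range(5)]
    ys = [0, 1, 0, 1, 1]
    f1 = empirical_fisher(apply_fn, params, xs, ys)
    f2 = empirical_fisher(apply_fn, params, xs[::-1], ys[::-1])
    assert np.allclose(f1, f2)
    assert np.allclose(mas_importance(apply_fn, params, xs),
                       mas_importance(apply_fn, params, xs[::-1]))


# ---------------------------------------------------------------------------
# quadratic penalties
# ---------------------------------------------------------------------------

def _state(method, theta_old, weights, lam):
    kw = {"fisher": weights} if method == "EWC" else {"omega": weights}
    return MethodState(method_id=method, theta_old=theta_old, lam=lam, **kw)


def test_ewc_penalty_examples():
    st = _state("EWC", np.array([1.0, 2.0]), np.array([1.0, 2.0]), 1.0)
    assert ewc_penalty(np.array([1.0, 2.0]), st) == 0.0
    assert np.isclose(ewc_penalty(np.array([1.5, 1.0]), st), 1 * 0.25 + 2 * 1.0)
    st2 = _state("EWC", np.array([1.0, 2.0]), np.array([1.0, 2.0]), 2.0)
    assert np.isclose(ewc_penalty(np.array([1.5, 1.0]), st2),
                      2 * ewc_penalty(np.array([1.5, 1.0]), st))


def test_mas_penalty_example_and_structural_equivalence_to_ewc():
    st = _state("MAS", np.array([0.0]), np.array([5.0]), 2.0)
    assert np.isclose(mas_penalty(np.array([0.2]), st), 2 * 5 * 0.04)
    ewc_st = _state("EWC", np.array([0.0]), np.array([5.0]), 2.0)
    assert ewc_penalty(np.array([0.2]), ewc_st) == mas_penalty(np.array([0.2]), st)


def test_penalties_are_quadratic_and_nonnegative():
    rng = np.random.default_rng(8)
    theta_old = rng.normal(size=20)
    w = np.abs(rng.normal(size=20))
    st = _state("EWC", theta_old, w, 1.3)
    delta = rng.normal(size=20)
    p1 = ewc_penalty(theta_old + delta, st)
    p2 = ewc_penalty(theta_old + 2 * delta, st)
    assert p1 > 0 and np.isclose(p2, 4 * p1)
    assert ewc_penalty(theta_old, st) == 0.0


def test_penalty_index_mismatch_raises():
    st = _state("EWC", np.zeros(3), np.ones(3), 1.0)
    with pytest.raises(ValueError):
        ewc_penalty(np.zeros(4), st)
    with pytest.raises(ValueError):
        mas_penalty(np.zeros(3), st)  # EWC state carries no MAS weights


def test_lambda_zero_total_gradient_is_bitwise_new_task_gradient():
    rng = np.random.default_rng(9)
    lin = nn.Linear(3, 2, rng=rng)
    x = Tensor(rng.normal(size=(4, 3)))
    labels = np.array([0, 1, 1, 0])
    onehot = Tensor(np.eye(2)[labels])

    def ce():
        return -ad.mean_(ad.sum_(ad.log_softmax(lin(x), axis=1) * onehot, axis=1))

    g_plain = ad.grad(ce(), lin.parameters())
    old_probs = np.full((4, 2), 0.5)
    cur = ad.softmax(lin(x), axis=1)
    total = ce() + Tensor(0.0) * distillation_ce(old_probs, cur, 2.0)
    g_lwf = ad.grad(total, lin.parameters())
    for a, b in zip(g_plain, g_lwf):
        assert np.array_equal(a.data, b.data)
    # analytic quadratic-anchor gradient vanishes at lambda = 0
    st = _state("EWC", np.zeros(8), np.ones(8), 0.0)
    assert np.all(penalty_gradient(np.ones(8), st) == 0.0)
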