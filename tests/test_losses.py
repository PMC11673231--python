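import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mtlrank.losses import (
    discrete_loss_grad,
    loss_cox,
    loss_cox_grad,
    loss_deephit,
    loss_nmtlr,
    loss_nmtlr_rank,
    loss_pmf,
    loss_rank,
    pmf_from_phi,
    predict_discrete,
    reverse_cumsum,
)


def _unstabilized_pmf(phi):
    """High-precision literal transcription of the softmax formulas."""
    phi = np.asarray(phi, dtype=np.longdouble)
    e = np.exp(phi)
    denom = 1.0 + e.sum(axis=1, keepdims=True)
    pmf = np.concatenate([e / denom, 1.0 / denom], axis=1)
    S = 1.0 - np.cumsum(pmf[:, :-1], axis=1)
    return pmf.astype(float), S.astype(float)


class TestReverseCumsum:
    def test_example(self):
        np.testing.assert_allclose(reverse_cumsum(np.array([[1.0, 2, 3]])), [[6, 5, 3]])

    def test_zeros_and_m1(self):
        np.testing.assert_array_equal(reverse_cumsum(np.zeros((2, 3))), 0.0)
        np.testing.assert_array_equal(reverse_cumsum(np.array([[4.0]])), [[4.0]])


class TestPmfFromPhi:
    def test_uniform_softmax(self):
        pred = pmf_from_phi(np.zeros((1, 3)))
        np.testing.assert_allclose(pred.pmf[0], 0.25)
        np.testing.assert_allclose(pred.S_at_cuts[0], [0.75, 0.5, 0.25])

    def test_saturation(self):
        pred = pmf_from_phi(np.array([[50.0, 0.0, 0.0]]))
        assert pred.pmf[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert pred.S_at_cuts[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_against_unstabilized_oracle(self):
        phi = np.array([[1.0, -1.0]])
        pred = pmf_from_phi(phi)
        np.testing.assert_allclose(pred.pmf[0, :2], [0.66524096, 0.09003057], atol=1e-7)
        pmf_o, S_o = _unstabilized_pmf(phi)
        np.testing.assert_allclose(pred.pmf, pmf_o, atol=1e-14)
        np.testing.assert_allclose(pred.S_at_cuts, S_o, atol=1e-14)

    @given(
        hnp.arrays(np.float64, (4, 6), elements=st.floats(-30, 30)),
    )
    @settings(deadline=None, max_examples=100)
    def test_rows_sum_to_one_and_survival_monotone(self, phi):
        pred = pmf_from_phi(phi)
        np.testing.assert_allclose(pred.pmf.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(pred.pmf >= 0)
        assert np.all(np.diff(pred.S_at_cuts, axis=1) <= 1e-12)
        assert np.all((pred.S_at_cuts >= 0) & (pred.S_at_cuts <= 1))


class TestLossPmf:
    def test_uniform_event_and_censored(self):
        pred = pmf_from_phi(np.zeros((1, 2)))  # masses 1/3 each, S1 = 2/3
        assert loss_pmf(pred, [1], [1]) == pytest.approx(-np.log(1 / 3))
        assert loss_pmf(pred, [1], [0]) == pytest.approx(-np.log(2 / 3))

    def test_event_in_interval_two(self):
        pred = pmf_from_phi(np.array([[1.0, -1.0]]))
        assert loss_pmf(pred, [2], [1]) == pytest.approx(-np.log(0.09003057), abs=1e-6)


class TestLossNmtlr:
    def test_equivalence_to_pmf_of_reverse_cumsum(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            psi = rng.normal(size=(20, 5))
            k = rng.integers(1, 6, 20)
            d = rng.integers(0, 2, 20)
            direct = loss_nmtlr(psi, k, d)
            two_step = loss_pmf(pmf_from_phi(reverse_cumsum(psi)), k, d)
            assert direct == pytest.approx(two_step, abs=1e-12)

    def test_zero_psi_reduces_to_uniform(self):
        assert loss_nmtlr(np.zeros((1, 2)), [1], [1]) == pytest.approx(-np.log(1 / 3))


def _two_subject_fixture():
    """S_i(k)=0.2, S_j(k)=0.9 at subject i's interval; one comparable pair."""
    # phi rows chosen so S at cut 1 equals 0.2 / 0.9 exactly:
    # S_1 = 1 - sigma_1; one-interval logits: sigma_1 = e^phi/(1+e^phi)
    phi_i = np.log(0.8 / 0.2)
    phi_j = np.log(0.1 / 0.9)
    pred = pmf_from_phi(np.array([[phi_i], [phi_j]]))
    time = np.array([1.0, 2.0])
    event = np.array([1, 0])
    k = np.array([1, 1])
    return pred, k, event, time


class TestLossRank:
    def test_identical_curves_give_exp_zero(self):
        pred = pmf_from_phi(np.zeros((2, 3)))
        out = loss_rank(pred, [1, 1], [1, 0], [1.0, 2.0], beta=1.0)
        assert out == pytest.approx(1.0)

    def test_hand_value(self):
        pred, k, event, time = _two_subject_fixture()
        out = loss_rank(pred, k, event, time, beta=0.48)
        assert out == pytest.approx(np.exp((0.2 - 0.9) / 0.48), abs=1e-9)

    def test_all_censored_gives_zero(self):
        pred = pmf_from_phi(np.random.default_rng(0).normal(size=(4, 3)))
        assert loss_rank(pred, [1, 2, 3, 1], [0, 0, 0, 0], [1, 2, 3, 4], beta=1.0) == 0.0

    def test_brute_force_pair_oracle(self):
        rng = np.random.default_rng(9)
        n, m = 15, 4
        pred = pmf_from_phi(rng.normal(size=(n, m)))
        time = rng.uniform(1, 10, n)
        event = rng.integers(0, 2, n)
        k = rng.integers(1, m + 1, n)
        beta = 0.7
        total, n_pairs = 0.0, 0
        for i in range(n):
            for j in range(n):
                if event[i] == 1 and time[i] < time[j]:
                    si = pred.S_at_cuts[i, k[i] - 1]
                    sj = pred.S_at_cuts[j, k[i] - 1]
                    total += np.exp((si - sj) / beta)
                    n_pairs += 1
        assert loss_rank(pred, k, event, time, beta) == pytest.approx(total / n_pairs)

    def test_translation_invariance_of_pairwise_term(self):
        # shifting BOTH subjects' survival at the compared interval by the
        # same constant cancels in the difference
        pred, k, event, time = _two_subject_fixture()
        base = loss_rank(pred, k, event, time, beta=0.48)
        shifted = pred
        shifted.S_at_cuts = pred.S_at_cuts + 0.05
        assert loss_rank(shifted, k, event, time, beta=0.48) == pytest.approx(base)

    def test_beta_must_be_positive(self):
        pred = pmf_from_phi(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            loss_rank(pred, [1, 1], [1, 0], [1, 2], beta=0.0)


class TestCompositeLosses:
    def test_deephit_alpha_reductions(self):
        pred, k, event, time = _two_subject_fixture()
        assert loss_deephit(pred, k, event, time, 1.0, 0.48) == pytest.approx(
            loss_pmf(pred, k, event)
        )
        assert loss_deephit(pred, k, event, time, 0.0, 0.48) == pytest.approx(
            loss_rank(pred, k, event, time, 0.48)
        )

    def test_deephit_linear_combination(self):
        pred, k, event, time = _two_subject_fixture()
        expected = 0.25 * loss_pmf(pred, k, event) + 0.75 * loss_rank(pred, k, event, time, 0.48)
        assert loss_deephit(pred, k, event, time, 0.25, 0.48) == pytest.approx(expected)

    def test_nmtlr_rank_component_recomposition(self):
        rng = np.random.default_rng(13)
        psi = rng.normal(size=(10, 4))
        k = rng.integers(1, 5, 10)
        event = rng.integers(0, 2, 10)
        event[0] = 1
        time = rng.uniform(1, 10, 10)
        pred = predict_discrete(psi)
        expected = 0.25 * loss_pmf(pred, k, event) + 0.75 * loss_rank(pred, k, event, time, 0.48)
        assert loss_nmtlr_rank(psi, k, event, time, 0.25, 0.48) == pytest.approx(expected, abs=1e-12)

    def test_alpha_out_of_range(self):
        pred, k, event, time = _two_subject_fixture()
        with pytest.raises(ValueError):
            loss_deephit(pred, k, event, time, 1.5, 1.0)


class TestLossCox:
    def test_null_model_two_events(self):
        assert loss_cox(np.zeros(2), [1.0, 2.0], [1, 1]) == pytest.approx(
            (np.log(2) + np.log(1)) / 2
        )

    def test_singleton_risk_set(self):
        assert loss_cox(np.array([3.0]), [5.0], [1]) == pytest.approx(0.0)

    def test_hand_partial_likelihood(self):
        got = loss_cox(np.array([1.0, 0.0]), np.array([1.0, 2.0]), np.array([1, 1]))
        assert got == pytest.approx((-1 + np.log(np.e + 1) + 0.0) / 2, abs=1e-9)

    def test_brute_force_risk_set_oracle(self):
        rng = np.random.default_rng(21)
        n = 12
        theta = rng.normal(size=n)
        time = rng.choice(np.arange(1.0, 9.0), n)  # forces ties
        event = rng.integers(0, 2, n)
        event[0] = 1
        total = 0.0
        for j in range(n):
            if event[j]:
                risk = np.exp(theta[time >= time[j]]).sum()
                total -= theta[j] - np.log(risk)
        assert loss_cox(theta, time, event) == pytest.approx(total / event.sum(), abs=1e-10)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            loss_cox(np.zeros(3), [1, 2, 3], [0, 0, 0])


class TestGradients:
    """Analytic gradients vs central differences (the trainer's contract)."""

    @pytest.mark.parametrize("alpha,use_cumsum", [(1.0, True), (0.25, True), (0.0, True), (0.4, False)])
    def test_discrete_loss_grad(self, alpha, use_cumsum):
        rng = np.random.default_rng(3)
        n, m = 10, 4
        psi = rng.normal(size=(n, m))
        k = rng.integers(1, m + 1, n)
        event = rng.integers(0, 2, n)
        event[:2] = 1
        time = rng.uniform(1, 10, n)
        _, g = discrete_loss_grad(psi, k, event, time, alpha, 0.48, use_cumsum=use_cumsum)
        eps = 1e-6
        for i in range(n):
            for j in range(m):
                up, dn = psi.copy(), psi.copy()
                up[i, j] += eps
                dn[i, j] -= eps
                lu, _ = discrete_loss_grad(up, k, event, time, alpha, 0.48, use_cumsum=use_cumsum)
                ld, _ = discrete_loss_grad(dn, k, event, time, alpha, 0.48, use_cumsum=use_cumsum)
                assert g[i, j] == pytest.approx((lu - ld) / (2 * eps), abs=1e-6)

    def test_cox_grad(self):
        rng = np.random.default_rng(4)
        n = 10
        theta = rng.normal(size=n)
        time = rng.choice(np.arange(1.0, 7.0), n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        _, g = loss_cox_grad(theta, time, event)
        eps = 1e-6
        for i in range(n):
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            assert g[i] == pytest.approx(
                (loss_cox(up, time, event) - loss_cox(dn, time, event)) / (2 * eps), abs=1e-6
            )


class TestPermutationInvariance:
    def test_all_losses_invariant_to_subject_order(self):
        rng = np.random.default_rng(17)
        n, m = 15, 4
        psi = rng.normal(size=(n, m))
        k = rng.integers(1, m + 1, n)
        event = rng.integers(0, 2, n)
        event[:3] = 1
        time = rng.uniform(1, 10, n)
        perm = rng.permutation(n)
        assert loss_nmtlr_rank(psi, k, event, time, 0.3, 0.5) == pytest.approx(
            loss_nmtlr_rank(psi[perm], k[perm], event[perm], time[perm], 0.3, 0.5), abs=1e-12
        )
        assert loss_cox(psi[:, 0], time, event) == pytest.approx(
            loss_cox(psi[perm, 0], time[perm], event[perm]), abs=1e-12
        )


def test_losses_decrease_under_gradient_descent():
    """Smoke: 200 plain gradient steps reduce the composite loss."""
    rng = np.random.default_rng(8)
    n, m = 20, 5
    psi = rng.normal(scale=0.1, size=(n, m))
    k = rng.integers(1, m + 1, n)
    event = rng.integers(0, 2, n)
    event[:5] = 1
    time = rng.uniform(1, 10, n)
    l0, _ = discrete_loss_grad(psi, k, event, time, 0.25, 0.48)
    for _ in range(200):
        _, g = discrete_loss_grad(psi, k, event, time, 0.25, 0.48)
        psi -= 0.5 * g
    l1, _ = discrete_loss_grad(psi, k, event, time, 0.25, 0.48)
    assert l1 < l0
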