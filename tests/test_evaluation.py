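import numpy as np
import pytest

from mtlrank.evaluation import (
    brier_score,
    c_index_td,
    integrated_brier_score,
    km_estimator,
)


class TestKMEstimator:
    def test_no_events_is_flat_one(self):
        km = km_estimator([1.0, 2.0, 3.0], [0, 0, 0])
        np.testing.assert_allclose(km.predict([0.5, 2.5, 10.0]), 1.0)

    def test_hand_product_limit(self):
        km = km_estimator([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.predict(1.0) == pytest.approx(2 / 3)
        assert km.predict(2.0) == pytest.approx(2 / 3)
        assert km.predict(3.0) == pytest.approx(0.0)

    def test_all_events_matches_ecdf(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        km = km_estimator(t, np.ones(4))
        np.testing.assert_allclose(km.predict(t), 1 - np.arange(1, 5) / 4)

    def test_left_limit(self):
        km = km_estimator([1.0, 2.0], [1, 1])
        assert km.predict_left(1.0) == pytest.approx(1.0)
        assert km.predict(1.0) == pytest.approx(0.5)


def _curves_from_risk(risk, eval_times, scale=1.0):
    return np.exp(-np.outer(risk, eval_times) * scale)


class TestCIndexTD:
    def test_perfect_ordering_is_one(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(1, 100, 40))
        ev_times = np.linspace(0, 100, 50)
        S = _curves_from_risk(1 / t, ev_times)
        assert c_index_td(S, ev_times, t, np.ones(40)) == 1.0

    def test_random_predictions_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        T = rng.exponential(1000, n)
        C = rng.uniform(0, 3500, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
        ev_times = np.linspace(0, time.max(), 100)
        S = _curves_from_risk(rng.exponential(1 / 1000, n), ev_times)
        assert c_index_td(S, ev_times, time, event) == pytest.approx(0.5, abs=0.02)

    def test_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(12)
        n = 25
        time = rng.uniform(1, 50, n)
        event = rng.integers(0, 2, n)
        event[:5] = 1
        ev_times = np.linspace(0, 50, 30)
        S = rng.uniform(0, 1, size=(n, len(ev_times)))
        S = np.sort(S, axis=1)[:, ::-1]

        def interp(row, t):
            return np.interp(t, ev_times, S[row])

        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                comparable = event[i] == 1 and (
                    time[i] < time[j] or (time[i] == time[j] and event[j] == 0)
                )
                if comparable:
                    si, sj = interp(i, time[i]), interp(j, time[i])
                    num += 1.0 if si < sj else (0.5 if si == sj else 0.0)
                    den += 1
        assert c_index_td(S, ev_times, time, event) == pytest.approx(num / den, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        n = 30
        time = rng.uniform(1, 50, n)
        event = np.ones(n)
        ev_times = np.linspace(0, 50, 200)
        S = np.sort(rng.uniform(0, 1, (n, 200)), axis=1)[:, ::-1]
        c1 = c_index_td(S, ev_times, time, event)
        c2 = c_index_td(S**3, ev_times, time, event)  # strictly monotone map
        # interpolation is nonlinear under the transform; allow grid-level slack
        assert c1 == pytest.approx(c2, abs=0.02)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        n = 40
        time = rng.uniform(1, 50, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        ev_times = np.linspace(0, 50, 30)
        S = np.sort(rng.uniform(0, 1, (n, 30)), axis=1)[:, ::-1]
        perm = rng.permutation(n)
        assert c_index_td(S, ev_times, time, event) == pytest.approx(
            c_index_td(S[perm], ev_times, time[perm], event[perm])
        )

    def test_no_comparable_pairs_errors(self):
        S = np.ones((2, 3)) * 0.5
        with pytest.raises(ValueError):
            c_index_td(S, np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0]), np.array([0, 0]))


class TestBrierScore:
    def test_oracle_predictions_no_censoring_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        ev_times = np.linspace(0, 4, 400)
        S = (ev_times[None, :] < t[:, None]).astype(float)
        for te in [0.5, 1.5, 3.5]:
            assert brier_score(S, ev_times, t, np.ones(4), te) == pytest.approx(0.0, abs=1e-4)

    def test_constant_half_prediction(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        ev_times = np.linspace(0, 4, 10)
        S = np.full((4, 10), 0.5)
        for te in [0.5, 2.5]:
            assert brier_score(S, ev_times, t, np.ones(4), te) == pytest.approx(0.25)

    def test_no_censoring_equals_plain_mse(self):
        rng = np.random.default_rng(6)
        n = 30
        t = rng.uniform(1, 10, n)
        ev_times = np.linspace(0, 10, 100)
        S = np.sort(rng.uniform(0, 1, (n, 100)), axis=1)[:, ::-1]
        te = 5.0
        S_te = np.array([np.interp(te, ev_times, S[i]) for i in range(n)])
        status = (t > te).astype(float)  # 1 = still event-free
        expected = np.mean((status - S_te) ** 2)
        assert brier_score(S, ev_times, t, np.ones(n), te) == pytest.approx(expected, abs=1e-10)

    def test_hand_ipcw_sum(self):
        # n=5: deaths at 2 and 6, censorings at 4, 8; alive past 10
        time = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        event = np.array([1, 0, 1, 0, 0])
        ev_times = np.linspace(0, 10, 101)
        rng = np.random.default_rng(7)
        S = np.sort(rng.uniform(0, 1, (5, 101)), axis=1)[:, ::-1]
        te = 7.0
        # censoring KM G: censorings at 4 (4 at risk) and 8 (2 at risk)
        # => G(t) = 1 for t < 4; 3/4 for 4 <= t < 8; 3/8 for t >= 8
        S_te = np.array([np.interp(te, ev_times, S[i]) for i in range(5)])
        expected = (
            S_te[0] ** 2 / 1.0  # death at 2: weight 1/G(2-) = 1
            + 0.0  # censored at 4 < te: no contribution
            + S_te[2] ** 2 / (3 / 4)  # death at 6: 1/G(6-) = 4/3
            + (1 - S_te[3]) ** 2 / (3 / 4)  # t=8 > te: 1/G(7) = 4/3
            + (1 - S_te[4]) ** 2 / (3 / 4)
        ) / 5
        assert brier_score(S, ev_times, time, event, te) == pytest.approx(expected, abs=1e-10)


class TestIntegratedBrierScore:
    def test_constant_bs_integrates_to_itself(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        ev_times = np.linspace(0, 4, 10)
        S = np.full((4, 10), 0.5)
        assert integrated_brier_score(S, ev_times, t, np.ones(4)) == pytest.approx(0.25)

    def test_oracle_no_censoring_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        ev_times = np.linspace(0, 4, 800)
        S = (ev_times[None, :] < t[:, None]).astype(float)
        assert integrated_brier_score(S, ev_times, t, np.ones(4)) == pytest.approx(0.0, abs=5e-3)

    def test_quadrature_refinement(self):
        # KM marginal predictor: 100-point trapezoid within 1e-3 of a 10^4-point grid
        rng = np.random.default_rng(9)
        n = 80
        T = rng.exponential(5, n)
        C = rng.uniform(0, 12, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
        km = km_estimator(time, event)
        ev_times = np.linspace(0, time.max(), 500)
        S = np.tile(km.predict(ev_times), (n, 1))
        coarse = integrated_brier_score(S, ev_times, time, event)
        fine = integrated_brier_score(
            S, ev_times, time, event, grid=np.linspace(0, time.max(), 10_000)
        )
        assert coarse == pytest.approx(fine, abs=1e-3)

    def test_cross_check_against_scikit_survival(self):
        from sksurv.metrics import brier_score as sks_brier
        from sksurv.util import Surv

        rng = np.random.default_rng(10)
        n = 60
        T = rng.exponential(5, n)
        C = rng.uniform(0, 12, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(bool)
        ev_times = np.linspace(0, time.max(), 300)
        km = km_estimator(time, event)
        S = np.tile(km.predict(ev_times), (n, 1))
        y = Surv.from_arrays(event, time)
        t_evals = np.quantile(time, [0.2, 0.4, 0.6])
        S_at = np.column_stack([np.interp(te, ev_times, S[0]) * np.ones(n) for te in t_evals])
        _, sks = sks_brier(y, y, S_at, t_evals)
        ours = [brier_score(S, ev_times, time, event, te) for te in t_evals]
        np.testing.assert_allclose(ours, sks, atol=5e-3)
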