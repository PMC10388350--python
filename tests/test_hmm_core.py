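import numpy as np
import pytest

from _oracles import brute_loglik, brute_viterbi, random_model_and_burst
from photonhmm import hmm
from photonhmm.hmm import (
    H2MMModel,
    PhotonHMM,
    PhotonRecords,
    burst_loglik,
    forward_backward,
    rate_matrix_from_transition,
    viterbi,
)


def _records(colors, gaps, clock=12.5e-9):
    return PhotonRecords.from_arrays(np.asarray(colors, np.int8),
                                     np.asarray(gaps, np.int64), clock)


def _model(Q, E, p0, clock=12.5e-9):
    return H2MMModel(np.asarray(Q, float), np.asarray(E, float),
                     np.asarray(p0, float), clock)


class TestForwardOracle:
    def test_single_acceptor_photon_closed_form(self):
        E = np.array([0.8, 0.3])
        p0 = np.array([0.6, 0.4])
        m = _model(np.array([[-1e3, 1e3], [2e3, -2e3]]), E, p0)
        rec = _records([1], [0])
        ll, gamma, _ = forward_backward(m, rec)
        assert ll == pytest.approx(np.log(p0 @ E), abs=1e-12)
        assert burst_loglik(m, rec) == pytest.approx(ll, abs=1e-12)

    def test_frozen_two_state_five_photons(self):
        # expected value computed once with the exhaustive-path oracle
        Q = np.array([[-3000.0, 3000.0], [1500.0, -1500.0]])
        E = np.array([0.9, 0.2])
        p0 = np.array([0.5, 0.5])
        colors = [1, 0, 1, 1, 0]
        gaps = [0, 400, 1200, 80, 2500]
        expected = brute_loglik(Q, E, p0, np.array(colors),
                                np.array(gaps), 12.5e-9)
        ll = burst_loglik(_model(Q, E, p0), _records(colors, gaps))
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_static_identity_transitions_posteriors(self):
        # Q = 0 and a point-mass p0: all posterior mass stays on state 1
        m = _model(np.zeros((3, 3)), [0.5, 0.5, 0.5], [1.0, 0.0, 0.0])
        _, gamma, _ = forward_backward(m, _records([0, 1, 0], [0, 100, 100]))
        np.testing.assert_allclose(gamma[:, 0], 1.0, atol=1e-12)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(11)
        Q, E, p0, colors, gaps, clock = random_model_and_burst(rng)
        _, gamma, _ = forward_backward(_model(Q, E, p0, clock),
                                       _records(colors, gaps, clock))
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)

    def test_long_burst_no_underflow(self):
        rng = np.random.default_rng(2)
        n = 20000
        colors = rng.integers(0, 2, n).astype(np.int8)
        gaps = np.concatenate([[0], rng.integers(100, 2000, n - 1)])
        m = _model(np.array([[-3e3, 3e3], [3e3, -3e3]]), [0.8, 0.2], [0.5, 0.5])
        ll = burst_loglik(m, _records(colors, gaps))
        assert np.isfinite(ll)


class TestViterbiOracle:
    def test_identity_transitions_constant_path(self):
        m = _model(np.zeros((2, 2)), [0.9, 0.1], [0.3, 0.7])
        path, segs, best = viterbi(m, _records([1, 1, 1], [0, 100, 100]))
        # p0 slightly favors state 2, emissions strongly favor state 1;
        # with no transitions allowed the path is constant at the argmax
        assert len(set(path.tolist())) == 1
        assert len(segs[0]) == 1

    def test_pure_acceptor_burst_goes_to_high_e_state(self):
        Q = np.array([[-1.0, 1.0], [1.0, -1.0]])  # nearly static
        m = _model(Q, [0.9, 0.1], [0.5, 0.5])
        path, _, _ = viterbi(m, _records([1] * 8, [0] + [800] * 7))
        assert (path == 0).all()

    def test_frozen_two_state_six_photons(self):
        Q = np.array([[-4000.0, 4000.0], [2000.0, -2000.0]])
        E = np.array([0.85, 0.25])
        p0 = np.array([0.4, 0.6])
        colors = np.array([1, 1, 0, 0, 1, 0])
        gaps = np.array([0, 900, 150, 3000, 60, 700])
        ref_path, ref_lp = brute_viterbi(Q, E, p0, colors, gaps, 12.5e-9)
        path, _, lp = viterbi(_model(Q, E, p0), _records(colors, gaps))
        assert lp == pytest.approx(ref_lp, abs=1e-9)
        np.testing.assert_array_equal(path, ref_path)


class TestEMFit:
    def test_one_state_closed_form_mle(self):
        rng = np.random.default_rng(1)
        colors = (rng.random(4000) < 0.37).astype(np.int8)
        gaps = np.concatenate([[0], rng.integers(200, 2000, 3999)])
        rec = _records(colors, gaps)
        res = PhotonHMM(rec, 1).fit(restarts=1, max_iter=50, seed=0)
        assert res.efficiencies[0] == pytest.approx(colors.mean(), abs=1e-6)

    def test_loglik_trace_non_decreasing(self, apo_dataset):
        _, _, _, rec = apo_dataset
        res = PhotonHMM(rec, 3).fit(restarts=2, max_iter=25, restart_iter=8, seed=0)
        assert np.all(np.diff(res.loglik_trace) >= -1e-9)

    def test_canonical_state_order(self, apo_dataset):
        _, _, _, rec = apo_dataset
        res = PhotonHMM(rec, 3).fit(restarts=1, max_iter=15, seed=1)
        assert np.all(np.diff(res.efficiencies) <= 0)

    def test_degenerate_states_flagged(self):
        rng = np.random.default_rng(5)
        colors = (rng.random(3000) < 0.4).astype(np.int8)
        gaps = np.concatenate([[0], rng.integers(200, 2000, 2999)])
        res = PhotonHMM(_records(colors, gaps), 3).fit(restarts=1,
                                                       max_iter=40, seed=0)
        assert len(res.degenerate_states) > 0

    def test_expected_jump_counts_match_truth(self, apo_dataset, apo_true_hmm):
        # E-step sufficient statistics vs the generating paths' jump counts
        _, _, truth, rec = apo_dataset
        _, _, N = forward_backward(apo_true_hmm, rec)
        true_jumps = sum(max(len(s) - 1, 0) for s in truth.states)
        # only jumps inside the photon-observed span are inferable; the path
        # also runs before the first and after the last photon (~10% of time)
        assert 0.75 * true_jumps <= N.sum() <= 1.05 * true_jumps

    def test_summary_mentions_states_and_loglik(self, apo_dataset):
        _, _, _, rec = apo_dataset
        res = PhotonHMM(rec, 2).fit(restarts=1, max_iter=10, seed=0)
        s = res.summary()
        assert "log-likelihood" in s and "rate matrix" in s


class TestGlobalFit:
    def test_identical_datasets_match_single_fit(self, apo_dataset):
        _, _, _, rec = apo_dataset
        single = PhotonHMM(rec, 2).fit(restarts=1, max_iter=60, seed=0,
                                       tol=1e-9)
        both = hmm.GlobalPhotonHMM({"a": rec, "b": rec}, 2).fit(
            restarts=1, max_iter=60, seed=0, tol=1e-9)
        np.testing.assert_allclose(both.efficiencies, single.efficiencies,
                                   atol=1e-3)
        np.testing.assert_allclose(both.rate_matrix("a"),
                                   both.rate_matrix("b"), rtol=1e-6)

    def test_requires_two_datasets(self, apo_dataset):
        _, _, _, rec = apo_dataset
        with pytest.raises(ValueError):
            hmm.GlobalPhotonHMM({"a": rec}, 2)


class TestModelContainer:
    def test_json_round_trip(self, tmp_path, apo_true_hmm):
        p = tmp_path / "m.json"
        apo_true_hmm.to_json(p)
        m = H2MMModel.from_json(p)
        np.testing.assert_allclose(m.rate_matrix, apo_true_hmm.rate_matrix)
        np.testing.assert_allclose(m.efficiencies, apo_true_hmm.efficiencies)

    def test_transition_matrix_is_stochastic(self, apo_true_hmm):
        T = apo_true_hmm.transition_matrix(1000)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert (T >= 0).all()

    def test_rate_matrix_from_transition_inverts_expm(self, apo_true_hmm):
        T = apo_true_hmm.transition_matrix(1)
        Q = rate_matrix_from_transition(T, apo_true_hmm.clock_period)
        np.testing.assert_allclose(Q, apo_true_hmm.rate_matrix, rtol=1e-6,
                                   atol=1e-4)

    def test_canonical_order_permutes_consistently(self):
        Q = np.array([[-100.0, 60.0, 40.0], [10.0, -30.0, 20.0],
                      [5.0, 15.0, -20.0]])
        m = H2MMModel(Q, np.array([0.2, 0.9, 0.5]), np.array([0.2, 0.3, 0.5]))
        c = m.canonical_order()
        np.testing.assert_array_equal(c.efficiencies, [0.9, 0.5, 0.2])
        # rate from old state 2 (E=0.9) to old state 3 (E=0.5): Q[1,2]
        assert c.rate_matrix[0, 1] == Q[1, 2]
        assert c.initial_distribution[0] == 0.3
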