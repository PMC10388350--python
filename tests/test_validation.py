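import numpy as np
import pytest
from scipy.optimize import curve_fit

from photonhmm import simulate, validation
from photonhmm.hmm import H2MMModel, PhotonRecords
from photonhmm.validation import (
    burstwise_fcs,
    recolor_records,
    sample_posterior_paths,
    segment_histograms,
    weighted_dwell_times,
)


class TestRecoloring:
    def test_full_transfer_model_all_acceptor(self, apo_dataset):
        _, _, _, rec = apo_dataset
        m = H2MMModel(np.zeros((1, 1)), np.array([1.0]), np.array([1.0]))
        out = recolor_records(m, rec, seed=0)
        assert (out.colors == 1).all()
        np.testing.assert_array_equal(out.gaps_s, rec.gaps_s)
        np.testing.assert_array_equal(out.ptr, rec.ptr)

    def test_determinism(self, apo_true_hmm, apo_dataset):
        _, _, _, rec = apo_dataset
        a = recolor_records(apo_true_hmm, rec, seed=42)
        b = recolor_records(apo_true_hmm, rec, seed=42)
        np.testing.assert_array_equal(a.colors, b.colors)

    def test_color_marginal_matches_model(self, apo_true_hmm, apo_dataset):
        _, _, _, rec = apo_dataset
        out = recolor_records(apo_true_hmm, rec, seed=1)
        pi = apo_true_hmm.stationary
        expect = float(pi @ apo_true_hmm.efficiencies)
        n = out.n_photons
        se = np.sqrt(expect * (1 - expect) / n) * 2  # paths add correlation
        assert abs(out.colors.mean() - expect) < 4 * se


class TestPosteriorPaths:
    def test_determinism_and_state_range(self, apo_true_hmm, apo_dataset):
        _, _, _, rec = apo_dataset
        a = sample_posterior_paths(apo_true_hmm, rec, seed=3)
        b = sample_posterior_paths(apo_true_hmm, rec, seed=3)
        np.testing.assert_array_equal(a, b)
        assert set(np.unique(a)) <= set(range(4))

    def test_occupancy_matches_stationary(self, apo_true_hmm, apo_dataset):
        _, _, _, rec = apo_dataset
        s = sample_posterior_paths(apo_true_hmm, rec, seed=4)
        occ = np.bincount(s, minlength=4) / s.size
        np.testing.assert_allclose(occ, apo_true_hmm.stationary, atol=0.03)


class TestDwellTimes:
    def test_two_state_exponential_holding_time(self, two_state_model,
                                                two_state_dataset):
        # symmetric k = 2000/s: mean dwell 500 us in both states
        _, _, _, rec = two_state_dataset
        m = H2MMModel(two_state_model.rate_matrix, two_state_model.efficiencies,
                      np.array([0.5, 0.5]))
        dw = weighted_dwell_times(m, rec, seed=0)
        np.testing.assert_allclose(dw.tau, 500e-6, rtol=0.10)

    def test_apo_analytic_means(self, apo_true_hmm, apo_dataset):
        _, _, _, rec = apo_dataset
        dw = weighted_dwell_times(apo_true_hmm, rec, seed=0)
        # fixture algebra: state-1 mean dwell 1/(c(1-pi1)) ~ 364 us
        assert dw.tau_analytic[0] == pytest.approx(364e-6, abs=2e-6)

    def test_no_transition_model_flagged(self, apo_dataset):
        _, _, _, rec = apo_dataset
        m = H2MMModel(np.zeros((2, 2)), np.array([0.8, 0.2]),
                      np.array([0.5, 0.5]))
        dw = weighted_dwell_times(m, rec, seed=0)
        # no exits are ever observed: every state is censored-only or empty
        assert len(dw.flagged) == 2
        assert np.isnan(dw.tau).all()

    def test_frame_layout(self, apo_true_hmm, apo_dataset):
        _, _, _, rec = apo_dataset
        df = weighted_dwell_times(apo_true_hmm, rec, seed=0).to_frame()
        assert {"state", "tau_s", "tau_analytic_s"} <= set(df.columns)
        assert len(df) == 4


class TestSegmentHistograms:
    def test_static_data_single_group(self):
        m = simulate.GroundTruthModel(np.zeros((1, 1)), np.array([0.6]))
        stream, bursts, _ = simulate.simulate_dataset(m, 100, seed=8)
        rec = PhotonRecords.from_stream(stream, bursts)
        model = H2MMModel(np.array([[-1.0, 1.0], [1.0, -1.0]]),
                          np.array([0.6, 0.1]), np.array([0.9, 0.1]))
        sh = segment_histograms(model, rec)
        assert sh.counts.get(0, 0) >= 0.95 * rec.n_bursts

    def test_group_means_near_state_efficiencies(self):
        # slow-exchange 4-state model: single-state bursts are pure, so the
        # group mean burst-E is the conditional binomial mean E_i
        pi = simulate.FIXTURE_POPULATIONS["apo"]
        Q = 400.0 * np.tile(pi, (4, 1))
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        E = simulate.MICROSTATE_EFFICIENCIES.copy()
        m = simulate.GroundTruthModel(Q, E)
        stream, bursts, _ = simulate.simulate_dataset(m, 600, seed=41)
        rec = PhotonRecords.from_stream(stream, bursts)
        sh = segment_histograms(H2MMModel(Q, E, pi), rec)
        for state in sh.states:
            if sh.counts[state] < 20:
                continue
            assert abs(sh.mean_e[state] - E[state]) < 0.03

    def test_apo_group_means_strictly_ordered(self, apo_true_hmm, apo_dataset):
        # at fixture-scale exchange the groups are less pure, but their mean
        # burst-E values still separate in state order
        _, _, _, rec = apo_dataset
        sh = segment_histograms(apo_true_hmm, rec)
        means = [sh.mean_e[s] for s in sh.states]
        assert np.all(np.diff(means) < 0)

    def test_fast_exchange_yields_few_single_state_bursts(self):
        Q = np.array([[-1e5, 1e5], [1e5, -1e5]])
        m = simulate.GroundTruthModel(Q, np.array([0.9, 0.1]))
        stream, bursts, _ = simulate.simulate_dataset(m, 150, seed=9)
        rec = PhotonRecords.from_stream(stream, bursts)
        model = H2MMModel(Q, np.array([0.9, 0.1]), np.array([0.5, 0.5]))
        sh = segment_histograms(model, rec)
        assert sum(sh.counts.values()) < 0.2 * rec.n_bursts


class TestBurstwiseFCS:
    def test_static_poisson_flat(self):
        m = simulate.GroundTruthModel(np.zeros((1, 1)), np.array([0.45]))
        stream, bursts, _ = simulate.simulate_dataset(m, 900, seed=10)
        c = burstwise_fcs(stream, bursts, "DxA")
        assert np.abs(c.G - 1).max() < 0.03
        assert np.all(np.diff(c.lags) > 0)

    def test_two_state_exchange_timescale(self):
        # exchange at k_total = 4000/s: correlation relaxation time 250 us;
        # autocorrelations rise toward short lags, the donor-acceptor
        # cross-correlation is anti-correlated (dips below 1)
        Q = np.array([[-2000.0, 2000.0], [2000.0, -2000.0]])
        # no acceptor-excitation photons: they are uncorrelated and would
        # only dilute the acceptor-channel correlation amplitude
        m = simulate.GroundTruthModel(Q, np.array([0.9, 0.1]),
                                      burst_duration_mean=2e-3,
                                      aex_photon_rate=0.0)
        stream, bursts, _ = simulate.simulate_dataset(m, 1500, seed=11)
        auto = burstwise_fcs(stream, bursts, "AxA")
        assert auto.G[0] > 1.1  # rises at short lags
        sel = auto.lags < 2e-3
        f = lambda l, a, tc, g0: g0 + a * np.exp(-l / tc)
        (a, tc, g0), _ = curve_fit(f, auto.lags[sel], auto.G[sel],
                                   p0=[0.3, 3e-4, 1.0], maxfev=10000)
        assert abs(tc - 250e-6) / 250e-6 < 0.30
        cross = burstwise_fcs(stream, bursts, "DxA")
        assert cross.G[0] < 0.9

    def test_apo_departure_below_one_millisecond(self, apo_dataset):
        stream, bursts, _, _ = apo_dataset
        c = burstwise_fcs(stream, bursts, "DxA", min_bursts=100)
        short = np.abs(c.G[c.lags < 2e-4] - 1).mean()
        longl = np.abs(c.G[c.lags > 1.5e-3] - 1).mean()
        assert short > 3 * longl

    def test_requires_enough_bursts(self, apo_dataset):
        stream, bursts, _, _ = apo_dataset
        with pytest.raises(ValueError):
            burstwise_fcs(stream, bursts[:10], "DxD")

    def test_unknown_pair_rejected(self, apo_dataset):
        stream, bursts, _, _ = apo_dataset
        with pytest.raises(ValueError):
            burstwise_fcs(stream, bursts, "XxY")
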