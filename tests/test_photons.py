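import numpy as np
import pytest

from photonhmm import photons
from photonhmm.photons import (
    Burst,
    CorrectionSet,
    DataError,
    FormatError,
    PhotonStream,
    burst_search,
    compute_burst_quantities,
    fret_histogram,
    read_photon_stream,
    stoichiometry_filter,
    write_photon_stream,
)


def _stream(ticks, ch, slot, period=12.5e-9):
    return PhotonStream(np.asarray(ticks), period, np.asarray(ch), np.asarray(slot))


class TestIO:
    @pytest.mark.parametrize("fmt,suffix", [("photon-hdf5", ".h5"),
                                            ("columnar-text", ".csv")])
    def test_round_trip_identity(self, tmp_path, fmt, suffix):
        s = _stream([1, 5, 9], [0, 1, 0], [0, 0, 1])
        path = tmp_path / f"s{suffix}"
        write_photon_stream(s, path, format=fmt)
        r = read_photon_stream(path, format=fmt)
        np.testing.assert_array_equal(r.timestamps, s.timestamps)
        np.testing.assert_array_equal(r.channel, s.channel)
        np.testing.assert_array_equal(r.excitation_slot, s.excitation_slot)
        assert r.clock_period == s.clock_period

    def test_columnar_text_two_rows(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("timestamp,channel,slot\n10,D,Dex\n20,A,Aex\n")
        r = read_photon_stream(p, format="columnar-text")
        assert len(r) == 2
        assert list(r.channel) == [0, 1]
        assert list(r.excitation_slot) == [0, 1]

    def test_unsorted_timestamps_rejected(self):
        with pytest.raises(DataError):
            _stream([5, 3], [0, 0], [0, 0])

    def test_missing_field_named_in_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("timestamp,channel\n1,D\n")
        with pytest.raises(FormatError, match="slot"):
            read_photon_stream(p, format="columnar-text")


class TestBurstSearch:
    def _cluster_stream(self, n_clusters=1, spacing=10e-6, n=100, gap=10e-3):
        period = 12.5e-9
        ticks = []
        t = 0.0
        for _ in range(n_clusters):
            t += 1e-3  # flanking quiet time
            for i in range(n):
                ticks.append(round((t + i * spacing) / period))
            t += (n - 1) * spacing + gap
        k = len(ticks)
        return _stream(ticks, np.zeros(k, np.int8), np.zeros(k, np.int8), period)

    def test_sparse_stream_no_burst(self):
        # uniform 1 kHz photons, threshold 50 kHz
        ticks = (np.arange(200) * 1e-3 / 12.5e-9).astype(np.int64)
        s = _stream(ticks, np.zeros(200, np.int8), np.zeros(200, np.int8))
        assert burst_search(s, 10, 50e3, 30) == []

    def test_empty_stream(self):
        s = _stream([], [], [])
        assert burst_search(s) == []

    def test_single_cluster_found_whole(self):
        s = self._cluster_stream(1)
        out = burst_search(s, window_m=10, rate_threshold=50e3, min_size=30)
        assert len(out) == 1
        assert (out[0].start_index, out[0].stop_index) == (0, 100)

    def test_two_clusters_disjoint_ordered(self):
        s = self._cluster_stream(2)
        out = burst_search(s, window_m=10, rate_threshold=50e3, min_size=30)
        assert len(out) == 2
        assert (out[0].start_index, out[0].stop_index) == (0, 100)
        assert (out[1].start_index, out[1].stop_index) == (100, 200)
        assert out[0].stop_index <= out[1].start_index

    def test_rate_criterion_against_direct_computation(self):
        # every photon in a reported burst is covered by a qualifying window
        s = self._cluster_stream(2)
        m, thr = 10, 50e3
        t = s.times_s
        for b in burst_search(s, m, thr, 30):
            covered = np.zeros(len(s), bool)
            for i in range(len(s) - m + 1):
                span = t[i + m - 1] - t[i]
                if span <= 0 or (m - 1) / span >= thr:
                    covered[i:i + m] = True
            assert covered[b.start_index:b.stop_index].all()

    def test_translation_invariance(self):
        s = self._cluster_stream(1)
        shifted = PhotonStream(s.timestamps + 10_000_000, s.clock_period,
                               s.channel, s.excitation_slot)
        a = burst_search(s, 10, 50e3, 30)
        b = burst_search(shifted, 10, 50e3, 30)
        assert [(x.start_index, x.stop_index) for x in a] == \
            [(x.start_index, x.stop_index) for x in b]


class TestBurstQuantities:
    def _mixed_stream(self, n_dd, n_da, n_aa):
        ch = [0] * n_dd + [1] * n_da + [1] * n_aa
        slot = [0] * (n_dd + n_da) + [1] * n_aa
        ticks = np.arange(len(ch)) * 800
        return _stream(ticks, ch, slot)

    def test_e_and_s_from_counts(self):
        s = self._mixed_stream(5, 5, 10)
        b = compute_burst_quantities(s, Burst(0, len(s)))
        assert b.e_raw == pytest.approx(0.5)
        assert b.s_raw == pytest.approx(0.5)
        assert (b.n_dd, b.n_da, b.n_aa) == (5, 5, 10)

    def test_zero_acceptor_photons(self):
        s = self._mixed_stream(20, 0, 0)
        b = compute_burst_quantities(s, Burst(0, len(s)))
        assert b.e_raw == 0.0 and b.valid

    def test_zero_donor_excitation_flagged(self):
        s = self._mixed_stream(0, 0, 10)
        b = compute_burst_quantities(s, Burst(0, len(s)))
        assert not b.valid and np.isnan(b.e_raw)

    def test_identity_corrections(self):
        s = self._mixed_stream(6, 4, 5)
        b = compute_burst_quantities(s, Burst(0, len(s)),
                                     CorrectionSet(0.0, 0.0, 1.0))
        assert b.e_corr == pytest.approx(b.e_raw)

    def test_e_invariant_under_time_translation(self):
        s = self._mixed_stream(5, 5, 10)
        shifted = PhotonStream(s.timestamps + 123456, s.clock_period,
                               s.channel, s.excitation_slot)
        b1 = compute_burst_quantities(s, Burst(0, len(s)))
        b2 = compute_burst_quantities(shifted, Burst(0, len(s)))
        assert b1.e_raw == b2.e_raw


class TestStoichiometryFilter:
    def _bursts(self, svals):
        return [Burst(0, 1, s_raw=s, e_raw=0.5) for s in svals]

    def test_window_selects(self):
        out = stoichiometry_filter(self._bursts([0.1, 0.5, 0.95]), 0.3, 0.8)
        assert [b.s_raw for b in out] == [0.5]

    def test_full_window_is_identity(self):
        bs = self._bursts([0.1, 0.5, 0.95])
        assert stoichiometry_filter(bs, 0.0, 1.0) == bs

    def test_empty_input(self):
        assert stoichiometry_filter([], 0.2, 0.8) == []

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            stoichiometry_filter([], 0.8, 0.2)


class TestFretHistogram:
    def test_point_mass(self):
        bs = [Burst(0, 1, e_raw=0.5, valid=True) for _ in range(10)]
        h = fret_histogram(bs, n_bins=10)
        assert h["count"].sum() == 10
        assert (h["count"] > 0).sum() == 1

    def test_mass_conservation_random(self):
        rng = np.random.default_rng(0)
        bs = [Burst(0, 1, e_raw=v, valid=True) for v in rng.random(137)]
        h = fret_histogram(bs, n_bins=25)
        assert h["count"].sum() == 137

    def test_apo_major_peak_location(self, apo_dataset):
        # the apo condition's burst-E histogram peaks near E ~ 0.55
        _, bursts, _, _ = apo_dataset
        h = fret_histogram(bursts, n_bins=20)
        mode = h.loc[h["count"].idxmax()]
        center = 0.5 * (mode["bin_left"] + mode["bin_right"])
        assert 0.5 <= center <= 0.6
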