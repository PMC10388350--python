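"""Model validation for photon-by-photon HMM fits.

Four procedures, each probing a different aspect of a fitted model:

* recoloring — redraw photon colors from the fitted model while keeping the
  measured arrival times; the recolored burst-E histogram should overlay the
  measured one if the model describes the data.
* likelihood-weighted dwell-time analysis — durations of Viterbi state
  segments, weighted by their posterior support, fitted to monoexponentials
  and compared with the analytic mean dwell 1/(-Q_ii).
* segmentation histograms — burst-E histograms of bursts whose Viterbi path
  occupies a single state; well-separated peaks validate state assignment.
* burst-wise fluorescence correlation — photon-pair correlation within
  bursts; departures from a flat curve reveal dynamics on the exchange
  timescale without any Markov assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import pair_time_histogram
from .hmm import H2MMModel, PhotonRecords, _prepare_single, forward_backward_pass
from .photons import ACCEPTOR, DONOR, PhotonStream, Burst

__all__ = [
    "recolor_records",
    "recolor_stream",
    "viterbi_paths",
    "sample_posterior_paths",
    "weighted_dwell_times",
    "segment_histograms",
    "burstwise_fcs",
    "DwellTimeResult",
    "CorrelationCurve",
    "SegmentHistograms",
]


# ---------------------------------------------------------------------------
# Recoloring
# ---------------------------------------------------------------------------

def recolor_records(model: H2MMModel, records: PhotonRecords, seed=0) -> PhotonRecords:
    """Redraw photon colors from ``model`` at the recorded arrival times.

    For every burst a fresh hidden path is sampled (initial state from p0,
    transitions through exp(Q tau) between photon times) and each photon's
    color is drawn from the occupied state's efficiency.  Timestamps and the
    burst structure are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    _, _, _, _, A, _ = _prepare_single(model, records)
    # per-photon row-wise transition CDFs (renormalised: clipping can leave
    # rows marginally short of 1)
    cdf = np.cumsum(A, axis=2)
    cdf /= cdf[:, :, -1:]
    p0cdf = np.cumsum(model.initial_distribution)
    p0cdf /= p0cdf[-1]
    E = model.efficiencies
    n = records.n_photons
    u_state = rng.random(n)
    u_color = rng.random(n)
    states = np.empty(n, dtype=np.int32)
    ptr = records.ptr
    for jb in range(records.n_bursts):
        s, e = ptr[jb], ptr[jb + 1]
        st = int(np.searchsorted(p0cdf, u_state[s]))
        states[s] = st
        for t in range(s + 1, e):
            st = int(np.searchsorted(cdf[t, st], u_state[t]))
            states[t] = st
    colors = (u_color < E[states]).astype(np.int8)
    return PhotonRecords(colors, records.gaps_s.copy(), records.ptr.copy(),
                         records.clock_period, records.burst_index)


def recolor_stream(model: H2MMModel, stream: PhotonStream, bursts: list[Burst],
                   seed=0, min_photons: int = 1):
    """Recolor the donor-excitation photons of a burst set taken from a stream.

    Returns (records, recolored_records) so measured and recolored burst-E
    histograms can be overlaid.
    """
    rec = PhotonRecords.from_stream(stream, bursts, min_photons=min_photons)
    return rec, recolor_records(model, rec, seed)


# ---------------------------------------------------------------------------
# Viterbi segmentation
# ---------------------------------------------------------------------------

def viterbi_paths(model: H2MMModel, records: PhotonRecords):
    """Per-photon Viterbi states and per-burst segment lists."""
    from .hmm import viterbi

    return viterbi(model, records)


def _photon_times(records: PhotonRecords) -> np.ndarray:
    """Arrival times (s) within each burst, zeroed at the first photon."""
    t = records.gaps_s.copy()
    t[records.ptr[:-1]] = 0.0
    t = np.cumsum(t)
    # subtract each burst's origin
    origins = np.repeat(t[records.ptr[:-1]], np.diff(records.ptr))
    return t - origins


def sample_posterior_paths(model: H2MMModel, records: PhotonRecords,
                           seed=0) -> np.ndarray:
    """Draw one hidden-state sequence per burst from the exact posterior.

    Forward-filter backward-sample: states at photon times are drawn from
    P(states | colors, model).  Marginally over datasets generated by the
    model itself, sampled paths follow the chain's own law, which makes them
    the statistically faithful basis for dwell-time statistics (the Viterbi
    path, in contrast, systematically over-smooths fast excursions when
    neighbouring states have overlapping emission efficiencies).
    """
    q, U, V, lam, A, b_obs = _prepare_single(model, records)
    n, K = b_obs.shape
    alpha, beta, cvec = np.empty((n, K)), np.empty((n, K)), np.empty(n)
    forward_backward_pass(A, b_obs, records.ptr,
                          np.ascontiguousarray(model.initial_distribution),
                          alpha, beta, cvec)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    states = np.empty(n, dtype=np.int32)
    ptr = records.ptr
    for jb in range(records.n_bursts):
        s, e = ptr[jb], ptr[jb + 1]
        w = alpha[e - 1] / alpha[e - 1].sum()
        states[e - 1] = np.searchsorted(np.cumsum(w), u[e - 1])
        for t in range(e - 2, s - 1, -1):
            w = alpha[t] * A[t + 1][:, states[t + 1]]
            w /= w.sum()
            states[t] = np.searchsorted(np.cumsum(w), u[t])
    return states


@dataclass
class DwellTimeResult:
    """Per-state dwell durations with posterior-support weights."""

    dwells: dict  # state -> array of uncensored dwell durations (s)
    weights: dict  # state -> matching weights
    tau: np.ndarray  # fitted monoexponential mean per state (s)
    tau_analytic: np.ndarray  # 1 / (-Q_ii)
    n_censored: dict
    flagged: list  # states never visited (tau undefined)

    def to_frame(self) -> pd.DataFrame:
        K = self.tau.size
        return pd.DataFrame(
            {
                "state": np.arange(1, K + 1),
                "tau_s": self.tau,
                "tau_analytic_s": self.tau_analytic,
                "weight_sum": [float(np.sum(self.weights.get(i, 0.0))) for i in range(K)],
                "n_dwells": [len(self.dwells.get(i, ())) for i in range(K)],
                "n_censored": [self.n_censored.get(i, 0) for i in range(K)],
            }
        )


def weighted_dwell_times(model: H2MMModel, records: PhotonRecords,
                         seed=0) -> DwellTimeResult:
    """Likelihood-weighted dwell-time analysis of posterior-sampled segments.

    State segments come from a posterior path sample (see
    ``sample_posterior_paths``); each segment runs from the midpoint of the
    gap preceding its first photon to the midpoint of the gap following its
    last photon, and carries the mean per-photon posterior probability of
    its state as its likelihood weight (attached to the returned dwell
    histograms).  The per-state monoexponential mean is the censoring-aware
    maximum-likelihood estimate

        tau_i = (total time spent in i) / (number of observed exits from i),

    in which segments truncated by a burst edge contribute exposure but no
    exit event — the standard survival-analysis treatment of right
    censoring, without which burst-length selection biases tau.  The
    analytic means 1/(-Q_ii) are reported alongside for comparison.
    """
    states = sample_posterior_paths(model, records, seed)
    # posteriors for the weights
    q, U, V, lam, A, b_obs = _prepare_single(model, records)
    n, K = b_obs.shape
    alpha, beta, cvec = np.empty((n, K)), np.empty((n, K)), np.empty(n)
    forward_backward_pass(A, b_obs, records.ptr,
                          np.ascontiguousarray(model.initial_distribution),
                          alpha, beta, cvec)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    times = _photon_times(records)
    dwells: dict = {i: [] for i in range(K)}
    weights: dict = {i: [] for i in range(K)}
    n_cens: dict = {i: 0 for i in range(K)}
    exposure = np.zeros(K)
    exit_weight = np.zeros(K)
    for jb in range(records.n_bursts):
        s, e = records.ptr[jb], records.ptr[jb + 1]
        run = s
        for t in range(s + 1, e + 1):
            if t < e and states[t] == states[t - 1]:
                continue
            st = int(states[t - 1])
            left_edge = run == s
            right_edge = t == e
            t0 = times[run] - (0.0 if left_edge else 0.5 * records.gaps_s[run])
            t1 = times[t - 1] + (0.0 if right_edge else 0.5 * records.gaps_s[t])
            w = float(gamma[run:t, st].mean())
            exposure[st] += t1 - t0
            if right_edge:
                n_cens[st] += 1
            else:
                exit_weight[st] += 1.0
                if not left_edge:  # complete dwell: usable for the histogram
                    dwells[st].append(t1 - t0)
                    weights[st].append(w)
                else:
                    n_cens[st] += 1
            run = t

    tau = np.full(K, np.nan)
    flagged = []
    for i in range(K):
        if exit_weight[i] <= 0:
            flagged.append(i)
            continue
        tau[i] = float(exposure[i] / exit_weight[i])
    tau_analytic = 1.0 / np.maximum(-np.diag(model.rate_matrix), 1e-300)
    return DwellTimeResult(
        {i: np.asarray(v) for i, v in dwells.items()},
        {i: np.asarray(v) for i, v in weights.items()},
        tau, tau_analytic, n_cens, flagged,
    )


@dataclass
class SegmentHistograms:
    """Burst-E histograms of single-state bursts, grouped by state."""

    histograms: dict  # state -> DataFrame (bin_left, bin_right, count, density)
    mean_e: dict  # state -> mean burst E of the group
    counts: dict  # state -> number of single-state bursts
    state_efficiencies: np.ndarray

    @property
    def states(self) -> list:
        """Populated states ordered by descending efficiency."""
        return sorted(self.histograms, key=lambda i: -self.state_efficiencies[i])


def segment_histograms(model: H2MMModel, records: PhotonRecords,
                       n_bins: int = 40) -> SegmentHistograms:
    """Group bursts whose Viterbi path occupies exactly one state."""
    from .hmm import viterbi
    from .photons import fret_histogram

    _, segments, _ = viterbi(model, records)
    be = records.burst_e
    groups: dict = {}
    for jb, segs in enumerate(segments):
        if len(segs) == 1:
            groups.setdefault(segs[0][0], []).append(be[jb])
    hists, means, counts = {}, {}, {}
    for state, vals in groups.items():
        vals = np.asarray(vals)
        fake = [Burst(0, 1, e_raw=v, valid=True) for v in vals]
        hists[state] = fret_histogram(fake, n_bins=n_bins)
        means[state] = float(vals.mean())
        counts[state] = int(vals.size)
    return SegmentHistograms(hists, means, counts, model.efficiencies)


# ---------------------------------------------------------------------------
# Burst-wise fluorescence correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationCurve:
    lags: np.ndarray  # bin centers (s), ascending
    G: np.ndarray  # normalised correlation (-> 1 at the largest lag)
    channel_pair: str
    n_bursts: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "G": self.G})


_PAIRS = {"DxD": (DONOR, DONOR), "AxA": (ACCEPTOR, ACCEPTOR), "DxA": (DONOR, ACCEPTOR)}


def default_lag_grid(lag_min: float = 10e-6, lag_max: float = 10e-3,
                     points_per_decade: int = 8) -> np.ndarray:
    """Multi-tau-style logarithmic lag-bin edges."""
    n = int(np.ceil(points_per_decade * np.log10(lag_max / lag_min))) + 1
    return np.geomspace(lag_min, lag_max, n)


def burstwise_fcs(stream: PhotonStream, bursts: list[Burst], channel_pair: str,
                  lag_grid: np.ndarray | None = None,
                  min_bursts: int = 100,
                  min_pairs_per_lag: float = 500.0,
                  min_bursts_per_lag: int = 25) -> CorrelationCurve:
    """Photon-pair correlation within bursts, averaged over bursts.

    For each burst, ordered photon pairs (first channel then second) are
    histogrammed over the logarithmic lag grid and normalised by the pair
    count expected for a rate-matched uncorrelated (Poisson) burst of the
    same duration; bin ratios are pooled over bursts (sum of counts over sum
    of expectations, which weights bursts by their photon content).  The
    burst's first and last photon define its time span and are excluded
    from the pair counting: conditioned on the span, the interior photons
    of a Poisson burst are exactly iid uniform, which makes the expectation
    unbiased at all lags (pairs involving the span-defining photons are
    enriched at separations near the span itself).  The curve is finally
    normalised to 1 at the largest computed lag.  Lags longer than the
    available burst durations, or sampled by fewer than
    ``min_pairs_per_lag`` expected pairs (only the longest bursts reach the
    longest lags, so those bins carry large noise), or covered by fewer
    than ``min_bursts_per_lag`` bursts (a single long burst would dominate),
    drop out of the grid.
    """
    if channel_pair not in _PAIRS:
        raise ValueError(f"channel_pair must be one of {sorted(_PAIRS)}")
    code_x, code_y = _PAIRS[channel_pair]
    if lag_grid is None:
        lag_grid = default_lag_grid()
    edges = np.asarray(lag_grid, dtype=float)
    nbin = edges.size - 1
    counts = np.zeros(nbin, dtype=np.int64)
    expected = np.zeros(nbin)
    coverage = np.zeros(nbin, dtype=np.int64)  # bursts spanning each lag bin
    used = 0
    for b in bursts:
        sl = slice(b.start_index, b.stop_index)
        t = (stream.timestamps[sl] - stream.timestamps[b.start_index]) \
            * stream.clock_period
        ch = stream.channel[sl]
        T = float(t[-1]) if t.size > 1 else 0.0
        if T <= edges[0] or t.size < 4:
            continue
        t, ch = t[1:-1], ch[1:-1]  # interior photons only (see docstring)
        nx = int(np.sum(ch == code_x))
        ny = int(np.sum(ch == code_y))
        npairs = nx * ny - (nx if code_x == code_y else 0)
        if npairs <= 0:
            continue
        c = np.zeros(nbin, dtype=np.int64)
        pair_time_histogram(t.astype(float), ch.astype(np.int64),
                            code_x, code_y, edges, c)
        counts += c
        lo = np.minimum(edges[:-1], T)
        hi = np.minimum(edges[1:], T)
        expected += npairs * ((hi - lo) * T - 0.5 * (hi**2 - lo**2)) / T**2
        coverage += edges[1:] < T
        used += 1
    if used < min_bursts:
        raise ValueError(
            f"only {used} bursts usable; >= {min_bursts} required for averaging")
    keep = (expected > max(min_pairs_per_lag, 1e-12)) \
        & (coverage >= min_bursts_per_lag)
    if not keep.any():
        raise ValueError("no lag bin is sufficiently sampled; use more bursts "
                         "or a shorter lag grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        G = counts[keep] / expected[keep]
    centers = np.sqrt(edges[:-1] * edges[1:])[keep]
    G = G / G[-1]  # normalise at the largest computed lag
    return CorrelationCurve(centers, G, channel_pair, used)
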