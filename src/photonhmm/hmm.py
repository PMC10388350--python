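"""Photon-by-photon maximum-likelihood hidden Markov modeling.

The model: a molecule's conformation follows a continuous-time Markov chain
with generator Q (s^-1) over K states; each detected donor-excitation photon
is colored acceptor with the occupied state's FRET efficiency E_i.  Photon
arrival times are uninformative about the state (state-independent detection
rate), so the likelihood of a burst is

    L = p0 . diag(b_0) prod_t [ exp(Q tau_t) diag(b_t) ] . 1

with tau_t the inter-photon gaps and b_t the per-state color probabilities.
Propagators are computed from one eigendecomposition of Q per EM iteration;
the E-step accumulates the exact endpoint-conditioned sufficient statistics
of the hidden chain (expected state occupation times R_i and jump counts
N_ij) through the same eigenbasis, giving a Baum-Welch-type EM whose M-step
is closed form (k_ij = N_ij / R_i) and whose log-likelihood never decreases.

Fitting follows the statsmodels convention: construct ``PhotonHMM`` (one
dataset) or ``GlobalPhotonHMM`` (several conditions sharing efficiencies)
and call ``fit()`` to obtain a results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg

from ._kernels import (
    build_propagators,
    forward_backward_pass,
    forward_logliks,
    viterbi_pass,
)
from .kinetics import steady_state
from .photons import DEX, PhotonStream, Burst

__all__ = [
    "H2MMModel",
    "PhotonRecords",
    "PhotonHMM",
    "GlobalPhotonHMM",
    "PhotonHMMResults",
    "GlobalPhotonHMMResults",
    "em_fit",
    "global_fit",
    "forward_backward",
    "viterbi",
    "burst_loglik",
    "burst_logliks",
    "rate_matrix_from_transition",
    "k_scan",
]

_EFF_FLOOR = 1e-6  # keep emission probabilities away from {0, 1}


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class H2MMModel:
    """A K-state photon-color hidden Markov model.

    Parameterised by the rate matrix Q (s^-1); the per-tick transition
    matrix is exp(Q * clock_period).  Emissions are Bernoulli in photon
    color with per-state acceptor probability (FRET efficiency) E_i.
    """

    rate_matrix: np.ndarray
    efficiencies: np.ndarray
    initial_distribution: np.ndarray
    clock_period: float = 12.5e-9

    def __post_init__(self):
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.efficiencies = np.asarray(self.efficiencies, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)

    @property
    def n_states(self) -> int:
        return self.efficiencies.size

    @property
    def emission_matrix(self) -> np.ndarray:
        """K x 2 matrix of (donor, acceptor) color probabilities."""
        E = self.efficiencies
        return np.column_stack([1.0 - E, E])

    def transition_matrix(self, n_ticks: int = 1) -> np.ndarray:
        """exp(Q * clock_period * n_ticks)."""
        return scipy.linalg.expm(self.rate_matrix * self.clock_period * n_ticks)

    @property
    def stationary(self) -> np.ndarray:
        return steady_state(self.rate_matrix)

    def canonical_order(self) -> "H2MMModel":
        """States sorted by descending FRET efficiency (field convention)."""
        order = np.argsort(-self.efficiencies, kind="stable")
        return H2MMModel(
            self.rate_matrix[np.ix_(order, order)],
            self.efficiencies[order],
            self.initial_distribution[order],
            self.clock_period,
        )

    def to_json(self, path) -> None:
        obj = {
            "n_states": int(self.n_states),
            "clock_period_s": self.clock_period,
            "rate_matrix_s_inv": self.rate_matrix.tolist(),
            "efficiencies": self.efficiencies.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "H2MMModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            np.array(obj["rate_matrix_s_inv"], dtype=float),
            np.array(obj["efficiencies"], dtype=float),
            np.array(obj["initial_distribution"], dtype=float),
            float(obj["clock_period_s"]),
        )


def rate_matrix_from_transition(T: np.ndarray, clock_period: float) -> np.ndarray:
    """Q = logm(T) / clock_period with tiny negative off-diagonals clamped."""
    Q = np.real(scipy.linalg.logm(np.asarray(T, dtype=float))) / clock_period
    off = ~np.eye(Q.shape[0], dtype=bool)
    neg = off & (Q < 0)
    if np.any(Q[neg] < -1e-10 / clock_period):
        raise ValueError("logm produced significantly negative off-diagonal rates")
    Q[neg] = 0.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------------
# Photon records (fit-ready burst data)
# ---------------------------------------------------------------------------

@dataclass
class PhotonRecords:
    """Donor-excitation photons of a burst set, flattened CSR-style.

    colors: 0 donor / 1 acceptor; gaps_s: seconds since the previous photon
    of the same burst (0.0 for the first photon); ptr delimits bursts.
    """

    colors: np.ndarray
    gaps_s: np.ndarray
    ptr: np.ndarray
    clock_period: float
    burst_index: np.ndarray = field(default=None)  # into the source burst list

    def __post_init__(self):
        self.colors = np.asarray(self.colors, dtype=np.int8)
        self.gaps_s = np.asarray(self.gaps_s, dtype=float)
        self.ptr = np.asarray(self.ptr, dtype=np.int64)

    @property
    def n_photons(self) -> int:
        return self.colors.size

    @property
    def n_bursts(self) -> int:
        return self.ptr.size - 1

    @property
    def burst_e(self) -> np.ndarray:
        """Per-burst proximity ratio from the included photons."""
        acc = np.add.reduceat(self.colors.astype(float), self.ptr[:-1])
        n = np.diff(self.ptr)
        return acc / n

    @classmethod
    def from_stream(
        cls, stream: PhotonStream, bursts: list[Burst], min_photons: int = 5
    ) -> "PhotonRecords":
        """Extract donor-excitation photons burst by burst.

        Bursts with fewer than ``min_photons`` donor-excitation photons carry
        essentially no kinetic information and are dropped.
        """
        colors, gaps, ptr, kept = [], [], [0], []
        for ib, b in enumerate(bursts):
            sl = slice(b.start_index, b.stop_index)
            mask = stream.excitation_slot[sl] == DEX
            if mask.sum() < min_photons:
                continue
            t = stream.timestamps[sl][mask]
            colors.append(stream.channel[sl][mask])
            g = np.empty(t.size)
            g[0] = 0.0
            g[1:] = np.diff(t) * stream.clock_period
            gaps.append(g)
            ptr.append(ptr[-1] + t.size)
            kept.append(ib)
        return cls(
            np.concatenate(colors) if colors else np.empty(0, np.int8),
            np.concatenate(gaps) if gaps else np.empty(0),
            np.array(ptr, dtype=np.int64),
            stream.clock_period,
            np.array(kept, dtype=np.int64),
        )

    @classmethod
    def from_arrays(cls, colors, gaps_ticks, clock_period: float = 12.5e-9):
        """Single-burst records from color and integer tick-gap arrays."""
        colors = np.asarray(colors)
        gaps = np.asarray(gaps_ticks, dtype=float) * clock_period
        ptr = np.array([0, colors.size], dtype=np.int64)
        return cls(colors, gaps, ptr, clock_period)


# ---------------------------------------------------------------------------
# Propagators and E-step
# ---------------------------------------------------------------------------

def _eig_decompose(Q: np.ndarray):
    """Eigendecomposition Q = U diag(q) V with a conditioning guard.

    A nearly defective Q (ill-conditioned eigenbasis) is perturbed by a tiny
    deterministic jitter of its off-diagonal rates; the likelihood change is
    far below EM's convergence tolerance.
    """
    Q = np.asarray(Q, dtype=float)
    for attempt in range(4):
        q, U = np.linalg.eig(Q)
        if np.linalg.cond(U) < 1e8:
            break
        jit = 1e-7 * (1 + attempt) * np.abs(Q).max()
        bump = jit * (1.0 + 0.1 * np.arange(Q.size).reshape(Q.shape))
        Qj = Q + np.where(np.eye(Q.shape[0], dtype=bool), 0.0, bump)
        np.fill_diagonal(Qj, 0.0)
        np.fill_diagonal(Qj, -Qj.sum(axis=1))
        Q = Qj
    V = np.linalg.inv(U)
    # real spectrum (reversible-like Q): drop to real arithmetic, ~3x faster
    scale = max(1.0, float(np.abs(q.real).max()))
    if np.abs(q.imag).max() < 1e-10 * scale:
        return q.real.copy(), U.real.copy(), V.real.copy()
    return q, U, V


def _propagators(q, U, V, tau):
    """A[t] = exp(Q tau_t) for every photon (identity at tau = 0)."""
    lam = np.exp(np.multiply.outer(tau, q))  # (n, K), real or complex
    if lam.dtype == np.float64:
        A = np.empty((tau.size, q.size, q.size))
        build_propagators(np.ascontiguousarray(U), np.ascontiguousarray(V),
                          np.ascontiguousarray(lam), A)
    else:
        A = np.einsum("ap,tp,pb->tab", U, lam, V).real
        np.clip(A, 0.0, None, out=A)
    return lam, np.ascontiguousarray(A)


def _transition_statistics(q, U, V, lam, tau, alpha, b_obs, beta, cvec, ptr):
    """Endpoint-conditioned CTMC sufficient statistics, posterior-weighted.

    Returns G (K x K) such that E[N_ij] = Q_ij Re(G_ij) for i != j and
    E[R_i] = Re(G_ii), summed over all inter-photon gaps.  The eigenbasis
    sums Sum_t J_pq(tau_t) P_p C_q with J_pq = (e^{q_p tau}-e^{q_q tau}) /
    (q_p - q_q) factorise into three (m,K)->(K,K) products; near-degenerate
    eigenvalue pairs (|q_p - q_q| tau << 1) use the limit tau e^{q_p tau},
    which is also the numerically stable branch.
    """
    n, K = alpha.shape
    first = np.zeros(n, dtype=bool)
    first[ptr[:-1]] = True
    sel = np.flatnonzero(~first)
    Pw = (alpha[sel - 1] @ U) * (1.0 / cvec[sel])[:, None]  # (m, K)
    Cc = (b_obs[sel] * beta[sel]) @ V.T
    lam_s = lam[sel]
    tau_s = tau[sel]
    M1 = (Pw * lam_s).T @ Cc
    M2 = Pw.T @ (Cc * lam_s)
    Dg = (Pw * lam_s * tau_s[:, None]).T @ Cc
    qd = q[:, None] - q[None, :]
    tau_scale = float(np.median(tau_s)) if tau_s.size else 1.0
    degenerate = np.abs(qd) * max(tau_scale, 1e-300) < 1e-4
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (M1 - M2) / qd
    F[degenerate] = Dg[degenerate]
    return V.T @ F @ U.T


@dataclass
class _EStepOut:
    loglik: float
    gamma_first_sum: np.ndarray  # sum of first-photon posteriors
    emis_num: np.ndarray  # sum of posteriors over acceptor photons
    emis_den: np.ndarray  # sum of posteriors over all photons
    jump_counts: np.ndarray  # E[N_ij]
    occupation: np.ndarray  # E[R_i], seconds


def _e_step(Q, E, p0, rec: PhotonRecords) -> _EStepOut:
    n, K = rec.n_photons, E.size
    q, U, V = _eig_decompose(Q)
    lam, A = _propagators(q, U, V, rec.gaps_s)
    B = np.column_stack([1.0 - E, E])
    b_obs = np.ascontiguousarray(B[:, rec.colors].T)  # (n, K)
    alpha = np.empty((n, K))
    beta = np.empty((n, K))
    cvec = np.empty(n)
    ll = forward_backward_pass(A, b_obs, rec.ptr, np.ascontiguousarray(p0),
                               alpha, beta, cvec)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    acc = rec.colors == 1
    emis_num = gamma[acc].sum(axis=0)
    emis_den = gamma.sum(axis=0)
    gamma_first = gamma[rec.ptr[:-1]].sum(axis=0)
    G = _transition_statistics(q, U, V, lam, rec.gaps_s, alpha, b_obs, beta,
                               cvec, rec.ptr)
    Gr = G.real
    N = Q * Gr
    np.fill_diagonal(N, 0.0)
    np.clip(N, 0.0, None, out=N)
    R = np.clip(np.diag(Gr), 0.0, None)
    return _EStepOut(ll, gamma_first, emis_num, emis_den, N, R)


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

@dataclass
class _Params:
    """EM state: shared efficiencies, per-dataset rates and p0."""

    E: np.ndarray
    Qs: list
    p0s: list


def _em_iterate(params: _Params, recs: list, tol: float, max_iter: int,
                trace: list, min_rate: float = 1e-4):
    """Run EM until convergence; mutates nothing, returns final params."""
    E = params.E.copy()
    Qs = [Q.copy() for Q in params.Qs]
    p0s = [p.copy() for p in params.p0s]
    n_photons = sum(r.n_photons for r in recs)
    prev = -np.inf
    converged = False
    it = 0
    while it < max_iter:
        outs = [_e_step(Qs[d], E, p0s[d], recs[d]) for d in range(len(recs))]
        ll = sum(o.loglik for o in outs)
        trace.append(ll)
        if ll - prev < tol * n_photons and it > 0:
            converged = True
            break
        prev = ll
        # M-step: emissions pooled across datasets (shared E)
        num = sum(o.emis_num for o in outs)
        den = sum(o.emis_den for o in outs)
        E = np.clip(num / np.maximum(den, 1e-300), _EFF_FLOOR, 1 - _EFF_FLOOR)
        for d, o in enumerate(outs):
            with np.errstate(divide="ignore", invalid="ignore"):
                Qn = o.jump_counts / o.occupation[:, None]
            # states with no posterior occupation keep their previous rates
            dead = ~np.isfinite(Qn).all(axis=1) | (o.occupation <= 0)
            Qn[dead] = Qs[d][dead] - np.diag(np.diag(Qs[d]))[dead]
            np.clip(Qn, min_rate, None, out=Qn)
            np.fill_diagonal(Qn, 0.0)
            np.fill_diagonal(Qn, -Qn.sum(axis=1))
            Qs[d] = Qn
            p0 = o.gamma_first_sum / o.gamma_first_sum.sum()
            p0s[d] = np.clip(p0, 1e-12, None)
            p0s[d] /= p0s[d].sum()
        it += 1
    return _Params(E, Qs, p0s), converged, it


def _initial_params(recs: list, K: int, rng, jitter: bool,
                    rate_init: float = 1000.0) -> _Params:
    """Default initialisation: E on a grid spanning the burst-E 5th-95th
    percentiles, uniform exchange rates, optional random jitter per restart."""
    be = np.concatenate([r.burst_e for r in recs])
    lo, hi = np.percentile(be, [5, 95]) if be.size else (0.1, 0.9)
    lo = min(max(lo, 0.02), 0.5)
    hi = max(min(hi, 0.98), lo + 0.1)
    E = np.linspace(hi, lo, K)  # descending
    if jitter:
        E = np.clip(E + rng.uniform(-0.06, 0.06, K), 0.01, 0.99)
        E = np.sort(E)[::-1].copy()
    Qs, p0s = [], []
    for _ in recs:
        k = rate_init * (np.exp(rng.normal(0, 0.5)) if jitter else 1.0)
        Q = np.full((K, K), k)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        Qs.append(Q)
        p0s.append(np.full(K, 1.0 / K))
    return _Params(E, Qs, p0s)


def _fit_em(recs: list, K: int, restarts: int, tol: float, max_iter: int,
            seed, init: _Params | None, restart_iter: int | None, verbose: bool):
    """Multi-restart EM: short exploratory runs, then the best candidate is
    polished to convergence.  Returns (params, trace, converged, n_iter,
    restart_logliks)."""
    rng = np.random.default_rng(seed)
    if restart_iter is None:
        restart_iter = min(25, max_iter)
    candidates = []
    restart_lls = []
    n_restarts = max(1, restarts)
    for r in range(n_restarts):
        if init is not None and r == 0:
            p = init
        else:
            p = _initial_params(recs, K, rng, jitter=(r > 0))
        trace: list = []
        p_out, conv, it = _em_iterate(p, recs, tol, restart_iter, trace)
        candidates.append((trace[-1], it, r, p_out, trace, conv))
        restart_lls.append(trace[-1])
        if verbose:
            print(f"restart {r}: loglik {trace[-1]:.2f} after {it} iters")
    # best loglik wins; ties broken by lower iteration count
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, it0, _, best, trace, conv = candidates[0]
    if not conv and it0 >= restart_iter:
        more: list = []
        best, conv, it1 = _em_iterate(best, recs, tol, max_iter - it0, more)
        trace = trace + more[1:]  # first entry repeats the restart's last ll
        it0 += it1
    return best, np.asarray(trace), conv, it0, np.asarray(restart_lls)


def _canonicalize(params: _Params):
    order = np.argsort(-params.E, kind="stable")
    return _Params(
        params.E[order],
        [Q[np.ix_(order, order)] for Q in params.Qs],
        [p[order] for p in params.p0s],
    )


# ---------------------------------------------------------------------------
# Model / Results classes
# ---------------------------------------------------------------------------

class PhotonHMM:
    """Photon-by-photon HMM for a single burst dataset.

    Parameters
    ----------
    records : PhotonRecords (or build with ``from_stream``)
    k_states : number of hidden conformational states
    """

    def __init__(self, records: PhotonRecords, k_states: int = 4):
        if records.n_bursts == 0:
            raise ValueError("dataset is empty")
        if k_states < 1:
            raise ValueError("k_states must be >= 1")
        self.records = records
        self.k_states = k_states

    @classmethod
    def from_stream(cls, stream, bursts, k_states: int = 4, min_photons: int = 5):
        return cls(PhotonRecords.from_stream(stream, bursts, min_photons), k_states)

    def fit(self, restarts: int = 8, tol: float = 1e-8, max_iter: int = 200,
            seed=0, init: H2MMModel | None = None, restart_iter: int | None = None,
            verbose: bool = False) -> "PhotonHMMResults":
        init_p = None
        if init is not None:
            init_p = _Params(init.efficiencies.copy(), [init.rate_matrix.copy()],
                             [init.initial_distribution.copy()])
        params, trace, conv, n_iter, rls = _fit_em(
            [self.records], self.k_states, restarts, tol, max_iter, seed,
            init_p, restart_iter, verbose)
        params = _canonicalize(params)
        return PhotonHMMResults(self, params, trace, conv, n_iter, rls)


class GlobalPhotonHMM:
    """Joint fit of several conditions with shared FRET efficiencies.

    Each condition keeps its own rate matrix and initial distribution; the
    emission efficiencies are pooled across all datasets in the M-step.
    """

    def __init__(self, datasets: dict, k_states: int = 4):
        if len(datasets) < 2:
            raise ValueError("global fit requires >= 2 datasets")
        self.names = list(datasets)
        self.datasets = datasets
        self.k_states = k_states

    def fit(self, restarts: int = 8, tol: float = 1e-8, max_iter: int = 200,
            seed=0, init: _Params | None = None, restart_iter: int | None = None,
            verbose: bool = False) -> "GlobalPhotonHMMResults":
        recs = [self.datasets[n] for n in self.names]
        params, trace, conv, n_iter, rls = _fit_em(
            recs, self.k_states, restarts, tol, max_iter, seed, init,
            restart_iter, verbose)
        params = _canonicalize(params)
        return GlobalPhotonHMMResults(self, params, trace, conv, n_iter, rls)


class _ResultsBase:
    def __init__(self, model, params: _Params, trace, converged, n_iter, restart_lls):
        self.model = model
        self._params = params
        self.loglik_trace = np.asarray(trace)
        self.converged = bool(converged)
        self.n_iterations = int(n_iter)
        self.restart_logliks = restart_lls

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def efficiencies(self) -> np.ndarray:
        """Shared per-state FRET efficiencies, descending."""
        return self._params.E

    @property
    def degenerate_states(self) -> np.ndarray:
        """States whose efficiencies collapsed onto a neighbour (< 0.01 apart)."""
        E = np.sort(self._params.E)
        return np.flatnonzero(np.diff(E) < 0.01)

    def _n_free_params(self, n_datasets: int) -> int:
        K = self._params.E.size
        return K + n_datasets * (K * (K - 1) + (K - 1))

    def bic(self, n_photons: int, n_datasets: int) -> float:
        return self._n_free_params(n_datasets) * np.log(n_photons) - 2 * self.loglik


class PhotonHMMResults(_ResultsBase):
    """Results of a single-dataset fit."""

    @property
    def rate_matrix(self) -> np.ndarray:
        return self._params.Qs[0]

    @property
    def initial_distribution(self) -> np.ndarray:
        return self._params.p0s[0]

    @property
    def stationary(self) -> np.ndarray:
        """Populations from diagonalizing the fitted rate matrix."""
        return steady_state(self.rate_matrix)

    def as_h2mm(self) -> H2MMModel:
        return H2MMModel(self.rate_matrix, self.efficiencies,
                         self.initial_distribution, self.model.records.clock_period)

    def viterbi(self):
        from .validation import viterbi_paths

        return viterbi_paths(self.as_h2mm(), self.model.records)

    def dwell_times(self):
        from .validation import weighted_dwell_times

        return weighted_dwell_times(self.as_h2mm(), self.model.records)

    def segment_histograms(self, n_bins: int = 40):
        from .validation import segment_histograms

        return segment_histograms(self.as_h2mm(), self.model.records, n_bins)

    def recolor(self, seed=0):
        from .validation import recolor_records

        return recolor_records(self.as_h2mm(), self.model.records, seed)

    def summary(self) -> str:
        rec = self.model.records
        pi = self.stationary
        lines = [
            "Photon-by-photon HMM fit",
            "=" * 60,
            f"states: {self.model.k_states}   bursts: {rec.n_bursts}   "
            f"photons: {rec.n_photons}",
            f"log-likelihood: {self.loglik:.2f}   iterations: {self.n_iterations}"
            f"   converged: {self.converged}",
            "",
            f"{'state':>5} {'E':>8} {'pi':>8} {'p0':>8} {'tau_ms':>8}",
        ]
        tau = 1e3 / np.maximum(-np.diag(self.rate_matrix), 1e-300)
        for i in range(self.model.k_states):
            lines.append(
                f"{i + 1:>5} {self.efficiencies[i]:>8.3f} {pi[i]:>8.3f} "
                f"{self.initial_distribution[i]:>8.3f} {tau[i]:>8.3f}"
            )
        lines.append("")
        lines.append("rate matrix (s^-1):")
        for row in self.rate_matrix:
            lines.append("  " + " ".join(f"{v:>10.1f}" for v in row))
        return "\n".join(lines)


class GlobalPhotonHMMResults(_ResultsBase):
    """Results of a shared-efficiency global fit across conditions."""

    def rate_matrix(self, name) -> np.ndarray:
        return self._params.Qs[self.model.names.index(name)]

    def initial_distribution(self, name) -> np.ndarray:
        return self._params.p0s[self.model.names.index(name)]

    def stationary(self, name) -> np.ndarray:
        return steady_state(self.rate_matrix(name))

    def as_h2mm(self, name) -> H2MMModel:
        rec = self.model.datasets[name]
        return H2MMModel(self.rate_matrix(name), self.efficiencies,
                         self.initial_distribution(name), rec.clock_period)

    def macrostate(self, name):
        from .kinetics import MacrostateModel

        return MacrostateModel(str(name), self.rate_matrix(name), self.efficiencies)

    def summary(self) -> str:
        lines = [
            "Global photon-by-photon HMM fit (shared efficiencies)",
            "=" * 60,
            f"states: {self.model.k_states}   conditions: {self.model.names}",
            f"joint log-likelihood: {self.loglik:.2f}   iterations: "
            f"{self.n_iterations}   converged: {self.converged}",
            "shared E: " + " ".join(f"{e:.3f}" for e in self.efficiencies),
            "",
            f"{'condition':>12} " + " ".join(f"{'pi%d' % (i + 1):>7}"
                                             for i in range(self.model.k_states)),
        ]
        for name in self.model.names:
            pi = self.stationary(name)
            lines.append(f"{str(name):>12} " + " ".join(f"{v:>7.3f}" for v in pi))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional API
# ---------------------------------------------------------------------------

def em_fit(records: PhotonRecords, k_states: int, init: H2MMModel | None = None,
           tol: float = 1e-8, max_iter: int = 200, restarts: int = 8,
           seed=0, restart_iter: int | None = None) -> PhotonHMMResults:
    """Fit a K-state model to one dataset (see ``PhotonHMM.fit``)."""
    return PhotonHMM(records, k_states).fit(restarts=restarts, tol=tol,
                                            max_iter=max_iter, seed=seed,
                                            init=init, restart_iter=restart_iter)


def global_fit(datasets: dict, k_states: int, tol: float = 1e-8,
               max_iter: int = 200, restarts: int = 8, seed=0,
               restart_iter: int | None = None) -> GlobalPhotonHMMResults:
    """Fit several conditions jointly with shared efficiencies."""
    return GlobalPhotonHMM(datasets, k_states).fit(
        restarts=restarts, tol=tol, max_iter=max_iter, seed=seed,
        restart_iter=restart_iter)


def _prepare_single(model: H2MMModel, rec: PhotonRecords):
    q, U, V = _eig_decompose(model.rate_matrix)
    lam, A = _propagators(q, U, V, rec.gaps_s)
    B = model.emission_matrix
    b_obs = np.ascontiguousarray(B[:, rec.colors].T)
    return q, U, V, lam, A, b_obs


def forward_backward(model: H2MMModel, records: PhotonRecords):
    """Log-likelihood, per-photon posteriors and expected jump counts.

    Accepts a PhotonRecords (single- or multi-burst); posteriors are per
    photon, jump counts are summed over all bursts.
    """
    q, U, V, lam, A, b_obs = _prepare_single(model, records)
    n, K = b_obs.shape
    alpha, beta, cvec = np.empty((n, K)), np.empty((n, K)), np.empty(n)
    p0 = np.ascontiguousarray(model.initial_distribution)
    ll = forward_backward_pass(A, b_obs, records.ptr, p0, alpha, beta, cvec)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    G = _transition_statistics(q, U, V, lam, records.gaps_s, alpha, b_obs,
                               beta, cvec, records.ptr)
    N = model.rate_matrix * G.real
    np.fill_diagonal(N, 0.0)
    np.clip(N, 0.0, None, out=N)
    return ll, gamma, N


def burst_logliks(model: H2MMModel, records: PhotonRecords) -> np.ndarray:
    """Per-burst log-likelihood under ``model`` (forward pass only)."""
    _, _, _, _, A, b_obs = _prepare_single(model, records)
    out = np.empty(records.n_bursts)
    forward_logliks(A, b_obs, records.ptr,
                    np.ascontiguousarray(model.initial_distribution), out)
    return out


def burst_loglik(model: H2MMModel, records: PhotonRecords) -> float:
    """Total log-likelihood of all bursts in ``records``."""
    return float(burst_logliks(model, records).sum())


def viterbi(model: H2MMModel, records: PhotonRecords):
    """Most likely state sequence per photon plus segment lists.

    Returns (path, segments, best_logprob): path is per-photon states;
    segments is a per-burst list of (state, start_photon, stop_photon)
    half-open photon-index runs (indices into the flattened photon arrays).
    """
    _, _, _, _, A, b_obs = _prepare_single(model, records)
    tiny = 1e-300
    logA = np.log(np.maximum(A, tiny))
    logb = np.log(np.maximum(b_obs, tiny))
    logp0 = np.log(np.maximum(model.initial_distribution, tiny))
    path = np.empty(records.n_photons, dtype=np.int32)
    best = viterbi_pass(np.ascontiguousarray(logA), np.ascontiguousarray(logb),
                        records.ptr, np.ascontiguousarray(logp0), path)
    segments = []
    for jb in range(records.n_bursts):
        s, e = records.ptr[jb], records.ptr[jb + 1]
        segs = []
        run_start = s
        for t in range(s + 1, e):
            if path[t] != path[t - 1]:
                segs.append((int(path[t - 1]), int(run_start), int(t)))
                run_start = t
        segs.append((int(path[e - 1]), int(run_start), int(e)))
        segments.append(segs)
    return path, segments, float(best)


def k_scan(records: PhotonRecords, ks=(2, 3, 4, 5), restarts: int = 4,
           seed=0, **fit_kw) -> pd.DataFrame:
    """Model-size report: loglik and BIC versus the number of states.

    No automatic selection is performed; the table is for inspection.
    """
    rows = []
    for K in ks:
        res = em_fit(records, K, restarts=restarts, seed=seed, **fit_kw)
        rows.append(dict(k=K, loglik=res.loglik,
                         bic=res.bic(records.n_photons, 1),
                         converged=res.converged,
                         n_degenerate=len(res.degenerate_states)))
    return pd.DataFrame(rows)
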