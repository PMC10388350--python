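"""Numba kernels for the photon-by-photon forward/backward and Viterbi passes.

Data layout: all bursts of a dataset are flattened into photon-major arrays;
``ptr`` (n_bursts + 1) delimits bursts CSR-style.  ``A[t]`` is the hidden-state
propagator exp(Q * tau_t) over the gap preceding photon t (identity for the
first photon of a burst, which starts from p0), and ``b[t, i]`` the emission
probability of photon t's color in state i.  Scaled recursions keep every
quantity O(1) so bursts of 10^4+ photons do not underflow.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def build_propagators(U, V, lam, A):
    """A[t] = U diag(lam[t]) V, clipped at 0 (real-spectrum fast path)."""
    n, K = lam.shape
    for t in range(n):
        for a in range(K):
            for bcol in range(K):
                acc = 0.0
                for p in range(K):
                    acc += U[a, p] * lam[t, p] * V[p, bcol]
                A[t, a, bcol] = acc if acc > 0.0 else 0.0


@njit(cache=True)
def forward_backward_pass(A, b, ptr, p0, alpha, beta, cvec):
    """Scaled forward/backward over all bursts; returns total log-likelihood.

    Fills alpha (scaled forward), beta (scaled backward) and cvec (per-photon
    scale factors); the per-photon posterior is alpha * beta row-wise.
    """
    nb = ptr.size - 1
    K = p0.size
    ll = 0.0
    for jb in range(nb):
        s = ptr[jb]
        e = ptr[jb + 1]
        c = 0.0
        for i in range(K):
            v = p0[i] * b[s, i]
            alpha[s, i] = v
            c += v
        cvec[s] = c
        ll += np.log(c)
        for i in range(K):
            alpha[s, i] /= c
        for t in range(s + 1, e):
            c = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[t - 1, i] * A[t, i, j]
                v = acc * b[t, j]
                alpha[t, j] = v
                c += v
            cvec[t] = c
            ll += np.log(c)
            for j in range(K):
                alpha[t, j] /= c
        for i in range(K):
            beta[e - 1, i] = 1.0
        for t in range(e - 2, s - 1, -1):
            cn = cvec[t + 1]
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += A[t + 1, i, j] * b[t + 1, j] * beta[t + 1, j]
                beta[t, i] = acc / cn
    return ll


@njit(cache=True)
def forward_logliks(A, b, ptr, p0, out):
    """Forward pass only; per-burst log-likelihoods written to ``out``."""
    nb = ptr.size - 1
    K = p0.size
    a = np.empty(K)
    a2 = np.empty(K)
    for jb in range(nb):
        s = ptr[jb]
        e = ptr[jb + 1]
        ll = 0.0
        c = 0.0
        for i in range(K):
            a[i] = p0[i] * b[s, i]
            c += a[i]
        ll += np.log(c)
        for i in range(K):
            a[i] /= c
        for t in range(s + 1, e):
            c = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += a[i] * A[t, i, j]
                a2[j] = acc * b[t, j]
                c += a2[j]
            ll += np.log(c)
            for j in range(K):
                a[j] = a2[j] / c
        out[jb] = ll


@njit(cache=True)
def viterbi_pass(logA, logb, ptr, logp0, path):
    """Max-product decoding per burst; most likely state written to ``path``.

    Returns the summed best-path log-probability over all bursts.
    """
    nb = ptr.size - 1
    K = logp0.size
    n = logb.shape[0]
    delta = np.empty((n, K))
    bp = np.empty((n, K), np.int32)
    total = 0.0
    for jb in range(nb):
        s = ptr[jb]
        e = ptr[jb + 1]
        for i in range(K):
            delta[s, i] = logp0[i] + logb[s, i]
        for t in range(s + 1, e):
            for j in range(K):
                best = -1e308
                arg = 0
                for i in range(K):
                    v = delta[t - 1, i] + logA[t, i, j]
                    if v > best:
                        best = v
                        arg = i
                delta[t, j] = best + logb[t, j]
                bp[t, j] = arg
        best = -1e308
        arg = 0
        for i in range(K):
            if delta[e - 1, i] > best:
                best = delta[e - 1, i]
                arg = i
        total += best
        path[e - 1] = arg
        for t in range(e - 2, s - 1, -1):
            path[t] = bp[t + 1, path[t + 1]]
    return total


@njit(cache=True)
def pair_time_histogram(times, ch, code_x, code_y, edges, counts):
    """Count ordered photon pairs (x then y) with time difference in bins.

    ``times`` are seconds within one burst; edges ascending.  Used by the
    burst-wise correlation estimator.
    """
    n = times.size
    nbin = edges.size - 1
    tmax = edges[nbin]
    for i in range(n):
        if ch[i] != code_x:
            continue
        for j in range(n):
            if ch[j] != code_y or j == i:
                continue
            d = times[j] - times[i]
            if d <= edges[0] or d >= tmax:
                continue
            lo, hi = 0, nbin
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if d >= edges[mid]:
                    lo = mid
                else:
                    hi = mid
            counts[lo] += 1
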