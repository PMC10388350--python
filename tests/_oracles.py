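"""Independent brute-force oracles for the photon-by-photon HMM.

These never touch the package's forward/backward machinery: likelihoods are
computed by explicit summation over every hidden-state path, with inter-photon
propagators obtained from scipy's matrix exponential.
"""

import itertools

import numpy as np
import scipy.linalg


def enumerate_path_probs(Q, E, p0, colors, gap_ticks, clock_period):
    """Probability of every hidden path for a burst; returns (paths, probs)."""
    K = len(E)
    n = len(colors)
    B = np.column_stack([1.0 - np.asarray(E), np.asarray(E)])
    props = [None] + [scipy.linalg.expm(Q * clock_period * g) for g in gap_ticks[1:]]
    paths = np.array(list(itertools.product(range(K), repeat=n)))
    probs = p0[paths[:, 0]] * B[paths[:, 0], colors[0]]
    for t in range(1, n):
        probs = probs * props[t][paths[:, t - 1], paths[:, t]] \
            * B[paths[:, t], colors[t]]
    return paths, probs


def brute_loglik(Q, E, p0, colors, gap_ticks, clock_period):
    _, probs = enumerate_path_probs(Q, E, p0, colors, gap_ticks, clock_period)
    return np.log(probs.sum())


def brute_viterbi(Q, E, p0, colors, gap_ticks, clock_period):
    """(best path, its log-probability) by exhaustive search."""
    paths, probs = enumerate_path_probs(Q, E, p0, colors, gap_ticks, clock_period)
    k = int(np.argmax(probs))
    return paths[k], np.log(probs[k])


def random_model_and_burst(rng, k_max=3, n_max=8):
    """A random small model plus a random photon burst for oracle checks."""
    K = int(rng.integers(1, k_max + 1))
    n = int(rng.integers(1, n_max + 1))
    clock = 12.5e-9
    # rates spanning slow-to-fast relative to the gaps drawn below
    Q = rng.uniform(0.1, 1.0, (K, K)) * 10.0 ** rng.uniform(2, 6)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    E = rng.uniform(0.02, 0.98, K)
    p0 = rng.dirichlet(np.ones(K))
    colors = rng.integers(0, 2, n).astype(np.int8)
    gaps = np.concatenate([[0], rng.integers(1, 10 ** rng.uniform(1, 5), n - 1)
                           ]).astype(np.int64) if n > 1 else np.zeros(1, np.int64)
    return Q, E, p0, colors, gaps, clock
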