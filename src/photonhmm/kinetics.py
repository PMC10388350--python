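"""Rate-matrix algebra: stationary populations, equilibrium constants and
the two-macrostate thermodynamic cycle.

A fitted condition ("macrostate") is summarised by a continuous-time rate
matrix Q (s^-1, rows sum to zero), the shared per-state FRET efficiencies,
and the stationary distribution pi solving pi Q = 0.  Comparing the apo
(T, tense) and ATP (R, relaxed) macrostates microstate-by-microstate closes
a thermodynamic cycle: horizontal equilibrium constants along the microstate
ladder in each macrostate, and vertical T->R constants alpha_i known up to a
common factor, fixed by alpha_1 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal mol^-1 K^-1

__all__ = [
    "MacrostateModel",
    "ThermoCycle",
    "steady_state",
    "equilibrium_constants",
    "thermo_cycle",
    "validate_rate_matrix",
    "GAS_CONSTANT_KCAL",
]


class ReducibleChainError(ValueError):
    """Rate matrix is reducible; stationary distribution not unique."""


def validate_rate_matrix(Q: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -atol):
        raise ValueError("off-diagonal rates must be non-negative")
    if np.any(np.abs(Q.sum(axis=1)) > atol * max(1.0, np.abs(Q).max())):
        raise ValueError("rows of Q must sum to 0")
    return Q


def _unreachable_states(Q: np.ndarray) -> list[int]:
    """States not in the single closed communicating class (DFS both ways)."""
    n = Q.shape[0]
    adj = Q > 0

    def reach(start, mat):
        seen = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(mat[i]):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return seen

    fwd = reach(0, adj)
    bwd = reach(0, adj.T)
    comm = fwd & bwd
    return sorted(set(range(n)) - comm) if len(comm) < n else []


def steady_state(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi Q = 0, sum pi = 1, pi >= 0.

    Solved from the left null space of Q (equivalently by diagonalizing the
    rate matrix and taking the zero-eigenvalue left eigenvector).
    """
    Q = validate_rate_matrix(Q)
    bad = _unreachable_states(Q)
    if bad:
        raise ReducibleChainError(
            f"rate matrix is reducible; states outside the closed class: {bad}"
        )
    w, vl = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(vl[:, k])
    pi = np.abs(pi)
    pi /= pi.sum()
    # one Richardson step of power-iteration polish for crisp pi Q = 0
    P = np.eye(Q.shape[0]) + Q * (0.1 / max(np.abs(np.diag(Q)).max(), 1e-300))
    for _ in range(5):
        pi = pi @ P
        pi /= pi.sum()
    return pi


@dataclass
class MacrostateModel:
    """A fitted condition fingerprint."""

    condition: str
    rate_matrix: np.ndarray  # s^-1
    efficiencies: np.ndarray  # per-state FRET efficiency, descending
    stationary: np.ndarray = field(default=None)  # computed if omitted

    def __post_init__(self):
        self.rate_matrix = validate_rate_matrix(self.rate_matrix)
        self.efficiencies = np.asarray(self.efficiencies, dtype=float)
        if self.stationary is None:
            self.stationary = steady_state(self.rate_matrix)
        else:
            self.stationary = np.asarray(self.stationary, dtype=float)

    @property
    def mean_dwell_times(self) -> np.ndarray:
        """1 / (total exit rate) per state, seconds."""
        return 1.0 / (-np.diag(self.rate_matrix))


def equilibrium_constants(Q: np.ndarray) -> np.ndarray:
    """K(i -> i+1) = k(i->i+1) / k(i+1->i) along the microstate ladder."""
    Q = validate_rate_matrix(Q)
    n = Q.shape[0]
    K = np.empty(n - 1)
    for i in range(n - 1):
        fwd, bwd = Q[i, i + 1], Q[i + 1, i]
        if bwd <= 0:
            K[i] = np.inf if fwd > 0 else np.nan
        else:
            K[i] = fwd / bwd
    return K


@dataclass
class ThermoCycle:
    """Closed cycle between two macrostates via the shared microstates."""

    K_T: np.ndarray  # horizontal constants, T (apo) macrostate
    K_R: np.ndarray  # horizontal constants, R (ATP) macrostate
    alpha_rel: np.ndarray  # vertical T->R constants relative to alpha_1
    temperature: float  # K
    ddG: np.ndarray  # -RT ln(alpha_i / alpha_1), kcal/mol

    def ddg_between(self, i: int, j: int) -> float:
        """Free-energy difference of the vertical transition from microstate
        i relative to that from microstate j (1-based labels)."""
        r = self.alpha_rel[i - 1] / self.alpha_rel[j - 1]
        return -GAS_CONSTANT_KCAL * self.temperature * np.log(r)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.alpha_rel)
        return pd.DataFrame(
            {
                "i": np.arange(1, n + 1),
                "K_T": np.concatenate([self.K_T, [np.nan]]),
                "K_R": np.concatenate([self.K_R, [np.nan]]),
                "alpha_rel": self.alpha_rel,
                "ddG_kcal_mol": self.ddG,
            }
        )


def thermo_cycle(Q_T: np.ndarray, Q_R: np.ndarray, temperature: float = 295.15) -> ThermoCycle:
    """Build the closed thermodynamic cycle from apo (T) and ATP (R) rates.

    alpha_{i}/alpha_1 = prod_{j<i} K_R(j->j+1) / K_T(j->j+1); cycle closure
    alpha_{i+1}/alpha_i = K_R(i)/K_T(i) holds by construction.  ddG is quoted
    as -RT ln(alpha_i/alpha_1) in kcal/mol.
    """
    K_T = equilibrium_constants(Q_T)
    K_R = equilibrium_constants(Q_R)
    ratios = K_R / K_T
    alpha = np.concatenate([[1.0], np.cumprod(ratios)])
    ddG = -GAS_CONSTANT_KCAL * temperature * np.log(alpha)
    return ThermoCycle(K_T=K_T, K_R=K_R, alpha_rel=alpha, temperature=temperature, ddG=ddG)
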