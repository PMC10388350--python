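"""Synthetic photon-trajectory generator.

Emulates the statistical structure of diffusion-based smFRET data from a
single labeled chaperonin subunit: during each ~1 ms transit through the
confocal spot, a hidden continuous-time Markov chain over K conformational
microstates (submillisecond exchange) modulates the color of donor-excitation
photons — a photon is acceptor-colored with probability E_i, the FRET
efficiency of the state occupied at its arrival time.  Acceptor-excitation
(PIE) photons are all acceptor-colored and carry the stoichiometry signal.

Condition fixtures ("macrostates") are built with the construction
k_ij = c * pi_j (i != j), c = 3000 s^-1, whose stationary distribution is
exactly the target pi and whose single relaxation time 1/c ~ 333 us matches
the observed 300-500 us exchange timescale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .kinetics import steady_state, validate_rate_matrix
from .photons import ACCEPTOR, AEX, DEX, DONOR, Burst, PhotonStream

__all__ = [
    "GroundTruthModel",
    "TruthRecord",
    "make_macrostate_fixture",
    "simulate_state_path",
    "simulate_dataset",
    "simulate_titration",
    "MICROSTATE_EFFICIENCIES",
    "FIXTURE_POPULATIONS",
]

# Shared microstate FRET efficiencies, descending (microstates 1..4)
MICROSTATE_EFFICIENCIES = np.array([0.850, 0.608, 0.419, 0.213])

# Stationary microstate populations per condition.  apo prints as
# 8.4/55.1/29.6/7.0 % (sum 100.1); stored normalised to sum exactly 1.
FIXTURE_POPULATIONS = {
    "apo": np.array([0.084, 0.551, 0.296, 0.070]) / 1.001,
    "atp": np.array([0.048, 0.253, 0.584, 0.115]),
    "adp": np.array([0.085, 0.446, 0.384, 0.085]),
    "atp_es": np.array([0.047, 0.047, 0.254, 0.652]),
}

EXCHANGE_RATE_SCALE = 3000.0  # s^-1, fixture relaxation rate c
DEFAULT_CLOCK_PERIOD = 12.5e-9  # s (80 MHz sync)


@dataclass
class GroundTruthModel:
    """Generative model for synthetic bursts."""

    rate_matrix: np.ndarray  # K x K, s^-1
    efficiencies: np.ndarray  # K, acceptor-color probability per state
    initial_distribution: np.ndarray | None = None  # default: stationary
    burst_duration_mean: float = 1e-3  # s, exponential
    photon_rate: float = 100e3  # detected photons/s, donor excitation
    aex_photon_rate: float = 100e3  # photons/s, acceptor excitation
    background_rates: tuple = (0.0, 0.0)  # photons/s (donor ch, acceptor ch)
    clock_period: float = DEFAULT_CLOCK_PERIOD
    name: str = ""

    def __post_init__(self):
        self.rate_matrix = validate_rate_matrix(self.rate_matrix)
        self.efficiencies = np.asarray(self.efficiencies, dtype=float)
        if np.any((self.efficiencies < 0) | (self.efficiencies > 1)):
            raise ValueError("efficiencies must lie in [0, 1]")
        if self.initial_distribution is None:
            self.initial_distribution = steady_state(self.rate_matrix)
        else:
            self.initial_distribution = np.asarray(self.initial_distribution, float)

    @property
    def n_states(self) -> int:
        return self.rate_matrix.shape[0]

    @property
    def stationary(self) -> np.ndarray:
        return steady_state(self.rate_matrix)


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset."""

    jump_times: list = field(default_factory=list)  # per burst: times (s, burst frame)
    states: list = field(default_factory=list)  # per burst: state per path segment
    photon_states: list = field(default_factory=list)  # per burst: Dex photons' states
    macrostate_labels: np.ndarray | None = None  # per burst (titration mixtures)
    seed: int | None = None
    model_name: str = ""

    def to_json(self, path) -> None:
        obj = {
            "seed": self.seed,
            "model_name": self.model_name,
            "jump_times": [a.tolist() for a in self.jump_times],
            "states": [a.tolist() for a in self.states],
            "photon_states": [a.tolist() for a in self.photon_states],
            "macrostate_labels": (
                None if self.macrostate_labels is None else self.macrostate_labels.tolist()
            ),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def make_macrostate_fixture(name: str, **overrides) -> GroundTruthModel:
    """Condition fixture with printed stationary populations.

    Q is built as k_ij = c * pi_j (i != j) with c = 3000 s^-1, so that
    steady_state(Q) == pi analytically and the relaxation time is 1/c.
    """
    if name not in FIXTURE_POPULATIONS:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURE_POPULATIONS)}"
        )
    pi = FIXTURE_POPULATIONS[name]
    K = pi.size
    Q = EXCHANGE_RATE_SCALE * np.tile(pi, (K, 1))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return GroundTruthModel(
        rate_matrix=Q,
        efficiencies=MICROSTATE_EFFICIENCIES.copy(),
        name=name,
        **overrides,
    )


def simulate_state_path(Q: np.ndarray, duration: float, start_state: int, rng):
    """Exact (Gillespie) realisation of the hidden chain, truncated at duration.

    Returns (jump_times, states): states[k] is occupied on
    [jump_times[k], jump_times[k+1]) with jump_times[0] = 0 and an implicit
    final boundary at `duration`.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    Q = np.asarray(Q, dtype=float)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    times = [0.0]
    states = [int(start_state)]
    t = 0.0
    s = int(start_state)
    while True:
        exit_rate = -Q[s, s]
        if exit_rate <= 0:
            break  # absorbing: single segment to the end
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        probs = Q[s].copy()
        probs[s] = 0.0
        probs /= exit_rate
        s = int(rng.choice(Q.shape[0], p=probs))
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=np.int64)


def _states_at(times: np.ndarray, jump_times: np.ndarray, states: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(jump_times, times, side="right") - 1
    return states[idx]


def _strictly_increasing(ticks: np.ndarray) -> np.ndarray:
    """Enforce strictly increasing integer ticks with minimum step 1."""
    if ticks.size == 0:
        return ticks
    i = np.arange(ticks.size, dtype=np.int64)
    return np.maximum.accumulate(ticks - i) + i


def simulate_dataset(model: GroundTruthModel, n_bursts: int, seed):
    """Simulate a burst dataset.

    Per burst: duration ~ Exp(mean); donor-excitation photons are a Poisson
    process at `photon_rate`, each acceptor-colored with probability
    E_{state(t)}; acceptor-excitation photons are a Poisson process at
    `aex_photon_rate`, all acceptor-colored; optional uniform background in
    each channel (tagged with the matching excitation slot).  Bursts are
    separated by >= 10x the mean duration of dark time.

    Returns (stream, bursts, truth).
    """
    if n_bursts < 1:
        raise ValueError("n_bursts must be >= 1")
    rng = np.random.default_rng(seed)
    p0 = model.initial_distribution / model.initial_distribution.sum()
    E = model.efficiencies
    gap_mean = 10.0 * model.burst_duration_mean

    all_ticks, all_ch, all_slot = [], [], []
    bursts: list[Burst] = []
    truth = TruthRecord(seed=None if not np.isscalar(seed) else int(seed),
                        model_name=model.name)

    t_origin = 0.0
    for _ in range(n_bursts):
        dur = rng.exponential(model.burst_duration_mean)
        start_state = int(rng.choice(p0.size, p=p0))
        jt, st = simulate_state_path(model.rate_matrix, dur, start_state, rng)

        n_dex = rng.poisson(model.photon_rate * dur)
        t_dex = np.sort(rng.uniform(0.0, dur, n_dex))
        ph_states = _states_at(t_dex, jt, st)
        colors = (rng.random(n_dex) < E[ph_states]).astype(np.int8)

        n_aex = rng.poisson(model.aex_photon_rate * dur)
        t_aex = np.sort(rng.uniform(0.0, dur, n_aex))

        times = [t_dex, t_aex]
        chans = [colors, np.full(n_aex, ACCEPTOR, np.int8)]
        slots = [np.zeros(n_dex, np.int8), np.full(n_aex, AEX, np.int8)]
        bg_d, bg_a = model.background_rates
        for bg_rate, ch_code in ((bg_d, DONOR), (bg_a, ACCEPTOR)):
            if bg_rate > 0:
                n_bg = rng.poisson(bg_rate * dur)
                times.append(rng.uniform(0.0, dur, n_bg))
                chans.append(np.full(n_bg, ch_code, np.int8))
                slots.append(np.zeros(n_bg, np.int8))  # background in Dex slot

        t_all = np.concatenate(times)
        if t_all.size == 0:  # burst too short to yield a photon: undetectable
            t_origin += dur + gap_mean * (1.0 + rng.exponential(1.0))
            continue
        order = np.argsort(t_all, kind="stable")
        t_all = t_all[order]
        ch_all = np.concatenate(chans)[order]
        slot_all = np.concatenate(slots)[order]

        ticks = np.round((t_origin + t_all) / model.clock_period).astype(np.int64)
        ticks = _strictly_increasing(ticks)

        start_idx = sum(a.size for a in all_ticks)
        all_ticks.append(ticks)
        all_ch.append(ch_all)
        all_slot.append(slot_all)

        b = Burst(start_idx, start_idx + ticks.size, duration=dur)
        bursts.append(b)
        truth.jump_times.append(jt)
        truth.states.append(st)
        truth.photon_states.append(ph_states)

        t_origin += dur + gap_mean * (1.0 + rng.exponential(1.0))

    stream = PhotonStream(
        np.concatenate(all_ticks) if all_ticks else np.empty(0, np.int64),
        model.clock_period,
        np.concatenate(all_ch) if all_ch else np.empty(0, np.int8),
        np.concatenate(all_slot) if all_slot else np.empty(0, np.int8),
        {"generator": "photonhmm.simulate", "model": model.name},
    )
    from .photons import compute_burst_quantities

    bursts = [compute_burst_quantities(stream, b) for b in bursts]
    return stream, bursts, truth


def hill_fraction(conc, n: float, K: float) -> np.ndarray:
    """Hill saturation Y(c) = c^n / (K^n + c^n)."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        y = np.where(c > 0, 1.0 / (1.0 + (K / np.maximum(c, 1e-300)) ** n), 0.0)
    return y


def simulate_titration(
    conc_list,
    hill_n: float,
    hill_K: float,
    model_apo: GroundTruthModel,
    model_atp: GroundTruthModel,
    n_bursts_per_conc: int,
    seed,
):
    """Concentration-dependent two-macrostate mixture.

    At concentration c each burst is drawn from the ATP-macrostate model with
    probability Y(c) = c^n / (K^n + c^n), else from the apo model.  Returns
    {conc: (stream, bursts, truth)} with per-burst macrostate labels
    (0 = apo, 1 = atp) stored in each truth record.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    out = {}
    for conc, child in zip(conc_list, ss.spawn(len(list(conc_list)))):
        rng = np.random.default_rng(child)
        y = float(hill_fraction(conc, hill_n, hill_K))
        labels = (rng.random(n_bursts_per_conc) < y).astype(np.int8)
        # simulate each burst from its macrostate; stitch into one stream
        streams, bursts, truth, kept = _simulate_mixture(model_apo, model_atp, labels, rng)
        truth.macrostate_labels = labels[kept]
        out[float(conc)] = (streams, bursts, truth)
    return out


def _simulate_mixture(model_apo, model_atp, labels, rng):
    """Burst-wise mixture of two generative models sharing timing settings."""
    models = (model_apo, model_atp)
    all_ticks, all_ch, all_slot = [], [], []
    bursts, truth = [], TruthRecord()
    kept_mask: list = []
    t_origin = 0.0
    gap_mean = 10.0 * model_apo.burst_duration_mean
    clock = model_apo.clock_period
    for lab in labels:
        m = models[int(lab)]
        dur = rng.exponential(m.burst_duration_mean)
        p0 = m.initial_distribution / m.initial_distribution.sum()
        jt, st = simulate_state_path(m.rate_matrix, dur, int(rng.choice(p0.size, p=p0)), rng)
        n_dex = rng.poisson(m.photon_rate * dur)
        t_dex = np.sort(rng.uniform(0.0, dur, n_dex))
        ph_states = _states_at(t_dex, jt, st)
        colors = (rng.random(n_dex) < m.efficiencies[ph_states]).astype(np.int8)
        n_aex = rng.poisson(m.aex_photon_rate * dur)
        t_aex = np.sort(rng.uniform(0.0, dur, n_aex))

        t_all = np.concatenate([t_dex, t_aex])
        if t_all.size == 0:
            kept_mask.append(False)
            t_origin += dur + gap_mean * (1.0 + rng.exponential(1.0))
            continue
        kept_mask.append(True)
        order = np.argsort(t_all, kind="stable")
        ch_all = np.concatenate([colors, np.full(n_aex, ACCEPTOR, np.int8)])[order]
        slot_all = np.concatenate([np.zeros(n_dex, np.int8), np.full(n_aex, AEX, np.int8)])[order]
        ticks = _strictly_increasing(
            np.round((t_origin + t_all[order]) / clock).astype(np.int64)
        )
        start_idx = sum(a.size for a in all_ticks)
        all_ticks.append(ticks)
        all_ch.append(ch_all)
        all_slot.append(slot_all)
        bursts.append(Burst(start_idx, start_idx + ticks.size, duration=dur))
        truth.jump_times.append(jt)
        truth.states.append(st)
        truth.photon_states.append(ph_states)
        t_origin += dur + gap_mean * (1.0 + rng.exponential(1.0))

    stream = PhotonStream(
        np.concatenate(all_ticks) if all_ticks else np.empty(0, np.int64),
        clock,
        np.concatenate(all_ch) if all_ch else np.empty(0, np.int8),
        np.concatenate(all_slot) if all_slot else np.empty(0, np.int8),
    )
    from .photons import compute_burst_quantities

    bursts = [compute_burst_quantities(stream, b) for b in bursts]
    return stream, bursts, truth, np.asarray(kept_mask, dtype=bool)
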