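"""Photon streams, bursts and per-burst FRET quantities.

The raw observable of a diffusion-based smFRET experiment is a stream of
detected photons, each carrying an arrival time (integer ticks of the sync
clock), an emission channel (donor or acceptor detector) and, under pulsed
interleaved excitation (PIE), the excitation slot it was detected in
(donor- or acceptor-excitation period).  Molecules diffusing through the
confocal spot produce short (~1 ms) bursts of elevated count rate; each
burst is attributed to a single molecule transit and summarised by its
proximity ratio E and stoichiometry S.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PhotonStream",
    "Burst",
    "CorrectionSet",
    "read_photon_stream",
    "write_photon_stream",
    "burst_search",
    "compute_burst_quantities",
    "stoichiometry_filter",
    "fret_histogram",
    "bursts_to_table",
]

# channel / slot integer codes used in the arrays
DONOR, ACCEPTOR = 0, 1
DEX, AEX = 0, 1

_CHANNEL_NAMES = {"D": DONOR, "A": ACCEPTOR}
_SLOT_NAMES = {"Dex": DEX, "Aex": AEX}


class FormatError(ValueError):
    """A file does not conform to the declared photon-stream format."""


class DataError(ValueError):
    """Photon records violate a stream invariant (e.g. unsorted timestamps)."""


@dataclass
class PhotonStream:
    """Timestamped, channel-tagged photon records.

    Parameters
    ----------
    timestamps : integer array, clock ticks, monotone non-decreasing
    clock_period : seconds per tick (> 0)
    channel : per-photon emission channel, 0 = donor, 1 = acceptor
    excitation_slot : per-photon PIE slot, 0 = donor excitation, 1 = acceptor
    metadata : free-form provenance map
    """

    timestamps: np.ndarray
    clock_period: float
    channel: np.ndarray
    excitation_slot: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.channel = np.asarray(self.channel, dtype=np.int8)
        self.excitation_slot = np.asarray(self.excitation_slot, dtype=np.int8)
        if self.clock_period <= 0:
            raise DataError("clock_period must be positive")
        n = self.timestamps.size
        if self.channel.size != n or self.excitation_slot.size != n:
            raise DataError("tag arrays must match timestamps length")
        if n > 1 and np.any(np.diff(self.timestamps) < 0):
            raise DataError("timestamps must be sorted non-decreasing")

    def __len__(self):
        return self.timestamps.size

    @property
    def times_s(self) -> np.ndarray:
        """Arrival times in seconds."""
        return self.timestamps * self.clock_period

    def slice(self, start: int, stop: int) -> "PhotonStream":
        return PhotonStream(
            self.timestamps[start:stop],
            self.clock_period,
            self.channel[start:stop],
            self.excitation_slot[start:stop],
            dict(self.metadata),
        )


@dataclass
class Burst:
    """One molecule transit: a half-open index range [start, stop) of a stream."""

    start_index: int
    stop_index: int
    n_dd: int = 0  # donor excitation, donor channel
    n_da: int = 0  # donor excitation, acceptor channel
    n_aa: int = 0  # acceptor excitation, acceptor channel
    duration: float = 0.0  # seconds
    e_raw: float = np.nan  # proximity ratio
    s_raw: float = np.nan  # stoichiometry
    e_corr: float | None = None
    valid: bool = True  # False when E is undefined (no Dex photons)

    @property
    def size(self) -> int:
        return self.stop_index - self.start_index


@dataclass
class CorrectionSet:
    """Leakage l, direct excitation d, detection-efficiency ratio gamma."""

    leakage: float = 0.0
    direct_excitation: float = 0.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.leakage < 0 or self.direct_excitation < 0:
            raise ValueError("leakage and direct_excitation must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_photon_stream(stream: PhotonStream, path, format: str = "photon-hdf5") -> None:
    """Write a stream to Photon-HDF5-style HDF5 or the columnar text dialect."""
    if format == "photon-hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("photon_data")
            g.create_dataset("timestamps", data=stream.timestamps)
            # detectors: 0 donor, 1 acceptor — matched by detectors_specs below
            g.create_dataset("detectors", data=stream.channel.astype(np.int8))
            g.create_dataset("excitation_slots",
                             data=stream.excitation_slot.astype(np.int8))
            spec = g.create_group("timestamps_specs")
            spec.attrs["timestamps_unit"] = stream.clock_period
            ms = g.create_group("measurement_specs")
            ms.attrs["measurement_type"] = "smFRET-PIE"
            for k, v in stream.metadata.items():
                f.attrs[str(k)] = str(v)
    elif format == "columnar-text":
        ch = np.array(["D", "A"])[stream.channel]
        slot = np.array(["Dex", "Aex"])[stream.excitation_slot]
        df = pd.DataFrame(
            {"timestamp": stream.timestamps, "channel": ch, "slot": slot}
        )
        header = f"# clock_period_s={stream.clock_period!r}\n"
        buf = io.StringIO()
        buf.write(header)
        df.to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    else:
        raise FormatError(f"unknown format: {format!r}")


def read_photon_stream(path, format: str = "photon-hdf5") -> PhotonStream:
    """Read a photon stream; round-trips bit-exactly with write_photon_stream."""
    if format == "photon-hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            if "photon_data" not in f:
                raise FormatError("missing required group 'photon_data'")
            g = f["photon_data"]
            for fld in ("timestamps", "detectors", "timestamps_specs"):
                if fld not in g:
                    raise FormatError(f"missing required field 'photon_data/{fld}'")
            ts = g["timestamps"][...]
            ch = g["detectors"][...]
            if "excitation_slots" in g:
                slot = g["excitation_slots"][...]
            else:
                slot = np.zeros_like(ch)
            period = float(g["timestamps_specs"].attrs["timestamps_unit"])
            meta = {k: f.attrs[k] for k in f.attrs}
        return PhotonStream(ts, period, ch, slot, meta)
    elif format == "columnar-text":
        period = 1.0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                if "clock_period_s=" in first:
                    period = float(first.split("clock_period_s=")[1])
                body = fh.read()
            else:
                body = first + fh.read()
        df = pd.read_csv(io.StringIO(body))
        for col in ("timestamp", "channel", "slot"):
            if col not in df.columns:
                raise FormatError(f"missing required column '{col}'")
        try:
            ch = df["channel"].map(_CHANNEL_NAMES).to_numpy(dtype=np.int8)
            slot = df["slot"].map(_SLOT_NAMES).to_numpy(dtype=np.int8)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"bad channel/slot codes: {exc}") from exc
        return PhotonStream(df["timestamp"].to_numpy(np.int64), period, ch, slot)
    else:
        raise FormatError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# Burst search
# ---------------------------------------------------------------------------

def burst_search(
    stream: PhotonStream,
    window_m: int = 10,
    rate_threshold: float = 50e3,
    min_size: int = 30,
) -> list[Burst]:
    """All-photon sliding-window burst search.

    A photon belongs to a burst region when the local rate of the window of
    ``window_m`` consecutive photons starting at it,
    (m-1) / (t[i+m-1] - t[i]), is at least ``rate_threshold``.  Overlapping
    qualifying windows are merged maximally; merged regions shorter than
    ``min_size`` photons are discarded.
    """
    if window_m < 2:
        raise ValueError("window_m must be >= 2")
    if rate_threshold <= 0 or min_size <= 0:
        raise ValueError("thresholds must be positive")
    n = len(stream)
    if n < window_m:
        return []
    t = stream.times_s
    span = t[window_m - 1:] - t[: n - window_m + 1]
    # rate of m photons over their time span; zero span => infinite rate
    with np.errstate(divide="ignore"):
        rate = np.where(span > 0, (window_m - 1) / np.maximum(span, 1e-300), np.inf)
    qual = rate >= rate_threshold  # window starting at i qualifies
    if not qual.any():
        return []
    # maximal merge of overlapping qualifying windows [i, i+m); windows that
    # merely touch (adjacent clusters) start separate bursts
    starts = np.flatnonzero(qual)
    bursts = []
    run_start = int(starts[0])
    run_end = run_start + window_m
    for i in starts[1:]:
        if i < run_end:
            run_end = int(i) + window_m
        else:
            if run_end - run_start >= min_size:
                bursts.append(Burst(run_start, min(run_end, n)))
            run_start = int(i)
            run_end = run_start + window_m
    if run_end - run_start >= min_size:
        bursts.append(Burst(run_start, min(run_end, n)))
    return bursts


# ---------------------------------------------------------------------------
# Per-burst quantities
# ---------------------------------------------------------------------------

def compute_burst_quantities(
    stream: PhotonStream, burst: Burst, corrections: CorrectionSet | None = None
) -> Burst:
    """Fill counts, duration, proximity ratio E, stoichiometry S (and e_corr).

    E uses donor-excitation photons only; acceptor-excitation photons enter
    only through S.  With zero donor-excitation photons E is undefined and the
    burst is flagged invalid (excluded downstream).
    """
    s, e = burst.start_index, burst.stop_index
    if not (0 <= s < e <= len(stream)):
        raise ValueError("burst index range invalid for stream")
    ch = stream.channel[s:e]
    slot = stream.excitation_slot[s:e]
    dex = slot == DEX
    n_dd = int(np.sum(dex & (ch == DONOR)))
    n_da = int(np.sum(dex & (ch == ACCEPTOR)))
    n_aa = int(np.sum((slot == AEX) & (ch == ACCEPTOR)))
    dur = float((stream.timestamps[e - 1] - stream.timestamps[s]) * stream.clock_period)

    out = replace(burst, n_dd=n_dd, n_da=n_da, n_aa=n_aa, duration=dur)
    n_dex = n_dd + n_da
    if n_dex == 0:
        out.e_raw = np.nan
        out.valid = False
    else:
        out.e_raw = n_da / n_dex
        out.valid = True
    tot = n_dex + n_aa
    out.s_raw = n_dex / tot if tot > 0 else np.nan

    if corrections is not None and out.valid:
        l, d, g = corrections.leakage, corrections.direct_excitation, corrections.gamma
        num = n_da - l * n_dd - d * n_aa
        den = g * n_dd + num
        out.e_corr = num / den if den != 0 else np.nan
    return out


def stoichiometry_filter(bursts: list[Burst], s_min: float, s_max: float) -> list[Burst]:
    """Keep bursts with s_min <= S <= s_max (PIE selection of doubly labeled)."""
    if not (0 <= s_min < s_max <= 1):
        raise ValueError("require 0 <= s_min < s_max <= 1")
    return [b for b in bursts if np.isfinite(b.s_raw) and s_min <= b.s_raw <= s_max]


def fret_histogram(
    bursts: list[Burst], n_bins: int = 40, use_corrected: bool = False
) -> pd.DataFrame:
    """Burst-E histogram over [0, 1].

    Returns a DataFrame with columns bin_left, bin_right, count, density.
    Counts sum to the number of included (valid) bursts.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = []
    for b in bursts:
        if not b.valid:
            continue
        v = b.e_corr if use_corrected else b.e_raw
        if v is not None and np.isfinite(v):
            vals.append(v)
    vals = np.clip(np.asarray(vals, dtype=float), 0.0, 1.0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    # np.histogram's last bin is closed so E=1 is counted
    width = edges[1] - edges[0]
    total = counts.sum()
    density = counts / (total * width) if total else np.zeros(n_bins)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "density": density,
        }
    )


def bursts_to_table(bursts: list[Burst]) -> pd.DataFrame:
    """Burst table in the CSV export layout."""
    rows = []
    for i, b in enumerate(bursts):
        rows.append(
            dict(
                burst_id=i,
                start=b.start_index,
                stop=b.stop_index,
                n_dd=b.n_dd,
                n_da=b.n_da,
                n_aa=b.n_aa,
                duration_s=b.duration,
                e_raw=b.e_raw,
                s_raw=b.s_raw,
                e_corr=np.nan if b.e_corr is None else b.e_corr,
            )
        )
    return pd.DataFrame(rows)
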