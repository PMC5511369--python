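"""Spike-train cross-correlograms normalized to standard scores.

The correlogram counts ordered spike pairs by lag (time of a spike in train 2
minus time of a spike in train 1) in 1 ms bins.  Under the Poisson null the
expected count per bin is E = lambda1 * lambda2 * dt * T where lambda1 and
lambda2 are the average firing rates and T the recording time; the counts are
normalized to standard scores Z = (C - E) / sqrt(E).

A bin is called a significant peak when its Z score exceeds the Z score of
every other bin within +/-200 ms by more than three (the difference of Z
scores is > 3).  A looser reading (exceeding only the two immediately
adjacent bins) is exposed as ``mode='adjacent'``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

BIN_WIDTH_MS = 1.0
NEIGHBOURHOOD_MS = 200.0
Z_DIFFERENCE = 3.0


@dataclass(frozen=True)
class SpikeTrain:
    """A sorted spike-time sequence over a recording of known duration."""

    spike_times_ms: np.ndarray
    duration_ms: float

    def __post_init__(self):
        t = np.asarray(self.spike_times_ms, dtype=float)
        object.__setattr__(self, "spike_times_ms", t)
        if self.duration_ms <= 0:
            raise ValidationError("duration_ms must be positive")
        if t.ndim != 1:
            raise ValidationError("spike times must be a 1-D sequence")
        if t.size and (t[0] < 0 or t[-1] > self.duration_ms):
            raise ValidationError("spike times must lie in [0, duration_ms]")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_ms.size)

    @property
    def rate_hz(self) -> float:
        return self.n_spikes / (self.duration_ms / 1000.0)


@dataclass
class Correlogram:
    """Binned lag histogram with its Poisson normalization."""

    lags_ms: np.ndarray          # bin centers, integer multiples of bin width
    counts: np.ndarray           # C(lag)
    expected: float              # E = lambda1 * lambda2 * dt * T (per bin)
    sigma: float                 # sqrt(E)
    z_scores: np.ndarray         # (C - E) / sigma
    rate1_hz: float
    rate2_hz: float
    duration_ms: float
    bin_width_ms: float = BIN_WIDTH_MS
    meta: dict = field(default_factory=dict)

    @property
    def window_ms(self) -> float:
        return float(self.lags_ms[-1])


def crosscorrelogram(
    train1: SpikeTrain,
    train2: SpikeTrain,
    window_ms: float = 500.0,
    bin_width_ms: float = BIN_WIDTH_MS,
) -> Correlogram:
    """Cross-correlogram of two trains over lags in [-window, +window].

    The lag of an ordered pair is t2 - t1; each pair falls in the bin whose
    center (an integer multiple of the bin width) is nearest, which makes
    ``crosscorrelogram(a, b)`` and ``crosscorrelogram(b, a)`` exactly
    mirror images of each other.
    """
    if train1.n_spikes == 0 or train2.n_spikes == 0:
        raise ValidationError("cross-correlogram of an empty train is undefined")
    if window_ms < NEIGHBOURHOOD_MS:
        raise ValidationError(
            f"window must cover at least +/-{NEIGHBOURHOOD_MS:g} ms"
        )
    if abs(train1.duration_ms - train2.duration_ms) > 1e-9:
        raise ValidationError("trains must share the same recording duration")
    dt = float(bin_width_ms)
    n_side = int(round(window_ms / dt))
    lags = np.arange(-n_side, n_side + 1) * dt
    counts = np.zeros(lags.size, dtype=np.int64)

    t1 = train1.spike_times_ms
    t2 = train2.spike_times_ms
    half = n_side * dt + dt / 2.0
    lo = np.searchsorted(t2, t1 - half, side="left")
    hi = np.searchsorted(t2, t1 + half, side="right")
    for a, (i, j) in zip(t1, zip(lo, hi)):
        if i == j:
            continue
        b = np.rint((t2[i:j] - a) / dt).astype(np.int64) + n_side
        inside = (b >= 0) & (b < counts.size)
        np.add.at(counts, b[inside], 1)

    T = train1.duration_ms
    lam1 = train1.n_spikes / T  # spikes per ms
    lam2 = train2.n_spikes / T
    expected = lam1 * lam2 * dt * T
    sigma = float(np.sqrt(expected))
    z = (counts - expected) / sigma
    return Correlogram(
        lags_ms=lags,
        counts=counts,
        expected=float(expected),
        sigma=sigma,
        z_scores=z,
        rate1_hz=train1.rate_hz,
        rate2_hz=train2.rate_hz,
        duration_ms=float(T),
        bin_width_ms=dt,
    )


def significant_peaks(
    corr: Correlogram,
    z_difference: float = Z_DIFFERENCE,
    neighbourhood_ms: float = NEIGHBOURHOOD_MS,
    mode: str = "all",
) -> list[float]:
    """Lags (ms) of bins whose Z score exceeds comparison bins by > 3.

    ``mode='all'`` (default): the bin must exceed every other bin within the
    +/-200 ms neighbourhood.  ``mode='adjacent'``: it must exceed its two
    immediately adjacent bins.  Bins near the window edge are compared
    against their truncated neighbourhood.
    """
    if mode not in ("all", "adjacent"):
        raise ValidationError("mode must be 'all' or 'adjacent'")
    z = corr.z_scores
    lags = corr.lags_ms
    if lags[-1] < neighbourhood_ms:
        raise ValidationError(
            f"correlogram window narrower than the +/-{neighbourhood_ms:g} ms "
            "comparison neighbourhood"
        )
    n_nb = int(round(neighbourhood_ms / corr.bin_width_ms))
    out = []
    for b in range(z.size):
        if mode == "adjacent":
            nb = [i for i in (b - 1, b + 1) if 0 <= i < z.size]
        else:
            i0 = max(0, b - n_nb)
            i1 = min(z.size, b + n_nb + 1)
            nb = [i for i in range(i0, i1) if i != b]
        if nb and all(z[b] - z[i] > z_difference for i in nb):
            out.append(float(lags[b]))
    return out


def correlogram_frame(corr: Correlogram):
    """CSV-ready table with columns (lag_ms, count, expected, z)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "lag_ms": corr.lags_ms,
            "count": corr.counts,
            "expected": np.full(corr.lags_ms.size, corr.expected),
            "z": corr.z_scores,
        }
    )


def write_correlogram_csv(corr: Correlogram, path) -> None:
    correlogram_frame(corr).to_csv(path, index=False)


def write_spike_trains_csv(trains: dict[int, SpikeTrain], path) -> None:
    """Two-column CSV (cell_id, time_ms).  The recording duration is not part
    of the format; pass it to :func:`read_spike_trains_csv` when loading."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell_id", "time_ms"])
        for cid in sorted(trains):
            for t in trains[cid].spike_times_ms:
                w.writerow([cid, repr(float(t))])


def read_spike_trains_csv(path, duration_ms: float) -> dict[int, SpikeTrain]:
    """Read a two-column (cell_id, time_ms) CSV into SpikeTrains."""
    times: dict[int, list[float]] = {}
    with open(path, newline="") as fh:
        r = csv.DictReader(fh)
        if r.fieldnames is None or not {"cell_id", "time_ms"} <= set(r.fieldnames):
            raise ValidationError(
                "spike-train CSV must have columns cell_id, time_ms"
            )
        for row in r:
            times.setdefault(int(row["cell_id"]), []).append(float(row["time_ms"]))
    return {
        cid: SpikeTrain(np.sort(np.asarray(ts)), duration_ms)
        for cid, ts in times.items()
    }
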