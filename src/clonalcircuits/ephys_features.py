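"""Membrane/firing feature extraction and FS vs non-FS classification.

Nine features are measured from a current-clamp step family (one
subthreshold hyperpolarizing step plus 1 s depolarizing steps): resting
membrane potential, input resistance, AP threshold, AP half-width, AP rise
and decay time constants, maximal firing frequency within the 1 s step, AHP
amplitude, AHP time from peak, and the spike-frequency adaptation ratio
(last interspike interval divided by the first).

A cell is called fast-spiking (FS) iff it satisfies all nine threshold
criteria (max firing >= 80 Hz, AHP amplitude >= 8 mV, AP threshold >= -35 mV,
input resistance <= 300 MOhm, adaptation ratio <= 2.5, half-width <= 1.7 ms,
rise <= 1.9 ms, decay <= 7.5 ms, AHP time <= 6.5 ms); everything else is
non-FS.  The conjunction is strict: the published rule lists bounds only, so
the parameter-free AND of all nine is implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import FeatureUndefinedError, ValidationError

# operational spike-threshold criterion on the voltage derivative
DVDT_THRESHOLD_MV_PER_MS = 20.0
SPIKE_PROMINENCE_MV = 20.0
AHP_SEARCH_MS = 15.0


@dataclass(frozen=True)
class Sweep:
    """One current-clamp sweep with a known injected step."""

    trace_mV: np.ndarray
    sampling_rate_hz: float
    amp_pA: float
    onset_ms: float
    duration_ms: float


@dataclass
class MembraneFeatures:
    rmp_mV: float = math.nan
    input_resistance_MOhm: float = math.nan
    ap_threshold_mV: float = math.nan
    ap_halfwidth_ms: float = math.nan
    ap_rise_ms: float = math.nan
    ap_decay_ms: float = math.nan
    max_firing_Hz: float = math.nan
    ahp_amp_mV: float = math.nan
    ahp_time_ms: float = math.nan
    adaptation_ratio: float = math.nan

    def undefined(self) -> list[str]:
        return [f.name for f in fields(self) if not math.isfinite(getattr(self, f.name))]


@dataclass(frozen=True)
class SubtypeCriteria:
    """The nine FS bounds; defaults are the published values."""

    max_firing_ge: float = 80.0
    ahp_amp_ge: float = 8.0
    ap_threshold_ge: float = -35.0
    input_resistance_le: float = 300.0
    adaptation_ratio_le: float = 2.5
    halfwidth_le: float = 1.7
    rise_le: float = 1.9
    decay_le: float = 7.5
    ahp_time_le: float = 6.5


DEFAULT_CRITERIA = SubtypeCriteria()


def _spike_peaks(v: np.ndarray, rate_hz: float) -> np.ndarray:
    dist = max(1, int(round(0.001 * rate_hz)))  # >= 1 ms apart
    max_width = max(2, int(round(0.005 * rate_hz)))  # APs are < 5 ms wide
    peaks, _ = find_peaks(
        v,
        prominence=SPIKE_PROMINENCE_MV,
        distance=dist,
        width=(None, max_width),
        rel_height=0.5,
    )
    return peaks


def _threshold_index(v: np.ndarray, peak: int, rate_hz: float) -> Optional[int]:
    """Last sub-criterion sample before the peak, by the forward-difference
    dV/dt >= 20 mV/ms rule; returns the first supra-criterion index."""
    dt_ms = 1000.0 / rate_hz
    i = peak
    seen_upstroke = False
    while i > 0:
        dvdt = (v[i] - v[i - 1]) / dt_ms
        if dvdt >= DVDT_THRESHOLD_MV_PER_MS:
            seen_upstroke = True
        elif seen_upstroke:
            return i  # first sample of the suprathreshold upstroke
        i -= 1
    return None


def _cross_time(v, i0, i1, level, rate_hz, rising):
    """Linear-interpolated crossing time (ms) of `level` between samples."""
    dt_ms = 1000.0 / rate_hz
    for i in range(i0, i1):
        a, b = v[i], v[i + 1]
        if (rising and a < level <= b) or (not rising and a >= level > b):
            frac = (level - a) / (b - a) if b != a else 0.0
            return (i + frac) * dt_ms
    return None


def _spike_shape(v: np.ndarray, peak: int, next_peak: Optional[int], rate_hz: float):
    """Per-spike threshold, half-width, rise, decay, AHP amplitude/time."""
    rate = rate_hz
    dt_ms = 1000.0 / rate
    thr_idx = _threshold_index(v, peak, rate)
    if thr_idx is None:
        return None
    thr = v[thr_idx]
    amp = v[peak] - thr
    if amp <= 0:
        return None
    half = thr + amp / 2.0
    lo10, hi90 = thr + 0.1 * amp, thr + 0.9 * amp
    t_up_half = _cross_time(v, thr_idx - 1 if thr_idx else 0, peak, half, rate, True)
    t10 = _cross_time(v, thr_idx - 1 if thr_idx else 0, peak, lo10, rate, True)
    t90 = _cross_time(v, thr_idx - 1 if thr_idx else 0, peak, hi90, rate, True)
    end = len(v) - 1 if next_peak is None else next_peak
    end = min(end, peak + int(round(AHP_SEARCH_MS / dt_ms)))
    if end <= peak + 1:
        return None
    t_dn_half = _cross_time(v, peak, end, half, rate, False)
    trough_rel = int(np.argmin(v[peak : end + 1]))
    trough = peak + trough_rel
    ahp_amp = thr - v[trough]
    ahp_time = (trough - peak) * dt_ms
    if None in (t_up_half, t_dn_half, t10, t90):
        return None
    halfwidth = t_dn_half - t_up_half
    rise = t90 - t10
    # single-exponential fit of the repolarization toward the trough
    lvl_hi = thr + 0.9 * amp
    lvl_lo = v[trough] + 0.1 * amp
    seg = [i for i in range(peak, trough + 1) if lvl_lo <= v[i] <= lvl_hi]
    decay = math.nan
    if len(seg) >= 3:
        t = np.array(seg, float) * dt_ms
        y = np.log(v[seg] - v[trough] + 0.05)
        slope = np.polyfit(t, y, 1)[0]
        if slope < 0:
            decay = -1.0 / slope
    return {
        "threshold": thr,
        "halfwidth": halfwidth,
        "rise": rise,
        "decay": decay,
        "ahp_amp": ahp_amp,
        "ahp_time": ahp_time,
        "peak_time_ms": peak * dt_ms,
    }


def extract_features(sweeps: Sequence[Sweep]) -> MembraneFeatures:
    """Extract the nine-feature vector from a current-clamp step family.

    Requires at least one subthreshold (non-spiking, negative-current) sweep
    for input resistance; firing features come from the sweep with the most
    spikes.  When no sweep elicits spikes, the firing-dependent fields are
    returned as NaN (flagged undefined) rather than raising.
    """
    if not sweeps:
        raise ValidationError("empty sweep family")
    rate = sweeps[0].sampling_rate_hz
    feats = MembraneFeatures()

    # resting potential: pre-stimulus mean pooled over sweeps
    pre = []
    for s in sweeps:
        a = int(round(s.onset_ms / 1000.0 * rate))
        pre.append(s.trace_mV[:a])
    feats.rmp_mV = float(np.mean(np.concatenate(pre)))

    spike_idx = {}
    for k, s in enumerate(sweeps):
        a = int(round(s.onset_ms / 1000.0 * rate))
        b = int(round((s.onset_ms + s.duration_ms) / 1000.0 * rate))
        peaks = _spike_peaks(np.asarray(s.trace_mV, float), rate)
        spike_idx[k] = peaks[(peaks >= a) & (peaks < b)]

    # input resistance from the subthreshold hyperpolarizing step
    for k, s in enumerate(sweeps):
        if s.amp_pA < 0 and len(spike_idx[k]) == 0:
            a = int(round(s.onset_ms / 1000.0 * rate))
            b = int(round((s.onset_ms + s.duration_ms) / 1000.0 * rate))
            ss_start = b - max(1, int(round(0.2 * (b - a))))
            dv = float(np.mean(s.trace_mV[ss_start:b])) - float(np.mean(s.trace_mV[:a]))
            feats.input_resistance_MOhm = 1000.0 * dv / s.amp_pA
            break

    supra = [k for k in spike_idx if len(spike_idx[k]) > 0]
    if not supra:
        return feats  # firing fields stay flagged undefined

    counts = {k: len(spike_idx[k]) for k in supra}
    best = max(supra, key=lambda k: counts[k])
    s = sweeps[best]
    feats.max_firing_Hz = counts[best] / (s.duration_ms / 1000.0)

    # AP threshold from the first spike of the lowest suprathreshold sweep
    ref = min(supra, key=lambda k: sweeps[k].amp_pA)
    v_ref = np.asarray(sweeps[ref].trace_mV, float)
    ti = _threshold_index(v_ref, spike_idx[ref][0], rate)
    if ti is not None:
        feats.ap_threshold_mV = float(v_ref[ti])

    # waveform metrics averaged over the first spikes of the max-firing sweep
    v = np.asarray(s.trace_mV, float)
    peaks = spike_idx[best]
    shapes = []
    use = peaks[:-1] if len(peaks) > 1 else peaks
    for i, p in enumerate(use[:3]):
        nxt = peaks[i + 1] if i + 1 < len(peaks) else None
        sh = _spike_shape(v, int(p), None if nxt is None else int(nxt), rate)
        if sh is not None:
            shapes.append(sh)
    if shapes:
        for src, dst in (
            ("halfwidth", "ap_halfwidth_ms"),
            ("rise", "ap_rise_ms"),
            ("decay", "ap_decay_ms"),
            ("ahp_amp", "ahp_amp_mV"),
            ("ahp_time", "ahp_time_ms"),
        ):
            vals = [sh[src] for sh in shapes if math.isfinite(sh[src])]
            if vals:
                setattr(feats, dst, float(np.mean(vals)))

    if len(peaks) >= 3:
        isis = np.diff(peaks) * 1000.0 / rate
        feats.adaptation_ratio = float(isis[-1] / isis[0])
    elif len(peaks) >= 1:
        feats.adaptation_ratio = math.nan  # undefined with < 3 spikes
    return feats


def classify_subtype(
    features: MembraneFeatures, criteria: SubtypeCriteria = DEFAULT_CRITERIA
) -> str:
    """'FS' iff every one of the nine bounds holds, else 'nonFS'."""
    missing = features.undefined()
    if missing:
        raise FeatureUndefinedError(missing)
    fs = (
        features.max_firing_Hz >= criteria.max_firing_ge
        and features.ahp_amp_mV >= criteria.ahp_amp_ge
        and features.ap_threshold_mV >= criteria.ap_threshold_ge
        and features.input_resistance_MOhm <= criteria.input_resistance_le
        and features.adaptation_ratio <= criteria.adaptation_ratio_le
        and features.ap_halfwidth_ms <= criteria.halfwidth_le
        and features.ap_rise_ms <= criteria.rise_le
        and features.ap_decay_ms <= criteria.decay_le
        and features.ahp_time_ms <= criteria.ahp_time_le
    )
    return "FS" if fs else "nonFS"


def features_frame(cells: dict[int, Sequence[Sweep]], criteria: SubtypeCriteria = DEFAULT_CRITERIA):
    """One row per cell: the nine features plus cell_id and subtype_call."""
    import pandas as pd

    rows = []
    for cell_id, sweeps in cells.items():
        f = extract_features(sweeps)
        try:
            call = classify_subtype(f, criteria)
        except FeatureUndefinedError:
            call = "undefined"
        row = {"cell_id": cell_id}
        row.update({fl.name: getattr(f, fl.name) for fl in fields(MembraneFeatures)})
        row["subtype_call"] = call
        rows.append(row)
    return pd.DataFrame(rows)
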