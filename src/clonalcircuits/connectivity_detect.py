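"""Electrical- and chemical-connection calls on paired recordings.

Electrical coupling: during the 200 ms, -200 pA step in the driver, the
trial-averaged receiver membrane potential must co-hyperpolarize by more than
0.1 mV (steady-state mean of the last 100 ms of the pulse minus a 50 ms
pre-pulse baseline).  The coupling coefficient is the receiver deflection
divided by the driver deflection over the same epochs.

Chemical connection: with the postsynaptic cell voltage-clamped, the
AP-peak-triggered average postsynaptic current must exceed 0.5 pA within
1-5 ms after the presynaptic AP peak.  Because a gap junction alone also
produces AP-locked current in the clamped cell, the detector first estimates
the gap conductance from the hyperpolarizing epoch of the same trials (which
engages electrical but not chemical synapses) and subtracts the predicted
junctional current from the postsynaptic trace before applying the 0.5 pA
criterion; this is the operational form of the hyperpolarization-based
electrical-vs-chemical disambiguation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InsufficientDataError, ProtocolError
from .ephys_features import _spike_peaks
from .simcircuit import RecordingSession, Trial

PSC_ONSET_FRACTION = 0.2  # latency read-out: first crossing of 20% of the extremum


@dataclass(frozen=True)
class DetectionCriteria:
    electrical_min_mV: float = 0.1
    chemical_min_pA: float = 0.5
    chemical_window_ms: tuple[float, float] = (1.0, 5.0)
    min_trials_per_mode: int = 10
    hyper_baseline_ms: float = 50.0
    hyper_steady_ms: float = 100.0
    psc_measure: str = "peak"  # 'peak' (extremum of the average) or 'mean'
    holding_preference_mV: float = -70.0

    def __post_init__(self):
        lo, hi = self.chemical_window_ms
        if not lo < hi:
            raise ValueError("chemical window must have lower < upper")
        if self.electrical_min_mV <= 0 or self.chemical_min_pA <= 0:
            raise ValueError("detection thresholds must be positive")


DEFAULT_CRITERIA = DetectionCriteria()


@dataclass
class ElectricalResult:
    driver: int
    receiver: int
    coupled: bool
    receiver_deflection_mV: float
    driver_deflection_mV: float
    coupling_coefficient: float
    n_trials: int


@dataclass
class ChemicalResult:
    pre: int
    post: int
    connected: bool
    psc_amp_pA: float
    latency_ms: float
    peak_time_ms: float
    n_trials: int
    n_aps: int


@dataclass
class ConnectionResult:
    pair: tuple[int, int]
    electrical_coupled: bool
    coupling_coefficient: float
    electrical_by_direction: dict[tuple[int, int], ElectricalResult] = field(
        default_factory=dict
    )
    chemical_by_direction: dict[tuple[int, int], ChemicalResult] = field(
        default_factory=dict
    )

    @property
    def directionality(self) -> str:
        conn = [r.connected for r in self.chemical_by_direction.values()]
        n = sum(conn)
        return {0: "none", 1: "uni", 2: "bi"}[n]


def _hyper_epoch_indices(session: RecordingSession, criteria: DetectionCriteria):
    pulse = session.protocol.hyperpolarizing_pulse
    if pulse is None:
        raise ProtocolError("protocol has no hyperpolarizing pulse")
    onset, dur, _amp = pulse
    rate = session.sampling_rate_hz
    b0 = int(round((onset - criteria.hyper_baseline_ms) / 1000.0 * rate))
    b1 = int(round(onset / 1000.0 * rate))
    s0 = int(round((onset + dur - criteria.hyper_steady_ms) / 1000.0 * rate))
    s1 = int(round((onset + dur) / 1000.0 * rate))
    if b0 < 0:
        raise ProtocolError("hyperpolarizing pulse too early for a 50 ms baseline")
    return (b0, b1), (s0, s1)


def _deflection(trace: np.ndarray, base, steady) -> float:
    return float(np.mean(trace[steady[0] : steady[1]]) - np.mean(trace[base[0] : base[1]]))


def detect_electrical(
    session: RecordingSession,
    driver: int,
    receiver: int,
    criteria: DetectionCriteria = DEFAULT_CRITERIA,
) -> ElectricalResult:
    """Coupling call from the driver's hyperpolarizing epoch under all-cell
    current clamp."""
    trials = session.trials_for(driver, "electrical")
    if len(trials) < criteria.min_trials_per_mode:
        raise InsufficientDataError(
            f"{len(trials)} current-clamp trials for driver {driver}; "
            f"need {criteria.min_trials_per_mode}"
        )
    base, steady = _hyper_epoch_indices(session, criteria)
    avg = np.mean([t.traces for t in trials], axis=0)
    d_defl = _deflection(avg[driver], base, steady)
    r_defl = _deflection(avg[receiver], base, steady)
    if d_defl >= -1.0:
        raise ProtocolError(f"driver {driver} not hyperpolarized during the pulse")
    coupled = r_defl < 0 and abs(r_defl) > criteria.electrical_min_mV
    cc = r_defl / d_defl
    return ElectricalResult(
        driver=driver,
        receiver=receiver,
        coupled=bool(coupled),
        receiver_deflection_mV=r_defl,
        driver_deflection_mV=d_defl,
        coupling_coefficient=cc,
        n_trials=len(trials),
    )


def _chemical_trials(session, pre, post, criteria) -> list[Trial]:
    trials = [
        t
        for t in session.trials_for(pre, "chemical")
        if t.clamp[post] == "vc"
    ]
    preferred = [
        t for t in trials if t.holding_mV[post] == criteria.holding_preference_mV
    ]
    return preferred if preferred else trials


def detect_chemical(
    session: RecordingSession,
    pre: int,
    post: int,
    criteria: DetectionCriteria = DEFAULT_CRITERIA,
) -> ChemicalResult:
    """Chemical call from AP-peak-triggered postsynaptic currents."""
    trials = _chemical_trials(session, pre, post, criteria)
    if len(trials) < criteria.min_trials_per_mode:
        raise InsufficientDataError(
            f"{len(trials)} voltage-clamp trials for pair ({pre}->{post}); "
            f"need {criteria.min_trials_per_mode}"
        )
    rate = session.sampling_rate_hz
    avg = np.mean([t.traces for t in trials], axis=0)
    v_pre = avg[pre]
    i_post = avg[post].astype(float)

    # junctional-current subtraction: slope of post current vs driver voltage
    # over the hyperpolarizing epoch, where chemical synapses are silent
    base, steady = _hyper_epoch_indices(session, criteria)
    dv = _deflection(v_pre, base, steady)
    di = _deflection(i_post, base, steady)
    if abs(dv) > 1.0:
        i_post = i_post - (di / dv) * v_pre

    peaks = _spike_peaks(np.asarray(v_pre, float), rate)
    if len(peaks) == 0:
        raise ProtocolError(
            f"no presynaptic action potential detected for driver {pre} "
            f"in its voltage-clamp trials"
        )
    lo, hi = criteria.chemical_window_ms
    # only APs whose pre-peak baseline window is uncontaminated by the tail of
    # a preceding PSC are used (the brief isolated pulses of the protocol)
    min_gap_ms = 5.0 + hi + 5.0
    isolated = [
        p
        for k, p in enumerate(peaks)
        if k == 0 or (p - peaks[k - 1]) / rate * 1000.0 >= min_gap_ms
    ]
    if isolated:
        peaks = isolated
    pre_n = int(round(5.0 / 1000.0 * rate))
    win_n = int(round(hi / 1000.0 * rate))
    segs = []
    for p in peaks:
        if p - pre_n < 0 or p + win_n >= len(i_post):
            continue
        seg = i_post[p - pre_n : p + win_n + 1].copy()
        seg -= np.mean(seg[:pre_n])  # baseline: (-5, 0] ms before the AP peak
        segs.append(seg)
    if not segs:
        raise ProtocolError("presynaptic APs too close to the trace edges")
    resp = np.mean(segs, axis=0)
    t_rel = (np.arange(len(resp)) - pre_n) / rate * 1000.0
    in_win = (t_rel > lo) & (t_rel <= hi)
    window = resp[in_win]
    if criteria.psc_measure == "mean":
        amp = float(np.mean(window))
        peak_t = float(t_rel[in_win][np.argmax(np.abs(window))])
    else:
        k = int(np.argmax(np.abs(window)))
        amp = float(window[k])
        peak_t = float(t_rel[in_win][k])
    connected = abs(amp) > criteria.chemical_min_pA
    latency = np.nan
    if connected:
        # onset: first crossing of a fixed fraction of the extremum after the peak
        post_peak = resp[pre_n:]
        t_post = t_rel[pre_n:]
        crossing = np.nonzero(np.abs(post_peak) >= PSC_ONSET_FRACTION * abs(amp))[0]
        latency = float(t_post[crossing[0]]) if len(crossing) else peak_t
    return ChemicalResult(
        pre=pre,
        post=post,
        connected=bool(connected),
        psc_amp_pA=amp,
        latency_ms=latency,
        peak_time_ms=peak_t,
        n_trials=len(trials),
        n_aps=len(segs),
    )


def classify_pair(
    session: RecordingSession,
    i: int,
    j: int,
    criteria: DetectionCriteria = DEFAULT_CRITERIA,
) -> ConnectionResult:
    """Full pair call: electrical probed from both sides (coupled if either
    direction passes; gap junctions are bidirectional), chemical probed in
    both directions independently."""
    e_ij = detect_electrical(session, i, j, criteria)
    e_ji = detect_electrical(session, j, i, criteria)
    coupled = e_ij.coupled or e_ji.coupled
    cc = float(np.mean([e_ij.coupling_coefficient, e_ji.coupling_coefficient]))
    c_ij = detect_chemical(session, i, j, criteria)
    c_ji = detect_chemical(session, j, i, criteria)
    return ConnectionResult(
        pair=(min(i, j), max(i, j)),
        electrical_coupled=coupled,
        coupling_coefficient=cc,
        electrical_by_direction={(i, j): e_ij, (j, i): e_ji},
        chemical_by_direction={(i, j): c_ij, (j, i): c_ji},
    )


def connection_matrix(
    session: RecordingSession, criteria: DetectionCriteria = DEFAULT_CRITERIA
) -> list[ConnectionResult]:
    """classify_pair over every unordered pair, ordered by cell id."""
    n = session.n_cells
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(classify_pair(session, i, j, criteria))
    return out


def connections_frame(results: list[ConnectionResult]):
    """One row per ordered direction per pair (CSV-ready)."""
    import pandas as pd

    rows = []
    for r in results:
        for (a, b), chem in r.chemical_by_direction.items():
            elec = r.electrical_by_direction[(a, b)]
            rows.append(
                {
                    "pre": a,
                    "post": b,
                    "electrical_coupled": r.electrical_coupled,
                    "deflection_mV": elec.receiver_deflection_mV,
                    "coupling_coefficient": r.coupling_coefficient,
                    "chemical_connected": chem.connected,
                    "psc_amp_pA": chem.psc_amp_pA,
                    "latency_ms": chem.latency_ms,
                    "n_trials": elec.n_trials + chem.n_trials,
                }
            )
    return pd.DataFrame(rows)


def detected_graph(results: list[ConnectionResult]):
    """(electrical edge set, directed chemical edge set) from the calls."""
    elec = {r.pair for r in results if r.electrical_coupled}
    chem = {
        d
        for r in results
        for d, c in r.chemical_by_direction.items()
        if c.connected
    }
    return elec, chem


def ground_truth_graph(circuit) -> tuple[set, set]:
    """Edge sets of a CircuitSpec in the same form as detected_graph."""
    elec = {(i, j) for i, j, g in circuit.gap_junctions if g > 0}
    chem = {(s.pre, s.post) for s in circuit.chem_synapses if s.peak_conductance_nS > 0}
    return elec, chem
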