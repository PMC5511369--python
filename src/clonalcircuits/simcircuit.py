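"""Synthetic circuits, stimulation protocols, and paired-recording simulation.

This module is the ground-truth generator for the whole pipeline.  It builds
small circuits of leaky single-compartment neurons connected by gap junctions
(ohmic, bidirectional) and delayed GABAergic conductance synapses, drives one
cell at a time with the paired-recording stimulation protocol (brief and long
suprathreshold depolarizations plus a 200 ms hyperpolarizing step), and
returns multi-trial voltage/current traces with known connectivity so that
every downstream detector can be validated against a known answer.

Action potentials are stamped parametric waveforms: when the membrane crosses
threshold the voltage follows a precomputed template whose peak, half-width,
10-90% rise time, repolarization time constant, AHP amplitude and AHP latency
are direct parameters.  This keeps the features the subtype classifier
measures exactly controllable, which a conductance-based spike mechanism
would not.

Units: mV, pA, nS, pF, ms throughout (so g*V is pA and C/g is ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .errors import SimulationError, ValidationError

DT_MS = 0.05  # forward-Euler step
SAMPLING_HZ = 10_000.0  # recorded sampling rate (two integration substeps/sample)
SUBSTEPS = int(round(1000.0 / SAMPLING_HZ / DT_MS))

# default measurement-noise levels of the synthetic rig; the slice noise floor
# is not a published quantity, these are free parameters of the generator
DEFAULT_NOISE_SD_MV = 0.05
DEFAULT_NOISE_SD_PA = 0.5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusProtocol:
    """Current-injection protocol used to probe every pair.

    ``pulses`` is a sorted, non-overlapping list of
    ``(onset_ms, duration_ms, amplitude_pA)``.
    """

    pulses: tuple[tuple[float, float, float], ...]
    trial_length_ms: float
    n_trials_electrical: int = 10
    n_trials_chemical: int = 10

    def __post_init__(self):
        last_off = 0.0
        for onset, dur, _amp in self.pulses:
            if dur <= 0:
                raise ValidationError("pulse durations must be positive")
            if onset < last_off:
                raise ValidationError("pulses must be sorted and non-overlapping")
            last_off = onset + dur
        if self.trial_length_ms < last_off:
            raise ValidationError("trial_length_ms shorter than the last pulse offset")
        if self.n_trials_electrical < 1 or self.n_trials_chemical < 1:
            raise ValidationError("trial counts must be positive")

    @property
    def hyperpolarizing_pulse(self) -> Optional[tuple[float, float, float]]:
        for p in self.pulses:
            if p[2] < 0:
                return p
        return None

    @property
    def brief_pulses(self) -> tuple[tuple[float, float, float], ...]:
        return tuple(p for p in self.pulses if p[2] > 0 and p[1] <= 10.0)

    def current_waveform(self, dt_ms: float, n_steps: int) -> np.ndarray:
        """Injected current sampled on the integration grid."""
        out = np.zeros(n_steps)
        for onset, dur, amp in self.pulses:
            a = int(round(onset / dt_ms))
            b = int(round((onset + dur) / dt_ms))
            out[a:b] = amp
        return out

    def to_dict(self) -> dict:
        return {
            "pulses": [list(p) for p in self.pulses],
            "trial_length_ms": self.trial_length_ms,
            "n_trials_electrical": self.n_trials_electrical,
            "n_trials_chemical": self.n_trials_chemical,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            pulses=tuple(tuple(p) for p in d["pulses"]),
            trial_length_ms=float(d["trial_length_ms"]),
            n_trials_electrical=int(d["n_trials_electrical"]),
            n_trials_chemical=int(d["n_trials_chemical"]),
        )


def build_protocol(
    brief_amp_pA: float,
    long_depol_pA: float,
    hyper_amp_pA: float = 200.0,
    n_trials_electrical: int = 10,
    n_trials_chemical: int = 10,
) -> StimulusProtocol:
    """Standard pairing protocol: two 5 ms suprathreshold pulses 50 ms apart
    (20 Hz) plus a third 5 ms pulse at 500 ms, followed by a 200 ms
    low-suprathreshold depolarization and a 200 ms, -200 pA hyperpolarizing
    step 300 ms later.

    Amplitudes are validated against their allowed ranges: brief pulses
    600-1000 pA, long depolarization 200-600 pA, hyperpolarization fixed at
    200 pA magnitude.
    """
    if not 600.0 <= brief_amp_pA <= 1000.0:
        raise ValidationError("brief pulse amplitude must lie in [600, 1000] pA")
    if not 200.0 <= long_depol_pA <= 600.0:
        raise ValidationError("long depolarization amplitude must lie in [200, 600] pA")
    if hyper_amp_pA != 200.0:
        raise ValidationError("hyperpolarizing amplitude is fixed at 200 pA")
    pulses = (
        (100.0, 5.0, brief_amp_pA),
        (150.0, 5.0, brief_amp_pA),  # 50 ms inter-onset gap = 20 Hz
        (600.0, 5.0, brief_amp_pA),
        (800.0, 200.0, long_depol_pA),
        (1300.0, 200.0, -hyper_amp_pA),  # 300 ms after the long depolarization ends
    )
    return StimulusProtocol(
        pulses=pulses,
        trial_length_ms=1700.0,
        n_trials_electrical=n_trials_electrical,
        n_trials_chemical=n_trials_chemical,
    )


@dataclass(frozen=True)
class NeuronParams:
    """Biophysics of one model cell.

    The AP template is parameterized so that the downstream feature extractor
    recovers the stated values: ``ap_rise_ms`` is the 10-90% rise time,
    ``ap_halfwidth_ms`` the width at half peak-to-threshold amplitude,
    ``ahp_amp_mV`` the threshold-to-trough depth and ``ahp_time_ms`` the
    peak-to-trough latency.  ``adaptation_strength`` is a per-spike increment
    (mV) to an exponentially decaying threshold offset.
    """

    rest_mV: float
    R_in_MOhm: float
    C_pF: float
    spike_threshold_mV: float
    ap_peak_mV: float
    ap_halfwidth_ms: float
    ap_rise_ms: float
    ap_decay_ms: float
    ahp_amp_mV: float
    ahp_time_ms: float
    adaptation_strength: float = 0.0
    adaptation_tau_ms: float = 300.0
    subtype_label: str = "FS"

    def __post_init__(self):
        if self.R_in_MOhm <= 0 or self.C_pF <= 0:
            raise ValidationError("R_in and C must be positive")
        if min(self.ap_halfwidth_ms, self.ap_rise_ms, self.ap_decay_ms) <= 0:
            raise ValidationError("AP shape parameters must be positive")
        if self.rest_mV >= self.spike_threshold_mV:
            raise ValidationError("rest must lie below spike threshold")
        if self.ahp_amp_mV <= 0 or self.ahp_time_ms <= 0:
            raise ValidationError("AHP parameters must be positive")
        if self.adaptation_strength < 0:
            raise ValidationError("adaptation_strength must be >= 0")
        if self.subtype_label not in ("FS", "nonFS", "PN"):
            raise ValidationError("subtype_label must be FS, nonFS or PN")
        t_up = self.ap_rise_ms / 0.8
        t1 = self.ap_halfwidth_ms - t_up / 2.0
        if t1 <= 0:
            raise ValidationError("half-width too small for the requested rise time")
        if self.ahp_time_ms <= t1:
            raise ValidationError("ahp_time must exceed the fall-to-half time")

    @property
    def g_leak_nS(self) -> float:
        return 1000.0 / self.R_in_MOhm


@dataclass(frozen=True)
class CellMeta:
    cell_id: int
    fluor_label: str = "EGFP"  # EGFP | mCherry | EGFP+mCherry | none
    position_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    layer: str = "L2_3"  # L2_3 | L4 | L5 | L6
    area: str = "SCX"  # SCX | VCX
    age_P: int = 21
    clone_id: Optional[int] = None

    def __post_init__(self):
        if not all(math.isfinite(x) for x in self.position_um):
            raise ValidationError("position must be finite")
        if self.age_P < 0:
            raise ValidationError("postnatal age must be >= 0")


@dataclass(frozen=True)
class ChemSynapse:
    """Delayed conductance synapse triggered at the presynaptic AP peak.

    Default reversal of -40 mV mimics the depolarized chloride reversal of a
    high-Cl internal solution, so PSCs are measurable at both -70 and -20 mV
    holding potentials.
    """

    pre: int
    post: int
    peak_conductance_nS: float
    latency_ms: float = 2.0
    rise_ms: float = 0.5
    decay_ms: float = 5.0
    reversal_mV: float = -40.0

    def __post_init__(self):
        if self.pre == self.post:
            raise ValidationError("no self-connections")
        if self.peak_conductance_nS < 0:
            raise ValidationError("synaptic conductance must be >= 0")
        if not 0.8 <= self.latency_ms < 5.0:
            raise ValidationError("chemical latency must lie in [0.8, 5) ms")
        if self.rise_ms <= 0 or self.decay_ms <= self.rise_ms:
            raise ValidationError("need 0 < rise < decay")


@dataclass
class CircuitSpec:
    """Ground-truth circuit: cells plus undirected gap junctions (stored with
    i < j) and directed chemical synapses."""

    cells: list[tuple[NeuronParams, CellMeta]]
    gap_junctions: list[tuple[int, int, float]] = field(default_factory=list)
    chem_synapses: list[ChemSynapse] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.cells)
        norm = []
        for i, j, g in self.gap_junctions:
            if i == j:
                raise ValidationError("no self gap junctions")
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError("gap junction references unknown cell")
            if g < 0:
                raise ValidationError("gap conductance must be >= 0")
            norm.append((min(i, j), max(i, j), float(g)))
        self.gap_junctions = norm
        for s in self.chem_synapses:
            if not (0 <= s.pre < n and 0 <= s.post < n):
                raise ValidationError("chemical synapse references unknown cell")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gap_matrix(self) -> np.ndarray:
        g = np.zeros((self.n_cells, self.n_cells))
        for i, j, c in self.gap_junctions:
            g[i, j] += c
            g[j, i] += c
        return g

    def block_gap_junctions(self) -> "CircuitSpec":
        """Gap-junction blockade (carbenoxolone analogue): conductances to 0."""
        return CircuitSpec(
            cells=list(self.cells),
            gap_junctions=[(i, j, 0.0) for i, j, _ in self.gap_junctions],
            chem_synapses=list(self.chem_synapses),
        )


@dataclass
class Trial:
    driver: int
    clamp: np.ndarray  # per-cell 'cc' or 'vc'
    holding_mV: np.ndarray  # per-cell holding potential, NaN under current clamp
    traces: np.ndarray  # (n_cells, n_samples) float32; mV for cc, pA for vc


@dataclass
class RecordingSession:
    """Multi-cell, multi-trial synthetic recording.

    Each trial has exactly one driver receiving the protocol; all other cells
    are passive observers, current-clamped (electrical-coupling trials) or
    voltage-clamped (chemical-synapse trials).
    """

    sampling_rate_hz: float
    protocol: StimulusProtocol
    cell_meta: list[CellMeta]
    trials: list[Trial]
    seed: Optional[int] = None
    circuit: Optional[CircuitSpec] = None

    def __post_init__(self):
        n_samples = {t.traces.shape[1] for t in self.trials}
        if len(n_samples) > 1:
            raise ValidationError("all trials must have traces of equal length")
        per_driver: dict[int, int] = {}
        for t in self.trials:
            per_driver[t.driver] = per_driver.get(t.driver, 0) + 1
        for d, k in per_driver.items():
            if k < 20:
                raise ValidationError(
                    f"driver {d} probed in {k} trials; at least 20 required"
                )

    @property
    def n_cells(self) -> int:
        return len(self.cell_meta)

    def trials_for(self, driver: int, mode: str) -> list[Trial]:
        """mode: 'electrical' (all current clamp) or 'chemical' (driver only)."""
        out = []
        for t in self.trials:
            if t.driver != driver:
                continue
            all_cc = bool(np.all(t.clamp == "cc"))
            if mode == "electrical" and all_cc:
                out.append(t)
            elif mode == "chemical" and not all_cc:
                out.append(t)
        return out


@dataclass
class CloneSet:
    """3-D labelled point pattern with clone (barcode) identities."""

    points_um: np.ndarray  # (n, 3)
    clone_ids: np.ndarray  # (n,)
    fluor_labels: np.ndarray  # (n,)
    region: Optional[str] = None

    def __post_init__(self):
        self.points_um = np.asarray(self.points_um, dtype=float).reshape(-1, 3)
        self.clone_ids = np.asarray(self.clone_ids)
        self.fluor_labels = np.asarray(self.fluor_labels)
        n = len(self.points_um)
        if len(self.clone_ids) != n or len(self.fluor_labels) != n:
            raise ValidationError("points, clone ids and labels must align")
        if n and not np.all(np.isfinite(self.points_um)):
            raise ValidationError("positions must be finite")

    def __len__(self) -> int:
        return len(self.points_um)


# ---------------------------------------------------------------------------
# AP template
# ---------------------------------------------------------------------------


def ap_waveform_samples(p: NeuronParams, dt_ms: float = DT_MS) -> tuple[np.ndarray, int]:
    """Sampled AP template and the index of its peak.

    Upstroke: linear from threshold to peak over rise/0.8 (so the 10-90% rise
    time equals ``ap_rise_ms``).  Fall: linear to the half-amplitude level
    (placing the half-width exactly), then an exponential with time constant
    ``ap_decay_ms`` whose asymptote is chosen so the template reaches the AHP
    trough exactly ``ahp_time_ms`` after the peak.
    """
    thr, peak = p.spike_threshold_mV, p.ap_peak_mV
    ahp_min = thr - p.ahp_amp_mV
    v_half = (thr + peak) / 2.0
    t_up = p.ap_rise_ms / 0.8
    t1 = p.ap_halfwidth_ms - t_up / 2.0
    t2 = p.ahp_time_ms - t1
    n_up = max(1, int(round(t_up / dt_ms)))
    n1 = max(1, int(round(t1 / dt_ms)))
    n2 = max(2, int(round(t2 / dt_ms)))
    up = thr + (peak - thr) * np.arange(n_up) / n_up
    fall1 = peak + (v_half - peak) * np.arange(1, n1 + 1) / n1
    tau = p.ap_decay_ms
    e2 = math.exp(-t2 / tau)
    v_inf = (ahp_min - v_half * e2) / (1.0 - e2)
    fall2 = v_inf + (v_half - v_inf) * np.exp(-np.arange(1, n2 + 1) * dt_ms / tau)
    wave = np.concatenate([up, [peak], fall1, fall2])
    return wave, n_up


# ---------------------------------------------------------------------------
# integrator core
# ---------------------------------------------------------------------------


@njit(cache=True)
def _integrate(
    dt,
    n_steps,
    substeps,
    rest,
    gleak,
    cap,
    thr,
    adapt_inc,
    adapt_decay,
    wave,
    wave_len,
    wave_peak,
    gap,
    syn_pre,
    syn_post,
    syn_g,
    syn_delay,
    syn_er,
    syn_dr,
    syn_dd,
    syn_norm,
    inj,
    clamped,
    hold,
    inoise,
):  # pragma: no cover - exercised through simulate wrappers
    n = rest.shape[0]
    n_syn = syn_pre.shape[0]
    n_samples = n_steps // substeps
    out = np.zeros((n, n_samples))
    max_spk = 4096
    spk = np.zeros((n, max_spk))
    nspk = np.zeros(n, np.int64)
    sx = np.zeros(n_syn)
    sy = np.zeros(n_syn)
    sched = np.zeros((n_syn, max_spk), np.int64)
    sched_n = np.zeros(n_syn, np.int64)
    sched_done = np.zeros(n_syn, np.int64)
    V = rest.copy()
    w = np.zeros(n)
    stamp = np.full(n, -1, np.int64)
    for i in range(n):
        if clamped[i] == 1:
            V[i] = hold[i]
    Isyn = np.zeros(n)
    Igap = np.zeros(n)
    have_noise = inoise.shape[1] > 0
    for k in range(n_steps):
        for i in range(n):
            Isyn[i] = 0.0
        for s in range(n_syn):
            while sched_done[s] < sched_n[s] and sched[s, sched_done[s]] <= k:
                sx[s] += 1.0
                sy[s] += 1.0
                sched_done[s] += 1
            gval = syn_g[s] * syn_norm[s] * (sy[s] - sx[s])
            if gval != 0.0:
                pp = syn_post[s]
                Isyn[pp] += gval * (syn_er[s] - V[pp])
            sx[s] *= syn_dr[s]
            sy[s] *= syn_dd[s]
        for i in range(n):
            acc = 0.0
            for j in range(n):
                gij = gap[i, j]
                if gij != 0.0:
                    acc += gij * (V[j] - V[i])
            Igap[i] = acc
        rec_now = k % substeps == substeps - 1
        for i in range(n):
            if clamped[i] == 1:
                continue
            if stamp[i] >= 0:
                pos = stamp[i]
                V[i] = wave[i, pos]
                if pos == wave_peak[i]:
                    if nspk[i] < max_spk:
                        spk[i, nspk[i]] = k * dt
                        nspk[i] += 1
                    w[i] += adapt_inc[i]
                    for s in range(n_syn):
                        if syn_pre[s] == i and sched_n[s] < max_spk:
                            sched[s, sched_n[s]] = k + syn_delay[s]
                            sched_n[s] += 1
                pos += 1
                if pos >= wave_len[i]:
                    stamp[i] = -1
                else:
                    stamp[i] = pos
            else:
                iin = inj[i, k] + Igap[i] + Isyn[i]
                if have_noise:
                    iin += inoise[i, k]
                V[i] += dt * (gleak[i] * (rest[i] - V[i]) + iin) / cap[i]
                if not np.isfinite(V[i]):
                    return out, spk, nspk, k
                w[i] *= adapt_decay[i]
                if V[i] >= thr[i] + w[i]:
                    V[i] = wave[i, 0]
                    stamp[i] = 1 if wave_len[i] > 1 else -1
            if rec_now:
                out[i, k // substeps] = V[i]
        if rec_now:
            # clamp currents are recorded against the post-update voltages so
            # the junctional component is exactly linear in the recorded
            # driver trace (needed for clean gap-current subtraction)
            for i in range(n):
                if clamped[i] == 1:
                    acc = 0.0
                    for j in range(n):
                        gij = gap[i, j]
                        if gij != 0.0:
                            acc += gij * (V[j] - V[i])
                    out[i, k // substeps] = (
                        gleak[i] * (V[i] - rest[i]) - acc - Isyn[i] - inj[i, k]
                    )
    return out, spk, nspk, -1


def _pack_circuit(circuit: CircuitSpec, dt_ms: float):
    n = circuit.n_cells
    rest = np.array([p.rest_mV for p, _ in circuit.cells])
    gleak = np.array([p.g_leak_nS for p, _ in circuit.cells])
    cap = np.array([p.C_pF for p, _ in circuit.cells])
    thr = np.array([p.spike_threshold_mV for p, _ in circuit.cells])
    adapt_inc = np.array([p.adaptation_strength for p, _ in circuit.cells])
    adapt_decay = np.array(
        [math.exp(-dt_ms / p.adaptation_tau_ms) for p, _ in circuit.cells]
    )
    waves = []
    peaks = []
    for p, _ in circuit.cells:
        wv, pk = ap_waveform_samples(p, dt_ms)
        waves.append(wv)
        peaks.append(pk)
    maxw = max(len(w) for w in waves)
    wave = np.zeros((n, maxw))
    wave_len = np.zeros(n, np.int64)
    for i, wv in enumerate(waves):
        wave[i, : len(wv)] = wv
        wave_len[i] = len(wv)
    wave_peak = np.array(peaks, np.int64)
    gap = circuit.gap_matrix()
    syns = circuit.chem_synapses
    ns = len(syns)
    syn_pre = np.array([s.pre for s in syns], np.int64).reshape(ns)
    syn_post = np.array([s.post for s in syns], np.int64).reshape(ns)
    syn_g = np.array([s.peak_conductance_nS for s in syns]).reshape(ns)
    syn_delay = np.array(
        [int(round(s.latency_ms / dt_ms)) for s in syns], np.int64
    ).reshape(ns)
    syn_er = np.array([s.reversal_mV for s in syns]).reshape(ns)
    syn_dr = np.array([math.exp(-dt_ms / s.rise_ms) for s in syns]).reshape(ns)
    syn_dd = np.array([math.exp(-dt_ms / s.decay_ms) for s in syns]).reshape(ns)
    # normalize the double-exponential so its peak equals peak_conductance
    syn_norm = np.ones(ns)
    for i, s in enumerate(syns):
        tr, td = s.rise_ms, s.decay_ms
        tp = math.log(td / tr) * tr * td / (td - tr)
        peak = math.exp(-tp / td) - math.exp(-tp / tr)
        syn_norm[i] = 1.0 / peak
    return (
        rest,
        gleak,
        cap,
        thr,
        adapt_inc,
        adapt_decay,
        wave,
        wave_len,
        wave_peak,
        gap,
        syn_pre,
        syn_post,
        syn_g,
        syn_delay,
        syn_er,
        syn_dr,
        syn_dd,
        syn_norm,
    )


def simulate_traces(
    circuit: CircuitSpec,
    inj_pA: np.ndarray,
    duration_ms: float,
    clamped: Optional[Sequence[bool]] = None,
    holding_mV: float = -70.0,
    current_noise_sd_pA: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Integrate one deterministic sweep.

    ``inj_pA`` is (n_cells, n_steps) at the integration step or
    (n_cells, n_samples) at the recorded rate (then upsampled by repetition).
    Returns (traces (n_cells, n_samples), spike peak times per cell in ms).
    """
    n = circuit.n_cells
    n_steps = int(round(duration_ms / DT_MS))
    inj = np.asarray(inj_pA, dtype=float)
    if inj.shape == (n, n_steps // SUBSTEPS):
        inj = np.repeat(inj, SUBSTEPS, axis=1)
    if inj.shape != (n, n_steps):
        raise ValidationError("injection array has the wrong shape")
    if clamped is None:
        clamped_arr = np.zeros(n, np.int64)
    else:
        clamped_arr = np.asarray(clamped, dtype=np.int64)
    hold = np.full(n, holding_mV)
    if current_noise_sd_pA > 0:
        if rng is None:
            raise ValidationError("current noise requires an rng")
        inoise = rng.normal(0.0, current_noise_sd_pA, size=(n, n_steps))
    else:
        inoise = np.zeros((n, 0))
    args = _pack_circuit(circuit, DT_MS)
    out, spk, nspk, err = _integrate(
        DT_MS, n_steps, SUBSTEPS, *args, inj, clamped_arr, hold, inoise
    )
    if err >= 0:
        raise SimulationError(
            f"non-finite membrane state at t = {err * DT_MS:.3f} ms (step {err})"
        )
    spikes = [spk[i, : nspk[i]].copy() for i in range(n)]
    return out, spikes


def simulate_session(
    circuit: CircuitSpec,
    protocol: StimulusProtocol,
    noise_sd_mV: float = DEFAULT_NOISE_SD_MV,
    seed: Optional[int] = None,
    noise_sd_pA: float = DEFAULT_NOISE_SD_PA,
    drift_amp_mV: float = 0.0,
    drift_freq_hz: float = 0.5,
    drivers: Optional[Sequence[int]] = None,
    holding_mV: float = -70.0,
) -> RecordingSession:
    """Probe every driver with the protocol and record all cells.

    Per driver: ``n_trials_electrical`` trials with every cell current-clamped
    and ``n_trials_chemical`` trials with the non-driver cells voltage-clamped
    at ``holding_mV``.  Dynamics are deterministic, so each (driver, mode) is
    integrated once; Gaussian measurement noise (plus optional slow sinusoidal
    drift) is drawn independently per trial.  Identical seeds give
    bit-identical sessions.
    """
    if noise_sd_mV < 0 or noise_sd_pA < 0:
        raise ValidationError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = circuit.n_cells
    n_steps = int(round(protocol.trial_length_ms / DT_MS))
    n_samples = n_steps // SUBSTEPS
    t_s = np.arange(n_samples) / SAMPLING_HZ
    proto_wave = protocol.current_waveform(DT_MS, n_steps)
    if drivers is None:
        drivers = range(n)
    trials: list[Trial] = []

    def _noisy(clean: np.ndarray, clamp: np.ndarray) -> np.ndarray:
        tr = clean.copy()
        for i in range(n):
            sd = noise_sd_pA if clamp[i] == "vc" else noise_sd_mV
            if sd > 0:
                tr[i] += rng.normal(0.0, sd, size=n_samples)
            if drift_amp_mV > 0:
                phase = rng.uniform(0, 2 * np.pi)
                tr[i] += drift_amp_mV * np.sin(2 * np.pi * drift_freq_hz * t_s + phase)
        return tr.astype(np.float32)

    for d in drivers:
        inj = np.zeros((n, n_steps))
        inj[d] = proto_wave
        clean_e, _ = simulate_traces(circuit, inj, protocol.trial_length_ms)
        clamp_e = np.array(["cc"] * n)
        hold_e = np.full(n, np.nan)
        for _ in range(protocol.n_trials_electrical):
            trials.append(Trial(d, clamp_e.copy(), hold_e.copy(), _noisy(clean_e, clamp_e)))
        clamped = np.ones(n, bool)
        clamped[d] = False
        clean_c, _ = simulate_traces(
            circuit, inj, protocol.trial_length_ms, clamped=clamped, holding_mV=holding_mV
        )
        clamp_c = np.array(["vc" if clamped[i] else "cc" for i in range(n)])
        hold_c = np.where(clamped, holding_mV, np.nan)
        for _ in range(protocol.n_trials_chemical):
            trials.append(Trial(d, clamp_c.copy(), hold_c.copy(), _noisy(clean_c, clamp_c)))
    return RecordingSession(
        sampling_rate_hz=SAMPLING_HZ,
        protocol=protocol,
        cell_meta=[m for _, m in circuit.cells],
        trials=trials,
        seed=seed,
        circuit=circuit,
    )


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

# Preset membrane parameters.  FS presets satisfy every classification
# threshold with margin; non-FS presets violate several (input resistance,
# AP threshold, AHP amplitude, AHP latency); PN presets are regular-spiking
# excitatory cells and never classify as FS.
_PRESETS: dict[str, NeuronParams] = {
    "FS": NeuronParams(
        rest_mV=-65.0,
        R_in_MOhm=150.0,
        C_pF=80.0,
        spike_threshold_mV=-33.0,
        ap_peak_mV=25.0,
        ap_halfwidth_ms=0.5,
        ap_rise_ms=0.5,
        ap_decay_ms=2.0,
        ahp_amp_mV=12.0,
        ahp_time_ms=3.0,
        adaptation_strength=0.0,
        subtype_label="FS",
    ),
    "nonFS": NeuronParams(
        rest_mV=-60.0,
        R_in_MOhm=450.0,
        C_pF=60.0,
        spike_threshold_mV=-42.0,
        ap_peak_mV=20.0,
        ap_halfwidth_ms=1.0,
        ap_rise_ms=0.9,
        ap_decay_ms=4.0,
        ahp_amp_mV=4.0,
        ahp_time_ms=9.0,
        adaptation_strength=2.0,
        subtype_label="nonFS",
    ),
    "PN": NeuronParams(
        rest_mV=-70.0,
        R_in_MOhm=120.0,
        C_pF=150.0,
        spike_threshold_mV=-45.0,
        ap_peak_mV=30.0,
        ap_halfwidth_ms=1.4,
        ap_rise_ms=1.1,
        ap_decay_ms=5.0,
        ahp_amp_mV=6.0,
        ahp_time_ms=10.0,
        adaptation_strength=4.0,
        subtype_label="PN",
    ),
}

# Intervals each jittered parameter must stay inside so the preset keeps its
# intended side of every classification threshold (with margin).
_JITTER_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "FS": {
        "R_in_MOhm": (60.0, 280.0),
        "spike_threshold_mV": (-34.5, -25.0),
        "ap_halfwidth_ms": (0.35, 1.5),
        "ap_rise_ms": (0.25, 1.6),
        "ap_decay_ms": (0.8, 6.0),
        "ahp_amp_mV": (8.8, 20.0),
        "ahp_time_ms": (1.5, 6.0),
    },
    "nonFS": {
        "R_in_MOhm": (330.0, 800.0),
        "spike_threshold_mV": (-55.0, -36.5),
        "ahp_amp_mV": (1.0, 7.2),
        "ahp_time_ms": (7.2, 15.0),
    },
    "PN": {
        "R_in_MOhm": (60.0, 280.0),
        "spike_threshold_mV": (-55.0, -38.0),
        "ahp_amp_mV": (2.0, 7.2),
        "ahp_time_ms": (7.2, 18.0),
    },
}

_JITTERED_FIELDS = (
    "rest_mV",
    "R_in_MOhm",
    "C_pF",
    "spike_threshold_mV",
    "ap_halfwidth_ms",
    "ap_rise_ms",
    "ap_decay_ms",
    "ahp_amp_mV",
    "ahp_time_ms",
)


def preset(subtype: str) -> NeuronParams:
    """Reference membrane-parameter preset for FS, nonFS or PN."""
    return _PRESETS[subtype]


def _jittered(base: NeuronParams, jitter: float, rng: np.random.Generator) -> NeuronParams:
    if jitter == 0:
        return base
    kwargs = {}
    bounds = _JITTER_BOUNDS[base.subtype_label]
    for f in _JITTERED_FIELDS:
        v = getattr(base, f) * (1.0 + rng.uniform(-jitter, jitter))
        lo, hi = bounds.get(f, (-np.inf, np.inf))
        if not lo <= v <= hi:
            raise ValidationError(
                f"jitter moved {f}={v:.3g} across the classification margin "
                f"[{lo}, {hi}] for subtype {base.subtype_label}"
            )
        kwargs[f] = v
    return replace(base, **kwargs)


def make_population(
    n_FS: int,
    n_nonFS: int,
    n_PN: int = 0,
    jitter: float = 0.0,
    seed: Optional[int] = None,
    box_um: float = 200.0,
) -> list[tuple[NeuronParams, CellMeta]]:
    """Seeded population of preset cells with jittered parameters and random
    positions inside a cube of side ``box_um``."""
    if min(n_FS, n_nonFS, n_PN) < 0:
        raise ValidationError("counts must be >= 0")
    if jitter < 0:
        raise ValidationError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    cells = []
    cid = 0
    for subtype, count in (("FS", n_FS), ("nonFS", n_nonFS), ("PN", n_PN)):
        for _ in range(count):
            params = _jittered(_PRESETS[subtype], jitter, rng)
            pos = tuple(rng.uniform(0.0, box_um, size=3))
            cells.append((params, CellMeta(cell_id=cid, position_um=pos)))
            cid += 1
    return cells


# ---------------------------------------------------------------------------
# feature-protocol sweeps
# ---------------------------------------------------------------------------


def simulate_feature_sweeps(
    params: NeuronParams,
    amps_pA: Sequence[float] = (-50.0, 100.0, 200.0, 300.0, 400.0),
    noise_sd_mV: float = 0.0,
    seed: Optional[int] = None,
    baseline_ms: float = 200.0,
    step_ms: float = 1000.0,
    tail_ms: float = 200.0,
):
    """Current-clamp step family (one subthreshold hyperpolarizing step plus a
    1 s depolarizing step series) for feature extraction."""
    from .ephys_features import Sweep  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    duration = baseline_ms + step_ms + tail_ms
    n_steps = int(round(duration / DT_MS))
    circuit = CircuitSpec(cells=[(params, CellMeta(cell_id=0))])
    sweeps = []
    for amp in amps_pA:
        inj = np.zeros((1, n_steps))
        a = int(round(baseline_ms / DT_MS))
        b = int(round((baseline_ms + step_ms) / DT_MS))
        inj[0, a:b] = amp
        traces, _ = simulate_traces(circuit, inj, duration)
        v = traces[0]
        if noise_sd_mV > 0:
            v = v + rng.normal(0.0, noise_sd_mV, size=v.shape)
        sweeps.append(
            Sweep(
                trace_mV=v,
                sampling_rate_hz=SAMPLING_HZ,
                amp_pA=amp,
                onset_ms=baseline_ms,
                duration_ms=step_ms,
            )
        )
    return sweeps


# ---------------------------------------------------------------------------
# spike-train generators (synchrony experiments)
# ---------------------------------------------------------------------------


def poisson_train(
    rate_hz: float, duration_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson spike train on [0, duration_ms), sorted, in ms."""
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


def simulate_common_drive(
    gap_nS: float,
    drive_pA: float = 400.0,
    duration_ms: float = 10_000.0,
    current_noise_sd_pA: float = 60.0,
    seed: Optional[int] = None,
    params: Optional[NeuronParams] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two FS cells under a shared suprathreshold current with independent
    membrane current noise; returns the two spike trains (ms).

    With a gap junction the cells phase-lock and fire near-synchronously;
    with gap_nS = 0 the noise decorrelates them.
    """
    p = params or _PRESETS["FS"]
    cells = [(p, CellMeta(cell_id=0)), (p, CellMeta(cell_id=1))]
    circuit = CircuitSpec(cells=cells, gap_junctions=[(0, 1, gap_nS)])
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_ms / DT_MS))
    inj = np.full((2, n_steps), drive_pA)
    _, spikes = simulate_traces(
        circuit,
        inj,
        duration_ms,
        current_noise_sd_pA=current_noise_sd_pA,
        rng=rng,
    )
    return spikes[0], spikes[1]


# ---------------------------------------------------------------------------
# clonal point patterns
# ---------------------------------------------------------------------------


def make_clonal_pattern(
    n_clones: int,
    mean_clone_size: float,
    clone_sd_um: float,
    volume_um3: float,
    labelling_density: float = 1.0,
    seed: Optional[int] = None,
    labels: Sequence[str] = ("EGFP",),
    region: Optional[str] = "cortex",
) -> CloneSet:
    """Clustered clonal point pattern.

    Clone centres are uniform in a cube of the given volume; members are
    isotropic Gaussian offsets with sd ``clone_sd_um``.  ``labelling_density``
    subsamples whole clones (low density emulates sparse low-titre labelling
    with spatially isolated clusters).  Each retained clone carries one
    fluorophore label drawn from ``labels``.
    """
    if clone_sd_um < 0:
        raise ValidationError("clone_sd must be >= 0")
    if not 0 < labelling_density <= 1:
        raise ValidationError("labelling density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    side = volume_um3 ** (1.0 / 3.0)
    pts, cids, labs = [], [], []
    for c in range(n_clones):
        centre = rng.uniform(0.0, side, size=3)
        size = max(1, int(rng.poisson(max(mean_clone_size - 1.0, 0.0))) + 1)
        lab = labels[int(rng.integers(len(labels)))]
        keep = rng.uniform() < labelling_density
        members = centre + rng.normal(0.0, clone_sd_um, size=(size, 3))
        if keep:
            pts.append(members)
            cids.extend([c] * size)
            labs.extend([lab] * size)
    if not pts:
        return CloneSet(
            points_um=np.empty((0, 3)),
            clone_ids=np.empty(0, int),
            fluor_labels=np.empty(0, object),
            region=region,
        )
    return CloneSet(
        points_um=np.vstack(pts),
        clone_ids=np.array(cids, int),
        fluor_labels=np.array(labs, object),
        region=region,
    )


# ---------------------------------------------------------------------------
# pair-level cohort generator
# ---------------------------------------------------------------------------

LINEAGE_CLASSES = ("sparse_cluster", "non_lineage", "dense_dense")
SUBTYPE_PAIRS = ("FS_FS", "nonFS_nonFS", "FS_nonFS")


def simulate_pair_cohort(
    n_by_class: dict[str, int],
    p_electrical: dict[str, float],
    p_chemical: float | dict[str, float] = 0.25,
    p_bidirectional: float = 0.3,
    seed: Optional[int] = None,
    distance_range_um: tuple[float, float] = (10.0, 250.0),
    age_range: tuple[int, int] = (14, 40),
    subtype_probs: tuple[float, float, float] = (0.3, 0.4, 0.3),
):
    """Bernoulli pair-outcome cohort with lineage-class-dependent electrical
    coupling probability; chemical connectivity is drawn independently of the
    electrical outcome (the study-condition null).

    Returns a pandas DataFrame with PairRecord columns.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for cls, n in n_by_class.items():
        if cls not in LINEAGE_CLASSES:
            raise ValidationError(f"unknown lineage class {cls!r}")
        pe = p_electrical[cls]
        pc = p_chemical[cls] if isinstance(p_chemical, dict) else p_chemical
        for _ in range(n):
            elec = bool(rng.uniform() < pe)
            chem_conn = rng.uniform() < pc
            if chem_conn:
                chem = "bi" if rng.uniform() < p_bidirectional else "uni"
            else:
                chem = "none"
            rows.append(
                {
                    "pair_id": pid,
                    "lineage_class": cls,
                    "subtype_pair": SUBTYPE_PAIRS[
                        int(rng.choice(3, p=np.asarray(subtype_probs)))
                    ],
                    "intersoma_dist_um": float(rng.uniform(*distance_range_um)),
                    "age_P": int(rng.integers(age_range[0], age_range[1] + 1)),
                    "layer": str(rng.choice(["L2_3", "L4", "L5", "L6"])),
                    "area": str(rng.choice(["SCX", "VCX"])),
                    "electrical": elec,
                    "chemical": chem,
                    "both_output_to_common_PN": np.nan,
                }
            )
            pid += 1
    return pd.DataFrame(rows)
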