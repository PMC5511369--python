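import numpy as np
import pytest

from clonalcircuits import simcircuit as sc
from clonalcircuits.connectivity_detect import (
    DetectionCriteria,
    classify_pair,
    connection_matrix,
    connections_frame,
    detect_chemical,
    detect_electrical,
    detected_graph,
    ground_truth_graph,
)
from clonalcircuits.errors import InsufficientDataError, ProtocolError
from clonalcircuits.simcircuit import CellMeta, ChemSynapse, CircuitSpec


def test_detected_graph_matches_truth_noiseless(noiseless_session, demo_circuit):
    results = connection_matrix(noiseless_session)
    assert detected_graph(results) == ground_truth_graph(demo_circuit)


def test_detection_still_correct_under_default_noise(noisy_session, demo_circuit):
    results = connection_matrix(noisy_session)
    assert detected_graph(results) == ground_truth_graph(demo_circuit)


def test_gap_pair_not_called_chemical(noiseless_session):
    """A pure gap-junction pair is electrically coupled but not chemical."""
    r = classify_pair(noiseless_session, 0, 1)
    assert r.electrical_coupled
    assert r.directionality == "none"
    for c in r.chemical_by_direction.values():
        assert not c.connected


def test_chemical_amplitude_and_latency(noiseless_session):
    c = detect_chemical(noiseless_session, 1, 2)
    assert c.connected
    assert abs(c.psc_amp_pA) > 0.5
    # onset is measured at the detectability threshold, slightly after the
    # configured synaptic delay
    assert c.latency_ms == pytest.approx(2.0, abs=0.4)
    assert 0.0 < c.latency_ms <= 5.0


def test_coupling_coefficient_analytic(protocol):
    fs, nonfs = sc.preset("FS"), sc.preset("nonFS")
    g = 1.0
    circ = CircuitSpec(
        cells=[(fs, CellMeta(0)), (nonfs, CellMeta(1))], gap_junctions=[(0, 1, g)]
    )
    sess = sc.simulate_session(circ, protocol, 0.0, seed=1, noise_sd_pA=0.0, drivers=[0])
    e = detect_electrical(sess, 0, 1)
    analytic = g / (g + 1000.0 / nonfs.R_in_MOhm)
    assert e.coupled
    assert e.coupling_coefficient == pytest.approx(analytic, rel=0.02)


def test_cc_invariant_to_injected_amplitude():
    """Coupling coefficient does not depend on the driver amplitude."""
    from clonalcircuits.simcircuit import StimulusProtocol

    fs, nonfs = sc.preset("FS"), sc.preset("nonFS")
    circ = CircuitSpec(
        cells=[(fs, CellMeta(0)), (nonfs, CellMeta(1))], gap_junctions=[(0, 1, 1.0)]
    )
    ccs = []
    for amp in (-100.0, -200.0):
        proto = StimulusProtocol(
            pulses=((300.0, 200.0, amp),), trial_length_ms=700.0
        )
        sess = sc.simulate_session(
            circ, proto, 0.0, seed=1, noise_sd_pA=0.0, drivers=[0]
        )
        ccs.append(detect_electrical(sess, 0, 1).coupling_coefficient)
    assert ccs[0] == pytest.approx(ccs[1], rel=0.01)


def test_carbenoxolone_flip(protocol):
    """Zeroing the gap conductance flips coupled true -> false."""
    fs = sc.preset("FS")
    circ = CircuitSpec(
        cells=[(fs, CellMeta(0)), (fs, CellMeta(1))], gap_junctions=[(0, 1, 1.5)]
    )
    sess = sc.simulate_session(circ, protocol, seed=2, drivers=[0])
    assert detect_electrical(sess, 0, 1).coupled
    blocked = sc.simulate_session(
        circ.block_gap_junctions(), protocol, seed=2, drivers=[0]
    )
    assert not detect_electrical(blocked, 0, 1).coupled


def test_insufficient_trials(noiseless_session):
    crit = DetectionCriteria(min_trials_per_mode=100)
    with pytest.raises(InsufficientDataError):
        detect_electrical(noiseless_session, 0, 1, crit)
    with pytest.raises(InsufficientDataError):
        detect_chemical(noiseless_session, 1, 2, crit)


def test_missing_hyperpolarizing_pulse_is_protocol_error(demo_circuit):
    from clonalcircuits.simcircuit import StimulusProtocol

    proto = StimulusProtocol(pulses=((100.0, 5.0, 800.0),), trial_length_ms=400.0)
    sess = sc.simulate_session(demo_circuit, proto, seed=3, drivers=[0])
    with pytest.raises(ProtocolError):
        detect_electrical(sess, 0, 1)


def test_directionality_vocabulary(protocol):
    fs = sc.preset("FS")
    circ = CircuitSpec(
        cells=[(fs, CellMeta(0)), (fs, CellMeta(1))],
        chem_synapses=[
            ChemSynapse(pre=0, post=1, peak_conductance_nS=2.0, latency_ms=1.5),
            ChemSynapse(pre=1, post=0, peak_conductance_nS=2.0, latency_ms=1.5),
        ],
    )
    sess = sc.simulate_session(circ, protocol, seed=4)
    assert classify_pair(sess, 0, 1).directionality == "bi"

    circ_uni = CircuitSpec(
        cells=[(fs, CellMeta(0)), (fs, CellMeta(1))],
        chem_synapses=[
            ChemSynapse(pre=0, post=1, peak_conductance_nS=2.0, latency_ms=1.5)
        ],
    )
    sess = sc.simulate_session(circ_uni, protocol, seed=4)
    assert classify_pair(sess, 0, 1).directionality == "uni"

    empty = CircuitSpec(cells=[(fs, CellMeta(0)), (fs, CellMeta(1))])
    sess = sc.simulate_session(empty, protocol, seed=4)
    r = classify_pair(sess, 0, 1)
    assert not r.electrical_coupled and r.directionality == "none"


def test_pair_count_and_frame(noiseless_session):
    results = connection_matrix(noiseless_session)
    n = noiseless_session.n_cells
    assert len(results) == n * (n - 1) // 2
    df = connections_frame(results)
    assert len(df) == n * (n - 1)
    assert list(df.columns) == [
        "pre",
        "post",
        "electrical_coupled",
        "deflection_mV",
        "coupling_coefficient",
        "chemical_connected",
        "psc_amp_pA",
        "latency_ms",
        "n_trials",
    ]


def test_quadruple_pattern_reproduced(protocol):
    """Electrical 1-2 and 2-4; chemical 2<->4, 1->3, 2->3, 4->3 (0-indexed:
    electrical (0,1),(1,3); chemical (1,3),(3,1),(0,2),(1,2),(3,2))."""
    nonfs = sc.preset("nonFS")
    cells = [(nonfs, CellMeta(i)) for i in range(4)]
    syn = lambda a, b: ChemSynapse(pre=a, post=b, peak_conductance_nS=1.5, latency_ms=2.0)
    # weak gap junctions: the 0-1-3 chain must keep the indirect 0-3
    # co-deflection below the 0.1 mV criterion while the direct edges stay above
    circ = CircuitSpec(
        cells=cells,
        gap_junctions=[(0, 1, 0.06), (1, 3, 0.06)],
        chem_synapses=[syn(1, 3), syn(3, 1), syn(0, 2), syn(1, 2), syn(3, 2)],
    )
    sess = sc.simulate_session(circ, protocol, seed=9)
    elec, chem = detected_graph(connection_matrix(sess))
    assert elec == {(0, 1), (1, 3)}
    assert chem == {(1, 3), (3, 1), (0, 2), (1, 2), (3, 2)}
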