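import numpy as np
import pytest

from clonalcircuits import simcircuit as sc
from clonalcircuits.simcircuit import CellMeta, ChemSynapse, CircuitSpec


@pytest.fixture(scope="session")
def protocol():
    return sc.build_protocol(1000.0, 500.0)


@pytest.fixture(scope="session")
def demo_circuit():
    """Gap-coupled FS pair (0-1) plus a chemical synapse 1 -> 2."""
    fs = sc.preset("FS")
    nonfs = sc.preset("nonFS")
    return CircuitSpec(
        cells=[
            (fs, CellMeta(0, position_um=(0.0, 0.0, 0.0))),
            (fs, CellMeta(1, position_um=(40.0, 0.0, 0.0))),
            (nonfs, CellMeta(2, position_um=(80.0, 0.0, 0.0))),
        ],
        gap_junctions=[(0, 1, 1.5)],
        chem_synapses=[
            ChemSynapse(pre=1, post=2, peak_conductance_nS=1.5, latency_ms=2.0)
        ],
    )


@pytest.fixture(scope="session")
def noiseless_session(demo_circuit, protocol):
    return sc.simulate_session(
        demo_circuit, protocol, noise_sd_mV=0.0, noise_sd_pA=0.0, seed=11
    )


@pytest.fixture(scope="session")
def noisy_session(demo_circuit, protocol):
    return sc.simulate_session(demo_circuit, protocol, seed=12)


def random_quadruple(seed):
    """Random 4-cell circuit whose gap junctions form a matching.

    The pairwise deflection criterion cannot separate direct from indirect
    coupling along gap-junction chains, so fidelity experiments draw circuits
    without such chains.
    """
    rng = np.random.default_rng(seed)
    cells = [
        (sc.preset(rng.choice(["FS", "nonFS"])), CellMeta(i)) for i in range(4)
    ]
    order = list(rng.permutation(4))
    gaps = []
    for a, b in ((order[0], order[1]), (order[2], order[3])):
        if rng.uniform() < 0.5:
            i, j = min(a, b), max(a, b)
            gaps.append((i, j, float(rng.uniform(0.5, 3.0))))
    syns = []
    for i in range(4):
        for j in range(4):
            if i != j and rng.uniform() < 0.2:
                syns.append(
                    ChemSynapse(
                        pre=i,
                        post=j,
                        peak_conductance_nS=float(rng.uniform(0.5, 3.0)),
                        latency_ms=float(rng.uniform(1.0, 4.0)),
                    )
                )
    return CircuitSpec(cells=cells, gap_junctions=gaps, chem_synapses=syns)
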