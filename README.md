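# clonalcircuits

Synthetic paired-recording simulation and connectivity analysis for studying
how developmental lineage shapes interneuron circuits.

Lineage-tracing experiments in the developing neocortex label small clones of
inhibitory interneurons descended from single progenitors and then probe the
connectivity between clonally related cells with multi-cell whole-cell
recordings. The central finding such studies test is that **lineage-related
interneurons preferentially form electrical synapses (gap junctions)** with
one another — at several-fold the rate of unrelated neighbours — while
chemical (GABAergic) connectivity shows no such lineage bias, and that the
resulting electrical coupling synchronizes sibling activity and coordinates
their inhibitory output onto shared pyramidal targets.

This package provides the full computational side of that workflow on
synthetic ground-truth data:

| Module | Purpose |
| --- | --- |
| `simcircuit` | Leaky single-compartment circuit simulator: gap junctions, conductance-based chemical synapses, current/voltage-clamp protocols, population/clone/cohort generators with known ground truth |
| `ephys_features` | Membrane/AP feature extraction and fast-spiking (FS) vs non-FS classification from current-step families |
| `connectivity_detect` | Electrical-coupling detection (co-hyperpolarization criterion, coupling coefficients) and chemical-connection detection (AP-triggered PSC averaging with gap-current subtraction) |
| `sync_corr` | Spike-train cross-correlograms with Poisson-rate normalization and a 3-SD peak-significance rule |
| `spatial_clonal` | Nearest-neighbour-distance CDFs (with the analytic 3-D Poisson reference), intra- vs inter-clonal distances, same-barcode fractions, single-linkage dendrograms with Newick export |
| `cohort_stats` | Connectivity-rate contingency analyses (χ²/Fisher), stratified rates by subtype/distance/age, independence and coordinated-output tests, plus a transcribed source-count fixture that the pipeline re-derives exactly |
| `cli_io` | HDF5 session container, JSON circuit/config round-trips, and the `clonal-circuits` command-line interface |

## Worked example

Simulate a three-cell recording session — a gap-coupled FS pair plus a
chemical synapse onto a non-FS cell — and recover the connectivity:

```python
from clonalcircuits import simcircuit as sc
from clonalcircuits import connectivity_detect as cd
from clonalcircuits.simcircuit import CellMeta, ChemSynapse, CircuitSpec

circuit = CircuitSpec(
    cells=[
        (sc.preset("FS"), CellMeta(0)),
        (sc.preset("FS"), CellMeta(1)),
        (sc.preset("nonFS"), CellMeta(2)),
    ],
    gap_junctions=[(0, 1, 1.5)],  # nS
    chem_synapses=[ChemSynapse(pre=1, post=2, peak_conductance_nS=1.5, latency_ms=2.0)],
)
protocol = sc.build_protocol(1000.0, 500.0)
session = sc.simulate_session(circuit, protocol, seed=11)

for r in cd.connection_matrix(session):
    print(
        f"pair {r.pair}: electrical={r.electrical_coupled} "
        f"(cc={r.coupling_coefficient:.3f}), chemical={r.directionality}"
    )
```

Output:

```text
pair (0, 1): electrical=True (cc=0.184), chemical=none
pair (0, 2): electrical=False (cc=-0.000), chemical=none
pair (1, 2): electrical=False (cc=-0.000), chemical=uni
```

The recovered coupling coefficient matches the analytic value
`g / (g + G₂) = 1.5 / (1.5 + 6.67) ≈ 0.184` for a 1.5 nS junction onto a
150 MΩ FS cell.

## Command-line interface

```bash
clonal-circuits simulate --seed 7 --out out/          # demo session (HDF5) + circuit JSON
clonal-circuits detect --session out/session.h5       # connection calls -> connections.csv
clonal-circuits features --seed 3 --n-fs 3 --n-nonfs 3  # FS/non-FS classification table
clonal-circuits correlogram --spikes spikes.csv --duration-ms 20000 --cell-a 0 --cell-b 1
clonal-circuits spatial --cloneset clones.csv         # NND CDFs, clonal distances, dendrogram
clonal-circuits stats --cohort cohort.csv --stratifier lineage
clonal-circuits reproduce-paper                       # recompute the transcribed source counts
```

All commands accept `--config <json>` (see `cli_io.PipelineConfig`) and
`--out <dir>`; every artifact directory gets a run log with the seed,
a config hash and the package version, and seeded runs are byte-identical.

## Testing

```bash
pytest -q tests/
```

The suite covers analytic oracles (passive linearity, coupling coefficients,
Poisson NND law), independent brute-force reimplementations (single-linkage
clustering, pair enumeration, χ² tables), statistical calibration of the
correlogram null, byte-level determinism of the session container, and one
acceptance test per criterion.

See `docs/methods.md` for the model equations, parameter tables, detection
criteria and known limitations.
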