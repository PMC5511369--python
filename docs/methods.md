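# Methods

This document specifies the model, numerical choices, detection criteria and
statistical procedures implemented by `clonalcircuits`, and the known
limitations of each.

## 1. Neuron and circuit model (`simcircuit`)

Each cell is a leaky single-compartment membrane:

```
C dV/dt = -(V - V_rest)/R_in + I_gap + I_syn + I_inj + I_noise
```

with `G_leak = 1/R_in`. Gap junctions are ohmic and bidirectional,
`I_gap(i) = Σ_j g_ij (V_j - V_i)`; they are stored canonically as
`(min(i,j), max(i,j), g_nS)`. Chemical synapses are conductance-based with a
difference-of-exponentials kernel (`rise_ms`, `decay_ms`), a transmission
`latency_ms` measured from the presynaptic AP peak, and a GABAergic reversal
(default −40 mV relative to typical holding, giving depolarizing-clamp PSCs
of unambiguous sign at −70 mV).

**Action potentials are stamped, not integrated.** When `V` crosses
`spike_threshold_mV` from below, a parametric AP waveform (rise, half-width,
decay, afterhyperpolarization amplitude/time, optional spike-frequency
adaptation that increments an adaptive threshold) is written into the voltage
trajectory and the integrator resumes from the post-AHP state. This makes AP
shape an explicit, exactly-controllable feature target for the classifier
and keeps the subthreshold dynamics linear and analytically checkable.

Integration is forward Euler with `DT_MS = 0.05 ms`; recordings are sampled
at 10 kHz (two integration substeps per sample). The integrator is a numba
kernel; any non-finite membrane state raises `SimulationError` naming the
failing step. Dynamics are deterministic given the circuit, so each
(driver, clamp-mode) trial is integrated once; recording noise (Gaussian,
default 0.05 mV on voltage and 0.5 pA on current, optional slow sinusoidal
drift) is drawn independently per trial from the session seed.

### Presets

| Parameter | FS | non-FS | PN |
| --- | --- | --- | --- |
| V_rest (mV) | −65 | −60 | −70 |
| R_in (MΩ) | 150 | 450 | 120 |
| C (pF) | 80 | 60 | 150 |
| AP threshold (mV) | −33 | −42 | −45 |
| AP half-width (ms) | 0.5 | 1.0 | 1.4 |
| AHP amplitude (mV) | 12 | 4 | 6 |
| Adaptation strength | 0 | 2 | 4 |

`make_population` jitters these multiplicatively; jitter magnitudes that
would push a parameter across its subtype's classification margin raise
`ValidationError` rather than silently producing a mislabelled ground truth.

### Stimulus protocol and sessions

`build_protocol(brief_amp_pA, long_depol_pA)` assembles the paired-recording
trial: three brief suprathreshold pulses, a 200 ms / −200 pA hyperpolarizing
step, and a 1 s depolarization. A `RecordingSession` holds ≥ 20 trials per
driver in each of two modes: *electrical* trials (all cells in current
clamp) and *chemical* trials (all non-drivers voltage-clamped at −70 mV so
each driver's postsynaptic currents are read in isolation).

### Generators

`make_clonal_pattern` draws clone centres uniformly in a given volume and
scatters members isotropically (Gaussian, `clone_sd_um`), with optional
partial labelling and multiple fluorophores. `simulate_pair_cohort` draws
pair-level outcomes (electrical/chemical, subtype pair, distance, age,
layer) with class-dependent probabilities — outcomes across modalities are
generated independently, which is what the independence analyses assume
under the null. `simulate_common_drive` injects a shared suprathreshold
drive plus independent current noise (default 60 pA SD) into two FS cells
with an optional gap junction, for the synchrony experiment.

## 2. Feature extraction and subtype call (`ephys_features`)

From a current-step family (default −50, 100…400 pA; 1 s steps):
resting potential, input resistance (from the subthreshold step), AP
threshold (dV/dt criterion), half-width, rise and decay times, AHP amplitude
and time-to-trough, maximum firing rate, and adaptation ratio (last/first
interspike interval of the 1 s depolarization). Features that cannot be
measured from the provided sweeps are NaN and listed by
`MembraneFeatures.undefined()`; classifying with missing required features
raises `FeatureUndefinedError`.

A cell is called FS iff **all** criteria hold (defaults in
`SubtypeCriteria`): max firing ≥ 80 Hz, adaptation ratio ≤ 2.5, R_in ≤ 300
MΩ, AP threshold ≥ −35 mV, half-width ≤ 1.7 ms, rise ≤ 1.9 ms, decay ≤ 7.5
ms, AHP ≥ 8 mV, AHP time ≤ 6.5 ms. Each criterion is individually necessary
(tested by single-feature flips).

## 3. Connectivity detection (`connectivity_detect`)

**Electrical.** During the driver's −200 pA hyperpolarizing step, the
receiver's deflection is the mean over the last 100 ms of the step minus a
50 ms pre-step baseline, averaged across trials. A pair is coupled iff the
co-hyperpolarization exceeds 0.1 mV. The coupling coefficient is the
receiver/driver deflection ratio; for a passive two-cell circuit it equals
`g / (g + G₂)` analytically, and the simulator recovers it within 1%.

**Chemical.** From voltage-clamp (chemical-mode) trials: isolated
presynaptic APs (preceding interspike gap ≥ 15 ms) trigger averaging of the
postsynaptic current. A gap-junction current prediction — conductance
estimated by regressing postsynaptic current on presynaptic voltage during
the hyperpolarizing epoch of the same trials — is subtracted before
measurement, because gap-junction spikelet currents otherwise trip the
amplitude criterion on pure electrical pairs. A connection is called iff the
baseline-subtracted PSC in the (1, 5] ms window after the AP peak exceeds
0.5 pA. Both detectors require ≥ 10 trials per mode
(`InsufficientDataError`) and a protocol containing the required epochs
(`ProtocolError`).

## 4. Cross-correlograms (`sync_corr`)

For trains 1 and 2 of equal duration `T`, lags `t2 − t1` within ±window
(default 500 ms, must cover the 200 ms significance neighbourhood) are
counted in 1 ms bins centred on integer lags (round-half-even, which makes
the antisymmetry `C_ab(τ) = C_ba(−τ)` exact). The Poisson expectation per
bin is `E = λ₁ λ₂ Δt T` with `σ = √E` and `Z = (C − E)/σ`. A bin is a
significant peak iff its Z exceeds that of **every** other bin within
±200 ms by more than 3 (mode `"all"`, the default; `"adjacent"` compares
only the two neighbouring bins). Calibration on independent Poisson pairs:
Z mean ≈ 0, variance ≈ 1, ≤ 2% of runs with any significant peak.

The common-drive synchrony experiment uses 20 s of firing: near-periodic
~127 Hz firing gives the correlogram a comb structure whose ±8 ms harmonics
can come within 3 SD of the zero-lag peak at 10 s; 20 s separates them
reliably.

## 5. Spatial and clonal statistics (`spatial_clonal`)

Nearest-neighbour distances are computed with a KD-tree under three class
rules: `all`, `within-label` (nearest same-fluorophore neighbour) and
`cross-label` (nearest other-fluorophore neighbour, pooled over both
directions). The empirical NND CDF is compared against the analytic 3-D
Poisson law `F(d) = 1 − exp(−(4/3)πλd³)`. Clonal analysis splits all
pairwise distances into intra- and inter-clonal sets (Mann-Whitney
contrast); `same_barcode_fraction(max_dist_um)` is the fraction of pairs
within the distance cutoff sharing a barcode (None when no pair qualifies).
Dendrograms use SciPy single linkage (average available) on soma distances,
with recursive Newick export (branch length = merge-height difference).

## 6. Cohort statistics (`cohort_stats`)

Rates are percentages rounded half-up to one decimal (decimal arithmetic,
matching the source counts' convention). Group contrasts use Pearson χ²
without continuity correction (Fisher's exact optional for 2×2); tables with
an all-success or all-failure margin raise `DegenerateTableError`.
`stratified_rates` bins cohorts by lineage class, subtype pair, intersomatic
distance (default edges 0, 20, 50, 100, 150, 200, ∞ μm) or age (P0, 7, 11,
14, 22, ∞) and contrasts lineage classes within each stratum.
`electrical_chemical_independence` tests electrical rate by chemical status,
chemical rate by electrical status, and the bidirectional fraction by
electrical status (the last degrades to `test='none'` when a group is
empty). `coordinated_output` contrasts — within each lineage class — the
fraction of pairs that are both presynaptic to a common pyramidal cell,
between coupled and non-coupled pairs.

The bundled `data/paper_counts.csv` transcribes every (k, n) connectivity
count printed in the source study's results and
`data/paper_comparisons.csv` the significance labels of its group
contrasts; `reproduce_paper_report()` recomputes all of them and marks each
PASS/FAIL (all PASS).

## 7. I/O and CLI (`cli_io`)

Sessions are stored in HDF5 (`/trials/<k>/cells/<id>` float32 traces with
`clamp_mode`/`holding_mV` attributes, `/meta/cells` CSV table, root
attributes for sampling rate, protocol, seed and circuit). Files are written
with `track_times=False` and atomic temp-file-then-rename, so seeded runs
are byte-identical. `PipelineConfig` round-trips through JSON (open-ended
bins serialize as null), rejects unknown keys, and hashes to a 16-hex-digit
config identifier recorded with the seed and package version in every run
log. The `clonal-circuits` CLI exposes `simulate`, `features`, `detect`,
`correlogram`, `spatial`, `stats` and `reproduce-paper`; unknown flags exit
with status 2 and domain errors with status 1.

## 8. Known limitations

- **Indirect gap coupling.** The pairwise 0.1 mV co-deflection rule cannot
  distinguish direct from indirect coupling along gap-junction chains: with
  conductances of 0.5–3 nS, second-order deflections (≈ cc² of the driver
  deflection) exceed 0.1 mV, so a chain A–B–C is detected as a triangle.
  This is a property of the experimental criterion, not a detector bug.
  Fidelity experiments therefore sample gap edges as a matching (each cell
  in at most one gap junction), or use conductances weak enough that only
  direct edges cross the criterion.
- **Stamped APs.** Spike shape is parametric, so the simulator cannot
  exhibit conductance-driven AP distortions; near-threshold behaviour is a
  hard threshold rather than a soft spike-initiation dynamic.
- **Chemical kinetics.** PSCs are difference-of-exponentials with fixed
  kinetics per synapse; no short-term plasticity, so adaptation-dependent
  PSC trains are out of scope.
- **Cohort generator.** `simulate_pair_cohort` draws pair outcomes
  independently across modalities and pairs; it models printed rate tables,
  not within-slice correlation structure.
- **Real-data distributions** (coupling-strength distributions, PSC
  amplitude distributions, immunomarker concordance percentages) are not
  reproduction targets; only the printed counts, rates and significance
  labels are.
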