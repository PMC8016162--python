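# k2ptraj

Trajectory analysis for two-pore-domain (K2P) potassium-channel
simulations, built around the workflow used to characterise the TRAAK
channel in long molecular-dynamics campaigns: featurize the selectivity
filter (SF), embed its conformational space, classify metastable states,
count ion conduction events, and apply the standard gating and
lipid-penetration rules.

It is aimed at computational biophysicists who have (or emulate)
microsecond-scale trajectories of a K2P channel and want a tested,
reproducible implementation of the analysis chain rather than a pile of
one-off scripts.

## What it computes

**SF featurization.** The filter of a K2P channel is four P-loops of
five residues (the T-x-G-x-G motif). Its conformation is summarised by
44 torsions: backbone φ/ψ of the 20 filter residues plus χ₁ of the four
threonines that form the S4 ion site. The package extracts these from
PDB + DCD/XTC input, along with SF-backbone RMSD (Kabsch superposition),
axial ion coordinates and in-plane (membrane-plane) distances from the
pore axis.

**Sketch-map embedding.** A nonlinear multidimensional scaling that
preserves mid-range structure. Distances R (high-d) and r (low-d) pass
through sigmoids

    s(r) = 1 − (1 + (2^(p/q) − 1)(r/σ)^p)^(−q/p)

and the landmark embedding minimises the stress
χ² = Σ_{i<j} [F(R_ij) − f(r_ij)]², with F = s(·; σ, A, B) and
f = s(·; σ, a, b). Landmarks are chosen by farthest-point sampling; all
other frames are projected out of sample by minimising their
single-point stress against the fixed landmarks. `SketchMap` follows
the scikit-learn estimator protocol (`fit`/`transform`,
`get_params`/`set_params`) and composes with sklearn pipelines. The
customary parameter set σ = 2.5, A = B = 12, a = 1, b = 2 is the
default.

**State classification.** DBSCAN (min_points includes the point itself;
grid-accelerated exact implementation that stays in memory even when a
metastable state collapses to a near-duplicate cloud) partitions the
2-D map inside an analysis window. Each cluster is labelled by the
modal carbonyl-flip signature of its frames — which ion-site boundaries
(S4–S3 … S1–S0) have a backbone C=O rotated away from the pore axis,
and on which subunit — mapped onto the conventional state names I
(native/conductive) through VII, with population tables per simulation
condition.

**Permeation and conductance.** A three-region state machine detects
complete below→inside→above filter crossings per ion; the single-channel
conductance follows from the event count N over duration T at voltage
ΔV as G = N·e/(T·ΔV), aggregated over replicas as mean ± sample SD.
A constant-field helper converts a transmembrane voltage into the
uniform field E_z = ΔV/L_z.

**Gating and lipids.** TM2–TM4 interface Cα–Cα distances (e.g. Pro155
to Ile279) classify each frame as up (≤ 8 Å) or down (> 8 Å); a state
is *prevalent* only if it holds for strictly more than 50% of a run.
A lipid is *in the cavity* iff its headgroup sits strictly below 10 Å
from the pore axis for strictly more than 50% of the frames. Distance
distributions are summarised by KDE modes; transition counts support a
dwell-time debounce.

**Synthetic data.** Every input has a generator with exact ground
truth: an idealised four-fold filter with plantable carbonyl flips,
Markov-switching 44-D dihedral series (von Mises angular noise), ion
traces with an exact number of planted crossings, telegraph gating
traces, water-occupancy traces and lipid cavity excursions. These stand
in for trajectory data that cannot be redistributed, and make every
stage testable end to end.

## Worked example

The bundled campaign summary (32 replicas × 1 μs across two force
fields, two initial SF ion configurations and three voltages) carries
recorded conduction-event counts. Reproducing the replica-averaged
conductance lines:

```python
from k2ptraj.datasets import load_campaign_registry, campaign_event_counts
from k2ptraj.permeation import aggregate_conductance, round_half_up
from k2ptraj.io import total_duration_us

registry = load_campaign_registry()
print(f"campaign: {len(registry)} replicas, {total_duration_us(registry):.0f} us total")
for ff, cfg, mv in [("AMBER","KK",100.0), ("AMBER","KK",200.0),
                    ("AMBER","KWK",100.0), ("CHARMM","KK",200.0)]:
    counts, durations = campaign_event_counts(registry, ff, cfg, mv)
    est = aggregate_conductance(counts, durations, mv)
    print(f"{ff}-{cfg} at +{mv:.0f} mV: events {counts} -> "
          f"{round_half_up(est.mean,1)} +/- {round_half_up(est.sd,1)} pS")
```

prints

```
campaign: 32 replicas, 32 us total
AMBER-KK at +100 mV: events [2, 4, 2] -> 4.3 +/- 1.9 pS
AMBER-KK at +200 mV: events [3, 11, 8] -> 5.9 +/- 3.2 pS
AMBER-KWK at +100 mV: events [1, 0, 2] -> 1.6 +/- 1.6 pS
CHARMM-KK at +200 mV: events [0, 11, 0] -> 2.9 +/- 5.1 pS
```

Each line is charge transported per time per voltage: three crossings
per microsecond at +100 mV is ≈ 4.8 pS, an order of magnitude below the
tens-of-pS single-channel conductances measured electrophysiologically
for TRAAK — the well-known gap between simulated and measured
conduction.

The same stages run from the shell. A fully synthetic replica with
known ground truth:

```bash
k2ptraj simulate --out-dir replica0 --n-frames 5000 --events 4 --seed 1
k2ptraj permeation --ions replica0/ions.csv --voltage 100 --duration 1.0 --json
k2ptraj embed --features replica0/dihedrals.csv --landmarks 100 --sigma 100 \
              --out replica0/low_d.csv --seed 1
k2ptraj cluster --coords replica0/low_d.csv --eps 50 \
                --window -1e6 1e6 -1e6 1e6 --out replica0/labels.csv
```

`k2ptraj run config.yaml` orchestrates every stage over a replica
registry and writes JSON reports (per replica plus an aggregate with
population and conductance tables), each embedding the config hash,
seed and package version.

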