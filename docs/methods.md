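# Methods

This note documents the models, parameters and numerical choices behind
k2ptraj, in the spirit of the methods documentation of packages like
statsmodels or msprime: what each stage assumes, which knobs matter, and
what the synthetic generators do and do not emulate.

## Coordinate conventions

Coordinates and distances are Angstrom everywhere inside the package;
unit conversion happens only at file boundaries (XTC stores nm and is
converted on read/write). Times are nanoseconds internally; replica
durations are microseconds, matching how microsecond campaigns are
tabulated, with a single tested conversion (`us_to_ns`). Angles are
degrees in the half-open interval (−180, 180]; a value falling exactly
on the branch cut maps to +180. Residues keep the author numbering of
the input PDB (Thr129, Pro155, Ile279 …) and are never re-indexed;
insertion codes are rejected rather than silently flattened. The pore
axis is the z-axis after centering on the SF-backbone centroid — the
membrane normal is z by construction in membrane-protein setups — and a
fitted principal axis is deliberately out of scope.

## Featurization

The 44-column dihedral matrix is rigid by contract: four P-loops ×
(5 residues × φ/ψ + one threonine χ₁), P-loop-major, N→C within a loop,
χ₁ last. φ of the first filter residue needs the preceding residue's
carbonyl carbon and ψ of the last needs the following amide nitrogen;
if either is absent the extraction fails naming the atom rather than
dropping a column, because every downstream stage assumes the fixed
layout. Torsions use the atan2 formulation with the clockwise-positive
(IUPAC) sign convention; coincident or collinear defining atoms raise,
since the torsion is undefined there. SF-backbone RMSD superposes each
frame on the reference (first frame by default) with a Kabsch fit via
`scipy.spatial.transform.Rotation.align_vectors`, so the series
reflects internal deformation only; whether to superpose on the SF, the
whole protein, or not at all is a genuine analysis choice — fitting on
the SF itself is this package's documented default.

## Sketch-map

The switching function s(r) = 1 − (1 + (2^{p/q} − 1)(r/σ)^p)^{−q/p}
satisfies s(0) = 0, s(σ) = ½ for every exponent pair, and s → 1 as
r → ∞. The landmark stress is the unweighted sum of squared sigmoid
mismatches over landmark pairs; no pair weighting is applied. The
conventional parameter set σ = 2.5 (in feature-space distance units),
A = B = 12, a = 1, b = 2, with 1000 landmarks (capped at the frame
count), is the default.

Choices that were genuinely open:

* **Distance metric.** Dihedrals are periodic, so the default metric
  wraps each coordinate difference to min(|Δ|, 360 − |Δ|) before the
  euclidean norm; plain euclidean is available as a flag since using
  raw angle values directly is also common practice. Neither is
  asserted to be "the" field convention.
* **Landmark selection.** Farthest-point sampling: seeded random first
  pick, then each landmark maximises its minimum distance to the chosen
  set. FPS covers the data's extent, which suits a method whose purpose
  is to separate basins; density-biased selection is not provided.
* **Optimization.** Landmarks are initialised by classical (Torgerson)
  MDS on the F-transformed distance matrix, then refined by L-BFGS with
  analytic gradients; 4 seeded restarts perturb the MDS start and the
  best final stress wins (the stress is non-convex). Convergence uses
  ftol 1e−8 with a 10⁴-iteration cap; a non-finite stress aborts.
* **Out-of-sample projection.** Each point minimises its single-point
  stress with landmarks fixed. The coarse stage evaluates a 20 × 20
  grid over the landmark bounding box *plus the landmark positions
  themselves* — the latter guarantees that a duplicate of a landmark
  recovers that landmark's coordinates — and the best candidate is
  refined by 60 iterations of vectorized backtracking gradient descent.
  The procedure is deterministic given its inputs.
* **Map units.** The stress fixes only relative geometry; with b = 2
  the mutual repulsion of sigmoid-saturated pairs stops only where the
  low-d sigmoid flattens numerically, so well-separated basins land far
  apart and the map's absolute scale is meaningless. Any analysis
  window must therefore be expressed in *this* map's units; the package
  makes the window a user parameter and claims no equivalence to any
  published window.

Two performance details do not change semantics: integer sigmoid
exponents are evaluated by repeated multiplication rather than
`np.power` (the float-power path dominates runtime otherwise), and
point-to-landmark distances in the projection use the Gram expansion
‖p‖² − 2p·Y + ‖Y‖² so the hot loop is GEMM-bound. A 10⁵-frame, 44-D
projection onto 60 landmarks runs in about 90 s on one CPU.

## State classification

DBSCAN uses the convention in which `min_points` counts the point
itself (min_points = 3 means two genuine neighbours). Points outside
the rectangular analysis window never enter the clustering and are
noise by definition. The implementation is an exact grid-accelerated
DBSCAN: neighbour *counts* come from a KD-tree (memory O(n)); core
connectivity is resolved through cells of side eps/√2, inside which all
points are mutually within eps, so dense near-duplicate clouds — the
typical shape of a metastable state under a steep high-d sigmoid —
never materialise quadratic neighbour lists. Cluster ids are numbered
by ascending lowest member index and border points join the
smallest-id adjacent cluster, making the output deterministic for a
fixed point order. The implementation is property-tested against a
brute-force reference built directly from the distance matrix.

A carbonyl is *flipped* iff the in-plane component of its C→O unit
vector has strictly negative dot product with the in-plane unit vector
from C toward the pore axis; an exactly tangential carbonyl (cosine 0)
is not flipped. The residue-position → site-boundary table is
configurable and defaults to the KcsA-like assignment (threonine →
S4–S3, position 2 → S3–S2, position 3 → S2–S1, position 4 → S1–S0),
because the structural attribution of glycine flips in K2P filters is
genuinely debated. Clusters are labelled by their modal flip signature
with ties broken toward fewer flips (conservative toward the native
state); populations are percentages over *all* frames of a condition,
so noise and unmatched signatures fill the "other" column and rows sum
to 100.

## Permeation and conductance

The event detector is a three-region state machine (below / inside /
above the filter bounds). An event completes when an ion leaves the
filter on the side opposite to the one it entered from; excursions that
retreat count nothing, which prevents double counting when ions rattle
at a boundary plane. Ions that *start* inside the filter are treated by
default as part of the conducting file (their first exit counts); the
flag `count_initial_inside=False` disables this, since a pre-loaded
filter is the usual initial condition and the right treatment is a
modelling choice. The filter's crossing planes z_low/z_high are user
inputs with defaults ±6 Å around the SF centroid; no published
consensus definition exists.

Conductance: G[pS] = N × 1.602176634e−19 C / (T[s] × ΔV[V]) × 10¹²,
aggregated over replicas as mean ± sample SD (n − 1 denominator), with
zero-event replicas contributing 0 pS rather than being dropped —
dropping them would bias the mean upward. Report formatting rounds
half-up to one decimal. Conductance at 0 mV is undefined and raises.
Water gating: occupancy counts waters with z inside the bounds (and
optionally within the radial cylinder); only events completing at or
after the first zero-occupancy frame are kept, and if the filter never
empties, no events are countable.

## Gating and lipid rules

All three classification rules are strict inequalities, read literally
from their definitions: down ⇔ distance > 8 Å (exactly 8 is up);
prevalent ⇔ fraction > 0.5 (an exact half gives "none"); in-cavity ⇔
headgroup distance < 10 Å for a fraction > 0.5 of frames (exactly 10 Å
is outside, an exact half is not flagged). Transition counting debounces
by requiring a state to persist `min_dwell` frames; the default of 1
(no debounce) keeps the rule faithful, and the flag exists because
noisy distance traces need it. Distribution modes come from a Gaussian
KDE (Silverman bandwidth by default) evaluated on a 0.05 Å grid; all
local maxima above 10% of the global peak are reported in height order,
and a constant series short-circuits to its single value (a KDE is
singular there).

## Synthetic generators

The generators emulate the *statistical structure* the pipeline
consumes, not channel physics:

* `build_filter_coordinates` — an idealised four-fold filter: four
  P-loops at 90° azimuthal spacing (chains A/B each contributing two
  loops with author numbering 129–133 and 238–242), backbone N/CA/C/O
  for the five filter residues plus one flanking residue each side (so
  every φ/ψ is computable), threonine CB/OG1 for χ₁. Carbonyls point
  exactly at (or exactly away from) the pore axis; von Mises jitter
  with circular SD equal to `angular_noise` perturbs their in-plane
  orientation. At zero noise the flip classifier recovers the planted
  signature exactly, by construction.
* `simulate_dihedral_series` — a continuous-time Markov chain sampled
  at frame resolution through the exact transition kernel expm(Q·dt),
  started from its stationary distribution; per-state mean 44-vectors
  plus von Mises noise (wrapped support — no artefacts at ±180°).
  Reducible rate matrices are rejected. Empirical occupancies converge
  to the analytic stationary law; at 10⁵ frames the occupancy standard
  error is ≈ √(π(1−π)·2τ/N·dt⁻¹), so recovery tests use switching rates
  (≈ 0.5/ns at 0.1 ns frames) fast enough that a 2%-absolute band has
  real statistical power.
* `simulate_ion_traces` — 1-D axial traces only, since every permeation
  rule is axial. Background: a reflected random walk strictly below the
  filter entry. Planted events are deterministic linear ramps through
  both planes; after dwelling above, the trace returns below the filter
  *discontinuously* (the periodic-image re-entry of a real box), which
  crosses no plane from inside, so the planted count is exactly the
  detectable outward count — the ground-truth log is exact, not
  approximate.
* `simulate_gating_trace` / `simulate_water_trace` /
  `simulate_lipid_trace` — a two-state telegraph process with Gaussian
  noise; water traces that vacate the filter at an exact frame; lipid
  traces spending an exact rounded fraction of frames below the cavity
  cutoff (noise clipped so it cannot cross the boundary, keeping the
  fraction exact even at the strict 50% edge).

All generators are pure functions of (spec, seed) with a single
`numpy.random.default_rng(seed)` per call: identical arguments give
bitwise-identical output. What passing tests on these data do **not**
show: force-field realism, water-mediated conduction mechanisms,
radial ion behaviour, membrane mechanics, or kinetic rates of carbonyl
flips (no published rates exist; the generator's rates are free
parameters).

## Problem sizes and validation scales

The closed-loop recovery benchmark uses a three-state dihedral process
of 10⁵ frames at 0.1 ns (κ = 300, i.e. ≈ 3.3° angular SD), embedded
with σ = 100 (between the intra-state distance scale ≈ 30 and the
inter-state scale ≈ 700) onto 60 FPS landmarks, clustered at eps = 50
inside a wide window. This recovers the three states with perfect
purity and stationary populations within 1% absolute; the whole
benchmark runs in ≈ 2 minutes on one CPU, and the same configuration is
what `scripts/acceptance.py` re-runs. Permeation recovery is exact for
planted counts 0–11 whenever the background-walk noise amplitude stays
below a quarter of the filter span, the regime the generator enforces
by reflecting the walk below the entry plane.

## Known limitations

* XTC files carry no declared total frame count, so truncation at an
  exact frame boundary is detectable for DCD (header nset) but not XTC.
* PDB round-trips quantise coordinates to the format's 3 decimal places.
* The sketch-map map scale is run-specific; windows and eps values do
  not transfer between embeddings with different σ or data.
* Only orthorhombic boxes are represented; no PBC re-imaging is done
  beyond what the distance operations need.
* The pipeline's state labelling needs per-frame flip signatures
  (from 3-D frames or a signature sidecar); dihedral-only input can be
  clustered but clusters are then labelled generically.
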