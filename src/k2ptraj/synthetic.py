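"""Synthetic trajectory and feature generators with known ground truth.

Real microsecond MD of a K2P channel is not something a test suite can
produce, so every input the analysis pipeline consumes is emulated here
with generators whose ground truth is known exactly:

* an idealised four-fold selectivity filter with controllable carbonyl
  flips (:func:`build_filter_coordinates`),
* metastable 44-dimensional dihedral time series driven by a
  continuous-time Markov chain (:func:`simulate_dihedral_series`),
* ion axial traces with an exact number of planted permeation events
  (:func:`simulate_ion_traces`),
* two-state telegraph traces for the TM4 up/down gating distance
  (:func:`simulate_gating_trace`),
* lipid headgroup in-plane distance traces with cavity excursions
  (:func:`simulate_lipid_trace`).

All generators are pure functions of (spec, seed): the same arguments
give bitwise-identical output.  Angular noise is von Mises (wrapped
support) rather than Gaussian, so there are no artifacts at the +/-180
degree branch cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components

from .io import AtomRecord, FeatureTable, Trajectory
from .features import wrap_degrees

__all__ = [
    "SFGeometrySpec",
    "StateKineticsSpec",
    "IonTraceSpec",
    "build_filter_coordinates",
    "simulate_dihedral_series",
    "simulate_ion_traces",
    "simulate_gating_trace",
    "simulate_water_trace",
    "simulate_lipid_trace",
    "stationary_distribution",
]


class SyntheticError(ValueError):
    """Raised for invalid generator specifications."""


# ---------------------------------------------------------------------------
# Idealised selectivity-filter geometry
# ---------------------------------------------------------------------------

FILTER_MOTIF = ("THR", "ILE", "GLY", "PHE", "GLY")
FLANK_NAME = "ALA"
CO_BOND_LENGTH = 1.23  # Angstrom

# P-loop layout of the homodimer: (chain id, first filter residue).
DEFAULT_PLOOPS = (("A", 129), ("A", 238), ("B", 129), ("B", 238))


@dataclass(frozen=True)
class SFGeometrySpec:
    """Geometry of the idealised filter.

    ``flip_signature`` lists (ploop index 0-3, residue position 0-4) pairs
    whose backbone carbonyl points away from the pore axis; all other
    carbonyls point toward it.  ``angular_noise`` (degrees) jitters each
    carbonyl's in-plane orientation with a von Mises rotation.
    """

    n_ploops: int = 4
    residues_per_loop: int = 5
    pore_radius: float = 3.0
    rise_per_residue: float = 3.0
    flip_signature: frozenset = frozenset()
    angular_noise: float = 0.0
    ploop_layout: tuple = DEFAULT_PLOOPS

    def __post_init__(self) -> None:
        if self.n_ploops < 1:
            raise SyntheticError("n_ploops must be >= 1")
        if len(self.ploop_layout) < self.n_ploops:
            raise SyntheticError("ploop_layout shorter than n_ploops")
        for k, j in self.flip_signature:
            if not (0 <= k < self.n_ploops and 0 <= j < self.residues_per_loop):
                raise SyntheticError(f"flip target ({k}, {j}) out of range")
        if self.angular_noise < 0:
            raise SyntheticError("angular_noise must be >= 0")


def _vonmises_jitter(rng: np.random.Generator, noise_deg: float, size=None):
    """Von Mises rotation angles (radians) with circular sd ~ noise_deg."""
    if noise_deg == 0:
        return np.zeros(size) if size else 0.0
    kappa = 1.0 / np.radians(noise_deg) ** 2
    return rng.vonmises(0.0, kappa, size)


def build_filter_coordinates(spec: SFGeometrySpec, seed: int = 0) -> Trajectory:
    """Build a single-frame idealised filter as a :class:`Trajectory`.

    Each P-loop sits at a 90-degree azimuthal offset around the z axis
    (pseudo-4-fold symmetry).  Backbone N, CA, C, O are placed for the
    five filter residues plus one flanking residue on each side, so that
    every phi/psi of the filter is computable; the threonine carries CB
    and OG1 for chi1.  With ``angular_noise == 0`` the geometry is exact:
    a non-flipped carbonyl's C->O vector has inward radial cosine +1, a
    flipped one -1.
    """
    rng = np.random.default_rng(seed)
    rise = spec.rise_per_residue
    r_n, r_ca, r_c = spec.pore_radius + 1.6, spec.pore_radius + 2.2, spec.pore_radius + 1.0
    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []

    def add(chain, resid, resname, name, x, y, z):
        atoms.append(AtomRecord(name, resname, resid, chain, (x, y, z)))
        coords.append((x, y, z))

    def cart(radius, azimuth_deg, z):
        a = np.radians(azimuth_deg)
        return radius * np.cos(a), radius * np.sin(a), z

    for k in range(spec.n_ploops):
        chain, first = spec.ploop_layout[k]
        base_az = 360.0 * k / spec.n_ploops
        for j in range(-1, spec.residues_per_loop + 1):
            resid = first + j
            if 0 <= j < spec.residues_per_loop:
                resname = FILTER_MOTIF[j % len(FILTER_MOTIF)]
            else:
                resname = FLANK_NAME
            z0 = j * rise
            xn, yn, zn = cart(r_n, base_az - 8.0, z0)
            add(chain, resid, resname, "N", xn, yn, zn)
            xa, ya, za = cart(r_ca, base_az, z0 + 1.0)
            add(chain, resid, resname, "CA", xa, ya, za)
            xc, yc, zc = cart(r_c, base_az + 8.0, z0 + 2.0)
            add(chain, resid, resname, "C", xc, yc, zc)
            # carbonyl O: in-plane unit vector from C toward (flip: away from)
            # the axis, rotated by the von Mises jitter about z
            inward = -np.array([xc, yc])
            inward /= np.linalg.norm(inward)
            if (k, j) in spec.flip_signature:
                inward = -inward
            phi = _vonmises_jitter(rng, spec.angular_noise)
            ca_, sa_ = np.cos(phi), np.sin(phi)
            direction = np.array(
                [ca_ * inward[0] - sa_ * inward[1], sa_ * inward[0] + ca_ * inward[1]]
            )
            add(chain, resid, resname, "O",
                xc + CO_BOND_LENGTH * direction[0],
                yc + CO_BOND_LENGTH * direction[1], zc)
            if j == 0:  # threonine side chain for chi1
                xb, yb, zb = cart(r_ca + 1.5, base_az + 14.0, z0 + 1.5)
                add(chain, resid, resname, "CB", xb, yb, zb)
                xo, yo, zo = cart(r_ca + 2.4, base_az + 26.0, z0 + 1.2)
                add(chain, resid, resname, "OG1", xo, yo, zo)
    return Trajectory(atom_table=atoms, frames=np.array(coords)[None, :, :],
                      frame_interval=1.0)


# ---------------------------------------------------------------------------
# Markov-switching dihedral dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateKineticsSpec:
    """A continuous-time Markov chain over metastable SF conformations.

    ``rates`` is the K x K generator matrix in 1/ns (off-diagonal entries
    are transition rates; the diagonal is ignored and recomputed as the
    negative row sum).  ``means`` holds one 44-vector of mean dihedrals
    (degrees) per state; ``kappa`` the von Mises concentration of the
    angular noise (np.inf for noise-free output).  ``signatures`` may
    attach a carbonyl-flip signature to each state for closed-loop tests
    of the state-labelling stage.
    """

    labels: tuple[str, ...]
    rates: tuple = ()
    means: tuple = ()
    kappa: float = 50.0
    signatures: tuple = field(default=None)

    def rate_matrix(self) -> np.ndarray:
        q = np.array(self.rates, dtype=float)
        k = len(self.labels)
        if q.shape != (k, k):
            raise SyntheticError(f"rates must be {k}x{k}, got {q.shape}")
        if np.any(q[~np.eye(k, dtype=bool)] < 0):
            raise SyntheticError("off-diagonal rates must be >= 0")
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def mean_matrix(self) -> np.ndarray:
        m = np.array(self.means, dtype=float)
        if m.ndim != 2 or m.shape[0] != len(self.labels):
            raise SyntheticError("means must be (n_states, n_angles)")
        return m


def _check_irreducible(q: np.ndarray) -> None:
    adj = (q > 0).astype(int)
    np.fill_diagonal(adj, 0)
    n, _ = connected_components(adj, directed=True, connection="strong")
    if n != 1:
        raise SyntheticError("rate matrix is reducible: no unique stationary law")


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC generator matrix (pi @ Q = 0)."""
    k = q.shape[0]
    a = np.vstack([q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def _sample_markov_path(
    q: np.ndarray, n_frames: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Markov path at frame resolution via the exact transition kernel."""
    k = q.shape[0]
    if k == 1:
        return np.zeros(n_frames, dtype=int)
    p = expm(q * dt)
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    pi0 = stationary_distribution(q)
    path = np.empty(n_frames, dtype=int)
    path[0] = rng.choice(k, p=pi0)
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t - 1], side="right")
    return path


def simulate_dihedral_series(
    spec: StateKineticsSpec,
    n_frames: int,
    frame_interval: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a metastable dihedral time series.

    Returns ``(angles, state_path)`` where ``angles`` is (n_frames, 44)
    degrees in ``(-180, 180]`` and ``state_path`` the ground-truth state
    index per frame.  The chain starts from its stationary distribution,
    so empirical occupancies converge to the analytic stationary law.
    """
    q = spec.rate_matrix()
    _check_irreducible(q) if len(spec.labels) > 1 else None
    means = spec.mean_matrix()
    rng = np.random.default_rng(seed)
    path = _sample_markov_path(q, n_frames, frame_interval, rng)
    angles = means[path].astype(float)
    if np.isfinite(spec.kappa) and spec.kappa < 1e8:
        noise = rng.vonmises(0.0, spec.kappa, size=angles.shape)
        angles = angles + np.degrees(noise)
    return wrap_degrees(angles), path


# ---------------------------------------------------------------------------
# Ion traces with planted permeation events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonTraceSpec:
    """Axial K+ traces below the filter with planted complete crossings.

    ``planted_events`` is the total number of complete outward crossings
    over the whole ion set; events are distributed round-robin across
    ions.  Between events each ion performs a reflected random walk below
    ``z_low``.  After completing a crossing the trace jumps back below
    the filter discontinuously (the periodic-image re-entry of a real
    simulation box), which by construction crosses no plane from inside.
    """

    n_ions: int = 3
    planted_events: int = 0
    z_low: float = -6.0
    z_high: float = 6.0
    drift: float = 0.0
    noise_amplitude: float = 0.5
    ramp_frames: int = 20

    def __post_init__(self) -> None:
        if self.z_low >= self.z_high:
            raise SyntheticError("z_low must be < z_high")
        if self.planted_events < 0 or self.n_ions < 1:
            raise SyntheticError("planted_events >= 0 and n_ions >= 1 required")


def simulate_ion_traces(
    spec: IonTraceSpec,
    n_frames: int,
    frame_interval: float = 0.1,
    seed: int = 0,
) -> tuple[FeatureTable, list[dict]]:
    """Generate per-ion z(t) series plus the ground-truth event log.

    The event log lists, per planted crossing, the ion column, the frame
    at which the ion first enters the filter from below and the frame at
    which it first exceeds ``z_high``.
    """
    rng = np.random.default_rng(seed)
    events_per_ion = [spec.planted_events // spec.n_ions] * spec.n_ions
    for i in range(spec.planted_events % spec.n_ions):
        events_per_ion[i] += 1
    window = spec.ramp_frames + 5
    if max(events_per_ion, default=0) * (window + 10) > n_frames:
        raise SyntheticError(
            f"{n_frames} frames cannot host {spec.planted_events} events "
            f"across {spec.n_ions} ions (need windows of {window + 10} frames)"
        )
    rest = spec.z_low - 4.0
    ceiling = spec.z_low - 1.0  # background walk stays strictly below z_low
    columns: dict[str, np.ndarray] = {}
    log: list[dict] = []
    for ion in range(spec.n_ions):
        steps = spec.drift * frame_interval + rng.normal(
            0.0, spec.noise_amplitude, n_frames
        )
        z = np.empty(n_frames)
        z[0] = rest
        for t in range(1, n_frames):
            nxt = z[t - 1] + steps[t]
            if nxt > ceiling:  # reflect downward
                nxt = 2.0 * ceiling - nxt
            z[t] = nxt
        n_ev = events_per_ion[ion]
        if n_ev:
            slots = np.linspace(0, n_frames - window - 1, n_ev + 1)[:-1]
            starts = [int(s) + 5 for s in slots]
            for s in starts:
                ramp = np.linspace(z[s], spec.z_high + 2.0, spec.ramp_frames)
                z[s:s + spec.ramp_frames] = ramp
                z[s + spec.ramp_frames:s + window] = spec.z_high + 2.0
                # periodic-image style return below the filter
                if s + window < n_frames:
                    z[s + window] = rest
                entry = s + int(np.searchsorted(ramp, spec.z_low, side="right"))
                completion = s + int(np.searchsorted(ramp, spec.z_high, side="right"))
                log.append({"ion": f"ion_{ion}", "entry_frame": entry,
                            "completion_frame": completion, "direction": 1})
        columns[f"ion_{ion}"] = z
    times = np.arange(n_frames) * frame_interval
    return FeatureTable(times, columns), log


# ---------------------------------------------------------------------------
# Gating and lipid traces
# ---------------------------------------------------------------------------

def simulate_gating_trace(
    mean_up: float = 4.0,
    mean_down: float = 9.5,
    switch_rates: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.3,
    n_frames: int = 10000,
    frame_interval: float = 0.1,
    seed: int = 0,
    start_state: str = "up",
) -> tuple[FeatureTable, np.ndarray]:
    """Two-state telegraph trace of a TM2-TM4 interface distance.

    ``switch_rates`` are (up->down, down->up) rates in 1/ns.  Returns the
    distance series (Angstrom, Gaussian noise around the state mean) and
    the ground-truth state path (0 = up, 1 = down).
    """
    if start_state not in ("up", "down"):
        raise SyntheticError("start_state must be 'up' or 'down'")
    rng = np.random.default_rng(seed)
    k_ud, k_du = switch_rates
    if k_ud < 0 or k_du < 0:
        raise SyntheticError("switch rates must be >= 0")
    path = np.empty(n_frames, dtype=int)
    path[0] = 0 if start_state == "up" else 1
    if k_ud == 0 and k_du == 0:
        path[:] = path[0]
    else:
        p_ud = 1.0 - np.exp(-k_ud * frame_interval)
        p_du = 1.0 - np.exp(-k_du * frame_interval)
        u = rng.random(n_frames - 1)
        for t in range(1, n_frames):
            flip = u[t - 1] < (p_ud if path[t - 1] == 0 else p_du)
            path[t] = path[t - 1] ^ int(flip)
    means = np.where(path == 0, mean_up, mean_down)
    distance = means + rng.normal(0.0, noise_sd, n_frames)
    times = np.arange(n_frames) * frame_interval
    return FeatureTable(times, {"distance": distance}), path


def simulate_water_trace(
    n_frames: int,
    exit_frame: int | None,
    n_waters: int = 1,
    z_inside: float = 0.0,
    z_outside: float = -12.0,
    noise_sd: float = 0.5,
    frame_interval: float = 0.1,
    seed: int = 0,
) -> FeatureTable:
    """Water axial traces that vacate the filter at ``exit_frame``.

    All waters sit near ``z_inside`` (within the filter) for frames
    ``< exit_frame`` and near ``z_outside`` (below it) afterwards;
    ``exit_frame=None`` keeps them inside forever and ``exit_frame=0``
    means the filter was never occupied.  Noise is clipped so the ground
    truth first-empty frame is exactly ``exit_frame``.
    """
    rng = np.random.default_rng(seed)
    columns = {}
    for w in range(n_waters):
        z = np.full(n_frames, float(z_outside)) + rng.normal(0.0, noise_sd, n_frames)
        z = np.clip(z, None, z_outside + 3.0)
        cut = n_frames if exit_frame is None else min(max(exit_frame, 0), n_frames)
        if cut > 0:
            inside = z_inside + rng.normal(0.0, noise_sd, cut)
            z[:cut] = np.clip(inside, z_inside - 2.0, z_inside + 2.0)
        columns[f"water_{w}"] = z
    times = np.arange(n_frames) * frame_interval
    return FeatureTable(times, columns)


def simulate_lipid_trace(
    baseline: float = 16.0,
    cavity_value: float = 6.0,
    fraction_in_cavity: float = 0.0,
    n_frames: int = 10000,
    seed: int = 0,
    cutoff: float = 10.0,
    noise_sd: float = 0.5,
    frame_interval: float = 0.1,
) -> FeatureTable:
    """Headgroup in-plane distance trace with a cavity excursion.

    Exactly ``round(fraction_in_cavity * n_frames)`` frames lie below
    ``cutoff`` (the cavity boundary), as a single contiguous excursion
    at ``cavity_value``; the rest sit at ``baseline``.  Noise is clipped
    so it never crosses the cutoff, keeping the fraction exact.
    """
    if not (cavity_value < cutoff < baseline):
        raise SyntheticError("need cavity_value < cutoff < baseline")
    if not 0.0 <= fraction_in_cavity <= 1.0:
        raise SyntheticError("fraction_in_cavity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_below = int(round(fraction_in_cavity * n_frames))
    values = np.full(n_frames, baseline) + rng.normal(0.0, noise_sd, n_frames)
    values = np.clip(values, cutoff + 0.25, None)
    if n_below:
        start = (n_frames - n_below) // 2
        exc = cavity_value + rng.normal(0.0, noise_sd, n_below)
        values[start:start + n_below] = np.clip(exc, None, cutoff - 0.25)
    times = np.arange(n_frames) * frame_interval
    return FeatureTable(times, {"xy_distance": values})
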