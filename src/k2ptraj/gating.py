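"""TM-helix gating classification and lipid cavity-penetration analysis.

Mechanosensitive K2P channels gate through the TM4 helix: in the *up*
state TM4 packs against TM2 of the opposite subunit (reference
Ca-Ca distance near 4 Angstrom), while in the *down* state the helices
separate (above 8 Angstrom), opening a lateral fenestration toward the
membrane.  The classification rules used throughout are deliberately
strict:

* a frame is *down* iff the interface distance is strictly above the
  8 Angstrom threshold (exactly 8 is up);
* a state is *prevalent* in a run iff it holds for strictly more than
  50% of the frames, otherwise the run has no prevalent state;
* a lipid is *in the cavity* iff its headgroup in-plane distance is
  strictly below 10 Angstrom for strictly more than 50% of the frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .io import Trajectory

__all__ = [
    "GatingSummary",
    "LipidOccupancy",
    "interface_distances",
    "classify_updown",
    "count_transitions",
    "distribution_mode",
    "lipid_cavity_flag",
    "lipid_atom_profile",
    "DEFAULT_LIPID_ATOMS",
    "UP_DOWN_THRESHOLD",
    "CAVITY_CUTOFF",
]

UP_DOWN_THRESHOLD = 8.0   # Angstrom, up/down boundary of the TM2-TM4 distance
CAVITY_CUTOFF = 10.0      # Angstrom, cavity/membrane boundary for headgroups

# phosphate plus representative glycerol/acyl carbons of a PC lipid
DEFAULT_LIPID_ATOMS = ("P", "C21", "C36", "C218", "C316")


class GatingError(ValueError):
    """Raised for invalid gating/lipid inputs."""


@dataclass(frozen=True)
class GatingSummary:
    """Per-run summary of one TM2-TM4 interface."""

    fraction_down: float
    prevalent: str  # "up", "down" or "none"
    n_up_to_down: int
    n_down_to_up: int


@dataclass(frozen=True)
class LipidOccupancy:
    """Cavity-penetration summary of one lipid."""

    lipid: str
    fraction_below: float
    in_cavity: bool


def interface_distances(
    traj: Trajectory,
    refs: Sequence[tuple[tuple[str, int, str], tuple[str, int, str]]],
) -> np.ndarray:
    """Euclidean reference-atom distances per frame, one column per interface.

    ``refs`` pairs the two reference atoms of each interface, e.g. the
    Ca of Pro155 on TM2 of one subunit with the Ca of Ile279 on TM4 of
    the other.
    """
    index = traj.atom_index()
    cols = []
    for a_key, b_key in refs:
        for key in (a_key, b_key):
            if tuple(key) not in index:
                raise GatingError(
                    f"missing reference atom: chain {key[0]}, residue {key[1]}, "
                    f"atom {key[2]}"
                )
        a = traj.frames[:, index[tuple(a_key)], :]
        b = traj.frames[:, index[tuple(b_key)], :]
        cols.append(np.sqrt(((a - b) ** 2).sum(axis=1)))
    return np.column_stack(cols)


def classify_updown(
    distances: np.ndarray,
    threshold: float = UP_DOWN_THRESHOLD,
    min_dwell: int = 1,
) -> tuple[np.ndarray, GatingSummary]:
    """Classify a distance series into up/down states and summarise it.

    Returns the per-frame state array ("up"/"down") and a
    :class:`GatingSummary`.  Down requires distance strictly above the
    threshold; prevalence requires strictly more than half the frames.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise GatingError("distance series must be a non-empty 1-D array")
    down = d > threshold
    states = np.where(down, "down", "up")
    frac_down = float(down.mean())
    if frac_down > 0.5:
        prevalent = "down"
    elif (1.0 - frac_down) > 0.5:
        prevalent = "up"
    else:
        prevalent = "none"
    n_ud, n_du = count_transitions(states, min_dwell=min_dwell)
    return states, GatingSummary(
        fraction_down=frac_down, prevalent=prevalent,
        n_up_to_down=n_ud, n_down_to_up=n_du,
    )


def joint_label(summary_ab: GatingSummary, summary_ba: GatingSummary) -> str:
    """Joint prevalent-state label of the two interfaces, A-side first."""
    return f"{summary_ab.prevalent}/{summary_ba.prevalent}"


def count_transitions(states: np.ndarray, min_dwell: int = 1) -> tuple[int, int]:
    """Count up->down and down->up transitions with a dwell-time debounce.

    A state change only counts if the new state persists for at least
    ``min_dwell`` frames; shorter blips are ignored.  With
    ``min_dwell=1`` every change counts.
    """
    s = np.asarray(states)
    if min_dwell < 1:
        raise GatingError("min_dwell must be >= 1")
    # run-length encode, then drop runs shorter than min_dwell
    change = np.nonzero(s[1:] != s[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(s)]])
    runs = [
        (s[b], e - b) for b, e in zip(starts, ends) if (e - b) >= min_dwell
    ]
    n_ud = n_du = 0
    for (prev, _), (cur, _) in zip(runs, runs[1:]):
        if prev == cur:
            continue
        if prev == "up" and cur == "down":
            n_ud += 1
        elif prev == "down" and cur == "up":
            n_du += 1
    return n_ud, n_du


def distribution_mode(
    distances: np.ndarray,
    bandwidth: float | None = None,
    grid_step: float = 0.05,
    rel_height: float = 0.1,
) -> list[float]:
    """Modes of a distance distribution via Gaussian kernel density.

    The density is evaluated on a ``grid_step`` grid; all local maxima
    above ``rel_height`` of the global peak are returned ordered by
    height (global mode first).  Bandwidth defaults to Silverman's rule.
    A constant series trivially has its single value as the mode.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise GatingError("distance series must be a non-empty 1-D array")
    if np.ptp(d) < 1e-12:
        return [float(d[0])]
    kde = gaussian_kde(d, bw_method="silverman" if bandwidth is None else None)
    if bandwidth is not None:
        kde.set_bandwidth(bandwidth / d.std(ddof=1))
    pad = 3.0 * d.std(ddof=1)
    grid = np.arange(d.min() - pad, d.max() + pad + grid_step, grid_step)
    dens = kde(grid)
    interior = np.nonzero(
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    )[0] + 1
    peak = dens.max()
    maxima = [(dens[i], grid[i]) for i in interior if dens[i] >= rel_height * peak]
    maxima.sort(key=lambda t: -t[0])
    # merge plateau duplicates closer than one grid step
    out: list[float] = []
    for _, x in maxima:
        if all(abs(x - y) > grid_step for y in out):
            out.append(float(x))
    return out


def lipid_cavity_flag(
    distances: np.ndarray,
    lipid: str = "lipid",
    cutoff: float = CAVITY_CUTOFF,
    fraction_rule: float = 0.5,
) -> LipidOccupancy:
    """Apply the cavity-occupancy rule to a headgroup distance series.

    The lipid is flagged iff the fraction of frames with distance
    strictly below ``cutoff`` strictly exceeds ``fraction_rule``.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise GatingError("distance series must be a non-empty 1-D array")
    frac = float((d < cutoff).mean())
    return LipidOccupancy(lipid=lipid, fraction_below=frac,
                          in_cavity=frac > fraction_rule)


def lipid_atom_profile(
    distances_by_atom: dict[str, np.ndarray],
    atom_names: Sequence[str] = DEFAULT_LIPID_ATOMS,
    bin_width: float = 0.5,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Histograms of per-atom in-plane distances (0.5 Angstrom bins).

    ``distances_by_atom`` maps atom names to their distance series (as
    produced by the xy-distance featurizer for a single lipid).  Returns
    ``{atom: (bin_edges, counts)}``; a requested atom missing from the
    input is an error naming it.
    """
    out = {}
    for name in atom_names:
        if name not in distances_by_atom:
            raise GatingError(f"lipid atom {name!r} missing from the input series")
        d = np.asarray(distances_by_atom[name], dtype=float)
        hi = np.ceil(d.max() / bin_width) * bin_width + bin_width
        edges = np.arange(0.0, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(d, bins=edges)
        out[name] = (edges, counts)
    return out
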