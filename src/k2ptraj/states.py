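"""Conformational-state classification of the selectivity filter.

The low-dimensional sketch-map projection is partitioned with DBSCAN;
each cluster is then given a chemical identity from the carbonyl-flip
signatures of its member frames.  A flip signature records which ion
coordination-site boundaries (S4-S3, S3-S2, S2-S1, S1-S0) are disrupted
by a backbone carbonyl rotated away from the pore axis, and on which
subunit.  The recurring states carry the conventional names:

========  =============================================
state     flipped boundaries
========  =============================================
I         none (native, conductive filter)
II / II'  single S4-S3 flip on subunit A / B
III       single S3-S2 flip
IV        single S2-S1 flip
V         S4-S3 and S3-S2
VI        S3-S2 and S1-S0
VII       S3-S2, S2-S1 and S1-S0
other     anything else, plus DBSCAN noise frames
========  =============================================
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import KDTree

from .io import Trajectory
from .features import SFSelection, sf_axis_origin

__all__ = [
    "DBSCANParams",
    "dbscan",
    "classify_flips",
    "label_states",
    "population_table",
    "sum_states",
    "BOUNDARIES",
    "DEFAULT_BOUNDARY_MAP",
    "STATE_VOCABULARY",
]

BOUNDARIES = ("S4-S3", "S3-S2", "S2-S1", "S1-S0")

# residue position within the 5-residue filter motif -> site boundary
# (KcsA-like assignment; configurable because the structural mapping of
# glycine flips in K2P filters is debated)
DEFAULT_BOUNDARY_MAP = {0: "S4-S3", 1: "S3-S2", 2: "S2-S1", 3: "S1-S0"}


class StateError(ValueError):
    """Raised for invalid clustering or classification inputs."""


@dataclass(frozen=True)
class DBSCANParams:
    """DBSCAN settings plus the low-d analysis window.

    ``min_points`` counts the point itself (the common convention: with
    min_points = 3 a core point needs 2 neighbours within ``eps``).
    Points outside the rectangular window are labelled noise before
    clustering.
    """

    eps: float = 0.8
    min_points: int = 3
    window: tuple[tuple[float, float], tuple[float, float]] = ((-60.0, 60.0), (-60.0, 60.0))

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise StateError("eps must be > 0")
        if self.min_points < 1:
            raise StateError("min_points must be >= 1")


def dbscan(points: np.ndarray, params: DBSCANParams) -> np.ndarray:
    """Cluster 2-D points; returns per-point ids with -1 for noise.

    Standard DBSCAN semantics: a point is *core* when its eps-ball holds
    at least ``min_points`` points (itself included); clusters are the
    connected components of core points under the eps relation; a
    non-core point within eps of a core point is a border point of that
    cluster (ties go to the first-discovered cluster, i.e. the one with
    the smallest id); the rest is noise (-1).  Frames outside the
    analysis window never enter the clustering and are labelled -1.

    The implementation is grid-accelerated: core connectivity is
    resolved through cells of side eps/sqrt(2) (all points sharing a
    cell are mutually within eps), so dense near-duplicate clouds — the
    typical shape of a metastable state in a sketch-map — never require
    materializing quadratic neighbour lists.  Cluster ids are assigned
    by ascending lowest member index, making the result deterministic
    for a fixed point order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise StateError("points must be (n, 2)")
    if not np.all(np.isfinite(pts)):
        raise StateError("points must be finite")
    (x0, x1), (y0, y1) = params.window
    inside = (
        (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
        & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
    )
    labels = np.full(len(pts), -1, dtype=int)
    if inside.sum() == 0:
        return labels
    labels[inside] = _dbscan_core(pts[inside], params.eps, params.min_points)
    return labels


def _dbscan_core(pts: np.ndarray, eps: float, min_points: int) -> np.ndarray:
    n = len(pts)
    tree = KDTree(pts)
    counts = tree.query_radius(pts, r=eps, count_only=True)
    core = counts >= min_points
    core_idx = np.nonzero(core)[0]
    labels = np.full(n, -1, dtype=int)
    if core_idx.size == 0:
        return labels

    # union-find over core points
    parent = np.arange(n)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # cells of side eps/sqrt(2): any two points in one cell are within eps
    side = eps / np.sqrt(2.0)
    cell_of = np.floor(pts[core_idx] / side).astype(np.int64)
    cells: dict[tuple, np.ndarray] = {}
    order = np.lexsort((cell_of[:, 1], cell_of[:, 0]))
    sorted_cells = cell_of[order]
    boundaries = np.nonzero(np.any(np.diff(sorted_cells, axis=0) != 0, axis=1))[0] + 1
    for group in np.split(core_idx[order], boundaries):
        key = tuple(cell_of[np.searchsorted(core_idx, group[0])])
        cells[key] = np.sort(group)
        for other in group[1:]:
            union(int(group[0]), int(other))

    # link neighbouring cells when any cross pair of cores is within eps
    reach = int(np.ceil(np.sqrt(2.0)))  # eps spans sqrt(2) cells
    offsets = [
        (dx, dy)
        for dx in range(-reach, reach + 1)
        for dy in range(-reach, reach + 1)
        if (dx, dy) > (0, 0)  # each unordered cell pair once
    ]
    for key, members in cells.items():
        a = pts[members]
        for dx, dy in offsets:
            nb = (key[0] + dx, key[1] + dy)
            if nb not in cells:
                continue
            other = cells[nb]
            if find(int(members[0])) == find(int(other[0])):
                continue
            b = pts[other]
            if len(a) * len(b) <= 4096:
                d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
                linked = d2.min() <= eps * eps
            else:
                small, big = (a, b) if len(a) <= len(b) else (b, a)
                dist, _ = KDTree(big).query(small, k=1)
                linked = dist.min() <= eps
            if linked:
                union(int(members[0]), int(other[0]))

    # cluster ids by ascending root index (first-discovered ordering)
    roots = np.array([find(int(i)) for i in core_idx])
    ids: dict[int, int] = {}
    for root in roots:
        if root not in ids:
            ids[root] = len(ids)
    labels[core_idx] = [ids[r] for r in roots]

    # border points: first-discovered (smallest-id) adjacent core cluster
    noncore = np.nonzero(~core)[0]
    if noncore.size:
        core_tree = KDTree(pts[core_idx])
        chunk = max(1, int(1e6) // max(1, core_idx.size))
        for start in range(0, noncore.size, chunk):
            block = noncore[start:start + chunk]
            hits = core_tree.query_radius(pts[block], r=eps)
            for j, nb in zip(block, hits):
                if nb.size:
                    labels[j] = labels[core_idx[nb]].min()
    return labels


# ---------------------------------------------------------------------------
# Carbonyl-flip classification
# ---------------------------------------------------------------------------

def classify_flips(
    traj: Trajectory,
    sel: SFSelection,
    frame: int = 0,
    boundary_map: dict[int, str] | None = None,
) -> frozenset:
    """Flip signature of one frame: set of (chain_id, boundary) pairs.

    A residue's carbonyl is *flipped* iff the in-plane component of its
    C->O vector points away from the pore axis — i.e. the inward radial
    cosine (dot product of the unit C->O vector's xy part with the unit
    vector from C toward the axis) is strictly negative.  A carbonyl
    exactly tangential to the pore (cosine 0) is therefore not flipped.
    Only the four flip-capable residues per P-loop (motif positions 0-3)
    are examined; each maps to a boundary via ``boundary_map``.
    """
    bmap = DEFAULT_BOUNDARY_MAP if boundary_map is None else boundary_map
    index = traj.atom_index()
    origin = sf_axis_origin(traj, sel)[frame]
    signature = set()
    for loop in sel.ploops:
        for pos, res in enumerate(loop.residues):
            if pos not in bmap:
                continue
            try:
                c_idx = index[(loop.chain_id, res, "C")]
                o_idx = index[(loop.chain_id, res, "O")]
            except KeyError as exc:
                raise StateError(
                    f"missing carbonyl atom for chain {loop.chain_id}, residue {res}"
                ) from exc
            c = traj.frames[frame, c_idx]
            o = traj.frames[frame, o_idx]
            co = (o - c)[:2]
            if np.linalg.norm(co) < 1e-9:
                raise StateError(
                    f"degenerate C->O vector at chain {loop.chain_id}, residue {res}"
                )
            toward_axis = (origin - c)[:2]
            n = np.linalg.norm(toward_axis)
            if n < 1e-9:
                raise StateError(
                    f"carbonyl carbon on the pore axis at chain {loop.chain_id}, "
                    f"residue {res}: inward direction undefined"
                )
            cosine = float(np.dot(co / np.linalg.norm(co), toward_axis / n))
            if cosine < 0.0:
                signature.add((loop.chain_id, bmap[pos]))
    return frozenset(signature)


# ---------------------------------------------------------------------------
# State labelling and populations
# ---------------------------------------------------------------------------

STATE_VOCABULARY = ("I", "II", "II'", "III", "IV", "V", "VI", "VII", "other")


def _signature_label(sig: frozenset, subunit_a: str = "A", subunit_b: str = "B") -> str:
    """Map one flip signature to the I-VII vocabulary, else 'other'."""
    if not sig:
        return "I"
    boundaries = sorted({b for _, b in sig})
    chains = sorted({c for c, _ in sig})
    if boundaries == ["S4-S3"] and len(sig) == 1:
        chain = chains[0]
        if chain == subunit_a:
            return "II"
        if chain == subunit_b:
            return "II'"
        return "other"
    if len(sig) == len(boundaries) == 1 and boundaries == ["S3-S2"]:
        return "III"
    if len(sig) == len(boundaries) == 1 and boundaries == ["S2-S1"]:
        return "IV"
    if boundaries == ["S3-S2", "S4-S3"]:
        return "V"
    if boundaries == ["S1-S0", "S3-S2"]:
        return "VI"
    if boundaries == ["S1-S0", "S2-S1", "S3-S2"]:
        return "VII"
    return "other"


def label_states(
    cluster_ids: np.ndarray,
    signatures: list[frozenset],
    subunit_a: str = "A",
    subunit_b: str = "B",
) -> np.ndarray:
    """Per-frame state labels from cluster membership and flip signatures.

    Each cluster is labelled by the modal flip signature of its member
    frames (ties broken toward the signature with fewer flips — i.e.
    conservatively toward the native state); that signature is then
    mapped into the I-VII vocabulary.  Noise frames (-1) are 'other'.
    """
    cluster_ids = np.asarray(cluster_ids)
    if len(cluster_ids) != len(signatures):
        raise StateError("cluster_ids and signatures must align per frame")
    labels = np.full(len(cluster_ids), "other", dtype=object)
    for cid in np.unique(cluster_ids):
        if cid == -1:
            continue
        members = np.nonzero(cluster_ids == cid)[0]
        counts = Counter(signatures[i] for i in members)
        top = max(counts.values())
        modal = min(
            (sig for sig, c in counts.items() if c == top),
            key=lambda s: (len(s), sorted(s)),
        )
        labels[members] = _signature_label(modal, subunit_a, subunit_b)
    return labels.astype(str)


def population_table(traces: dict[str, np.ndarray]) -> pd.DataFrame:
    """Relative state populations (%) per condition.

    Percentages are taken over *all* frames of each condition, so noise
    and unmatched frames contribute to the 'other' column and every row
    sums to 100 within rounding.
    """
    rows = {}
    for condition, labels in traces.items():
        labels = np.asarray(labels, dtype=str)
        n = len(labels)
        if n == 0:
            raise StateError(f"condition {condition!r} has no frames")
        rows[condition] = {
            state: 100.0 * np.count_nonzero(labels == state) / n
            for state in STATE_VOCABULARY
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(STATE_VOCABULARY)]


def sum_states(table: pd.DataFrame, states: list[str], condition: str) -> float:
    """Sum of the named state populations (%) for one condition."""
    if not states:
        return 0.0
    return float(table.loc[condition, list(states)].sum())
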