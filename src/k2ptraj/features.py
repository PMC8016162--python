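"""Coordinate featurization for selectivity-filter (SF) analysis.

The SF of a K2P channel is built from four P-loops (two per subunit) of
five residues each, following the T-x-G-x-G motif of canonical potassium
channels.  Its conformation is summarised by 44 torsions: the backbone
phi/psi of all 20 filter residues plus the chi1 angle of the four
threonines whose side-chain hydroxyl forms the bottom (S4) ion site.

Angles are reported in degrees in ``(-180, 180]`` (ties at the branch cut
map to +180) with the IUPAC sign convention.  The pore axis is the z-axis
of the frame after centering on the SF backbone centroid; the membrane
plane is xy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io import Trajectory

__all__ = [
    "PLoop",
    "SFSelection",
    "canonical_sf_selection",
    "dihedral",
    "extract_sf_dihedrals",
    "dihedral_column_labels",
    "sincos_expand",
    "sf_backbone_rmsd",
    "sf_axis_origin",
    "axial_coordinate",
    "xy_distance",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class FeaturizationError(ValueError):
    """Raised when a required atom or selection element is missing."""


@dataclass(frozen=True)
class PLoop:
    """One pore loop: a 5-residue filter stretch on a chain."""

    chain_id: str
    first_res: int
    last_res: int
    thr_res: int

    def __post_init__(self) -> None:
        if self.last_res - self.first_res != 4:
            raise FeaturizationError(
                f"P-loop {self.chain_id}:{self.first_res}-{self.last_res} must "
                "span exactly 5 residues"
            )

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(range(self.first_res, self.last_res + 1))


@dataclass(frozen=True)
class SFSelection:
    """The four P-loops forming the selectivity filter."""

    ploops: tuple[PLoop, ...]

    def __post_init__(self) -> None:
        if len(self.ploops) != 4:
            raise FeaturizationError(
                f"an SF selection needs exactly 4 P-loops, got {len(self.ploops)}"
            )


def canonical_sf_selection(
    chain_ids: Sequence[str] = ("A", "A", "B", "B"),
    first_residues: Sequence[int] = (129, 238, 129, 238),
) -> SFSelection:
    """The TRAAK-like default: P1 (Thr129...) and P2 (Thr238...) on each subunit."""
    ploops = tuple(
        PLoop(chain_id=c, first_res=r, last_res=r + 4, thr_res=r)
        for c, r in zip(chain_ids, first_residues, strict=True)
    )
    return SFSelection(ploops=ploops)


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4, *, _eps: float = 1e-9) -> float:
    """Torsion angle of four points, degrees in ``(-180, 180]``.

    Sign follows the IUPAC convention (clockwise positive when looking
    from p2 toward p3).  Raises for coincident consecutive points or a
    collinear central geometry, where the torsion is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for name, b in (("p1-p2", b1), ("p2-p3", b2), ("p3-p4", b3)):
        if np.linalg.norm(b) < _eps:
            raise FeaturizationError(f"coincident consecutive points ({name})")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < _eps * nb2 or np.linalg.norm(n2) < _eps * nb2:
        raise FeaturizationError("collinear points: dihedral undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = np.degrees(np.arctan2(y, x))
    return wrap_degrees(ang)


def wrap_degrees(a):
    """Wrap degrees to ``(-180, 180]``; -180 maps to +180."""
    wrapped = -np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) + 180.0
    if np.ndim(wrapped) == 0:
        return float(wrapped)
    return wrapped


def dihedral_column_labels(sel: SFSelection) -> list[tuple[str, int, str]]:
    """Canonical (chain, residue, kind) order of the 44 dihedral columns.

    P-loop-major; within a loop phi/psi per residue from the N-terminal
    (S4) end to the C-terminal (S0) end, then the threonine chi1.
    """
    labels: list[tuple[str, int, str]] = []
    for loop in sel.ploops:
        for res in loop.residues:
            labels.append((loop.chain_id, res, "phi"))
            labels.append((loop.chain_id, res, "psi"))
        labels.append((loop.chain_id, loop.thr_res, "chi1"))
    return labels


def extract_sf_dihedrals(traj: Trajectory, sel: SFSelection) -> np.ndarray:
    """Per-frame 44-column dihedral matrix (degrees) for the SF selection.

    phi of the first filter residue uses the preceding residue's carbonyl
    carbon, which must be present; psi of the last residue likewise needs
    the following residue's amide nitrogen.  A missing atom is an error
    naming the (chain, residue, atom) triple — the 44-column contract is
    rigid.
    """
    index = traj.atom_index()

    def pos(chain: str, res: int, name: str) -> np.ndarray:
        key = (chain, res, name)
        if key not in index:
            raise FeaturizationError(
                f"missing atom: chain {chain}, residue {res}, atom {name}"
            )
        return traj.frames[:, index[key], :]

    quads: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for loop in sel.ploops:
        c = loop.chain_id
        for res in loop.residues:
            quads.append((pos(c, res - 1, "C"), pos(c, res, "N"),
                          pos(c, res, "CA"), pos(c, res, "C")))      # phi
            quads.append((pos(c, res, "N"), pos(c, res, "CA"),
                          pos(c, res, "C"), pos(c, res + 1, "N")))   # psi
        t = loop.thr_res
        quads.append((pos(c, t, "N"), pos(c, t, "CA"),
                      pos(c, t, "CB"), pos(c, t, "OG1")))            # chi1
    n_frames = traj.n_frames
    out = np.empty((n_frames, len(quads)))
    for j, (a, b, cpos, d) in enumerate(quads):
        out[:, j] = _dihedral_series(a, b, cpos, d)
    return out


def _dihedral_series(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized torsion over frames; same convention as :func:`dihedral`."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    if np.any(nb2 < 1e-9):
        raise FeaturizationError("coincident consecutive points in a frame")
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / nb2
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def sincos_expand(angles_deg: np.ndarray) -> np.ndarray:
    """Expand an angle matrix to interleaved (sin, cos) columns.

    Column order: sin(a1), cos(a1), sin(a2), cos(a2), ...  This removes
    the branch cut at +/-180 degrees before PCA.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    out = np.empty((a.shape[0], 2 * a.shape[1]))
    out[:, 0::2] = np.sin(a)
    out[:, 1::2] = np.cos(a)
    return out


# ---------------------------------------------------------------------------
# RMSD and axis-based coordinates
# ---------------------------------------------------------------------------

def _backbone_indices(traj: Trajectory, sel: SFSelection) -> list[int]:
    index = traj.atom_index()
    idx = []
    for loop in sel.ploops:
        for res in loop.residues:
            for name in BACKBONE_ATOMS:
                key = (loop.chain_id, res, name)
                if key not in index:
                    raise FeaturizationError(
                        f"missing atom: chain {loop.chain_id}, residue {res}, atom {name}"
                    )
                idx.append(index[key])
    return idx


def sf_backbone_rmsd(
    traj: Trajectory,
    sel: SFSelection,
    reference_frame: int = 0,
    reference_coords: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) of the SF backbone after optimal superposition.

    Each frame is rigidly fitted (Kabsch rotation + translation) onto the
    reference before the deviation is evaluated, so the series reports
    internal deformation of the filter, not rigid-body motion.  The
    reference defaults to the trajectory's first frame.
    """
    idx = _backbone_indices(traj, sel)
    coords = traj.frames[:, idx, :]
    if reference_coords is None:
        ref = coords[reference_frame]
    else:
        ref = np.asarray(reference_coords, dtype=float)
        if ref.shape != coords.shape[1:]:
            raise FeaturizationError(
                f"reference has shape {ref.shape}, expected {coords.shape[1:]}"
            )
    ref_centered = ref - ref.mean(axis=0)
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        mob = coords[i] - coords[i].mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mob)
        diff = rot.apply(mob) - ref_centered
        out[i] = np.sqrt((diff ** 2).sum() / len(idx))
    return out


def sf_axis_origin(traj: Trajectory, sel: SFSelection) -> np.ndarray:
    """Per-frame centroid of the SF backbone: the pore-axis origin."""
    idx = _backbone_indices(traj, sel)
    return traj.frames[:, idx, :].mean(axis=1)


def _atom_positions(traj: Trajectory, atoms: Sequence[tuple[str, int, str]]) -> np.ndarray:
    index = traj.atom_index()
    cols = []
    for key in atoms:
        if tuple(key) not in index:
            raise FeaturizationError(
                f"missing atom: chain {key[0]}, residue {key[1]}, atom {key[2]}"
            )
        cols.append(index[tuple(key)])
    return traj.frames[:, cols, :]


def axial_coordinate(
    traj: Trajectory,
    atoms: Sequence[tuple[str, int, str]],
    sel: SFSelection,
) -> np.ndarray:
    """z of the named atoms along the pore axis, origin at the SF centroid.

    Positive z points extracellular (above the filter).  Shape:
    (n_frames, n_atoms).  Rigid translations of the whole system cancel.
    """
    origin = sf_axis_origin(traj, sel)
    pos = _atom_positions(traj, atoms)
    return pos[:, :, 2] - origin[:, None, 2]


def xy_distance(
    traj: Trajectory,
    atoms: Sequence[tuple[str, int, str]],
    sel: SFSelection,
) -> np.ndarray:
    """In-plane (membrane-plane) distance of atoms from the pore axis.

    Shape: (n_frames, n_atoms); invariant under rigid z-translation.
    """
    origin = sf_axis_origin(traj, sel)
    pos = _atom_positions(traj, atoms)
    d = pos[:, :, :2] - origin[:, None, :2]
    return np.sqrt((d ** 2).sum(axis=2))
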