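"""Data model and file I/O for the analysis pipeline.

Internal unit conventions, used consistently by every module:

* coordinates and distances in Angstrom (XTC files store nm and are
  converted on read/write),
* times in nanoseconds; replica durations in microseconds, matching the
  usual bookkeeping of microsecond-scale simulation campaigns
  (:func:`us_to_ns` is the single conversion point),
* angles in degrees in the half-open interval ``(-180, 180]``.

Structures are exchanged as PDB (via gemmi), trajectories as DCD or XTC
(via MDAnalysis), per-frame feature series as plain CSV, and the replica
registry as YAML.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AtomRecord",
    "Trajectory",
    "ReplicaMeta",
    "FeatureTable",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_feature_table",
    "write_feature_table",
    "load_replica_registry",
    "total_duration_us",
    "us_to_ns",
]

NS_PER_US = 1000.0


def us_to_ns(duration_us: float) -> float:
    """Convert a duration in microseconds to nanoseconds."""
    return duration_us * NS_PER_US


class StructureError(ValueError):
    """Raised for unreadable or invalid structure files."""


class TrajectoryError(ValueError):
    """Raised for unreadable, truncated or mismatched trajectory files."""


class FeatureTableError(ValueError):
    """Raised for invalid feature tables."""


class RegistryError(ValueError):
    """Raised for malformed replica registries."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, in the author numbering of the input PDB."""

    atom_name: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: tuple[float, float, float]

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.atom_name)


@dataclass
class Trajectory:
    """A fixed atom table plus per-frame coordinates in Angstrom.

    ``frames`` has shape (n_frames, n_atoms, 3); ``frame_interval`` is the
    time between stored frames in ns; ``box`` optionally holds per-frame
    orthorhombic box lengths (n_frames, 3) in Angstrom.
    """

    atom_table: list[AtomRecord]
    frames: np.ndarray
    frame_interval: float = 1.0
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError(
                f"frames must have shape (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise TrajectoryError("a trajectory needs at least one frame")
        if self.frames.shape[1] != len(self.atom_table):
            raise TrajectoryError(
                f"coordinate array has {self.frames.shape[1]} atoms but the atom "
                f"table lists {len(self.atom_table)}"
            )
        if not self.frame_interval > 0:
            raise TrajectoryError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def atom_index(self) -> dict[tuple[str, int, str], int]:
        """Map (chain_id, residue_index, atom_name) to column position."""
        return {a.key(): i for i, a in enumerate(self.atom_table)}

    def times(self) -> np.ndarray:
        """Frame times in ns, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class ReplicaMeta:
    """Bookkeeping for one simulation run of the campaign design."""

    force_field: str
    init_config: str  # "KK" or "KWK"
    voltage_mV: float
    replica: int
    duration_us: float
    paths: dict = field(default_factory=dict, hash=False, compare=False)
    n_events: int | None = None

    def __post_init__(self) -> None:
        if self.init_config not in ("KK", "KWK"):
            raise RegistryError(
                f"init_config must be 'KK' or 'KWK', got {self.init_config!r}"
            )
        if not self.duration_us > 0:
            raise RegistryError("duration_us must be positive")


class FeatureTable:
    """Named per-frame numeric series on a strictly increasing time axis.

    A thin wrapper over a pandas DataFrame with a mandatory ``time_ns``
    column; angles are stored in degrees, distances in Angstrom,
    occupancies as counts.
    """

    TIME = "time_ns"

    def __init__(self, times: Sequence[float], columns: dict[str, Sequence[float]]):
        times = np.asarray(times, dtype=float)
        if times.ndim != 1:
            raise FeatureTableError("times must be one-dimensional")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise FeatureTableError("times must be strictly increasing")
        data = {self.TIME: times}
        for name, series in columns.items():
            series = np.asarray(series, dtype=float)
            if series.shape != times.shape:
                raise FeatureTableError(
                    f"column {name!r} has length {len(series)}, expected {len(times)}"
                )
            data[name] = series
        self._df = pd.DataFrame(data)

    @property
    def times(self) -> np.ndarray:
        return self._df[self.TIME].to_numpy()

    @property
    def column_names(self) -> list[str]:
        return [c for c in self._df.columns if c != self.TIME]

    def __getitem__(self, name: str) -> np.ndarray:
        return self._df[name].to_numpy()

    def __len__(self) -> int:
        return len(self._df)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        if cls.TIME not in df.columns:
            raise FeatureTableError(f"missing {cls.TIME!r} column")
        cols = {c: df[c].to_numpy() for c in df.columns if c != cls.TIME}
        return cls(df[cls.TIME].to_numpy(), cols)


# ---------------------------------------------------------------------------
# Structures (PDB via gemmi)
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> list[AtomRecord]:
    """Read ATOM/HETATM records from a PDB file into an atom table.

    Atom order, chain ids and author residue numbering are preserved.
    Insertion codes are rejected: the pipeline's residue references
    (Thr129, Pro155, Ile279, ...) assume plain author numbers.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such structure file: {path}")
    _prevalidate_pdb_lines(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no model found")
    atoms: list[AtomRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for chain in st[0]:
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise StructureError(
                    f"{path}: insertion code {res.seqid.icode!r} at "
                    f"{chain.name}/{res.name}{res.seqid.num} is not supported"
                )
            for atom in res:
                rec = AtomRecord(
                    atom_name=atom.name,
                    residue_name=res.name,
                    residue_index=res.seqid.num,
                    chain_id=chain.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                )
                if not all(np.isfinite(rec.position)):
                    raise StructureError(
                        f"{path}: non-finite coordinate for {rec.key()}"
                    )
                if rec.key() in seen:
                    raise StructureError(
                        f"{path}: duplicate atom (chain {rec.chain_id}, residue "
                        f"{rec.residue_index}, atom {rec.atom_name})"
                    )
                seen.add(rec.key())
                atoms.append(rec)
    if not atoms:
        raise StructureError(f"{path}: structure contains no atoms")
    return atoms


def _prevalidate_pdb_lines(path: Path) -> None:
    """Check fixed-column fields of ATOM/HETATM lines before parsing.

    gemmi is tolerant of damaged records; this pass gives the line-numbered
    error the pipeline's contracts require.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureError(
                    f"{path}:{lineno}: truncated ATOM/HETATM record"
                )
            try:
                int(line[22:26])
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise StructureError(
                    f"{path}:{lineno}: malformed ATOM/HETATM record ({exc})"
                ) from None


def write_structure(atoms: Iterable[AtomRecord], path: str | Path) -> None:
    """Write an atom table as a single-model PDB file (3-decimal coords)."""
    atoms = list(atoms)
    if not atoms:
        raise StructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = "k2ptraj"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple[str, int], gemmi.Residue] = {}
    for rec in atoms:
        if rec.chain_id not in chain_map:
            chain = gemmi.Chain(rec.chain_id)
            model.add_chain(chain)
            chain_map[rec.chain_id] = model[-1]
        chain = chain_map[rec.chain_id]
        rkey = (rec.chain_id, rec.residue_index)
        if rkey not in res_map:
            res = gemmi.Residue()
            res.name = rec.residue_name
            res.seqid = gemmi.SeqId(rec.residue_index, " ")
            chain.add_residue(res)
            res_map[rkey] = chain[-1]
        res = res_map[rkey]
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.pos = gemmi.Position(*rec.position)
        atom.element = gemmi.Element(_guess_element(rec.atom_name))
        res.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] in "CNOSHPK":
        return stripped[0]
    return stripped[:2].capitalize()


# ---------------------------------------------------------------------------
# Trajectories (DCD / XTC via MDAnalysis)
# ---------------------------------------------------------------------------

def read_trajectory(
    structure: list[AtomRecord],
    path: str | Path,
    frame_interval: float | None = None,
) -> Trajectory:
    """Read a DCD or XTC trajectory against a known atom table.

    Coordinates are returned in Angstrom regardless of the on-disk unit
    (MDAnalysis converts XTC's nm). ``frame_interval`` (ns) overrides the
    interval recorded in the file; if neither is available it defaults to
    1 ns per frame.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"no such trajectory file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        reader_cls = mda.coordinates.DCD.DCDReader
    elif suffix == ".xtc":
        reader_cls = mda.coordinates.XTC.XTCReader
    else:
        raise TrajectoryError(f"unsupported trajectory format: {suffix!r}")
    try:
        reader = reader_cls(str(path))
    except Exception as exc:  # unreadable/corrupt header
        raise TrajectoryError(f"{path}: cannot open trajectory ({exc})") from exc
    with reader:
        if reader.n_atoms != len(structure):
            raise TrajectoryError(
                f"{path}: trajectory has {reader.n_atoms} atoms but the "
                f"structure has {len(structure)}"
            )
        frames = []
        boxes = []
        try:
            for ts in reader:
                frames.append(ts.positions.astype(float).copy())
                if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
                    boxes.append(ts.dimensions[:3].astype(float).copy())
        except Exception as exc:
            raise TrajectoryError(f"{path}: error while reading frames ({exc})") from exc
        file_dt_ps = getattr(reader, "dt", None)
    if suffix == ".dcd":
        declared = _dcd_declared_frames(path)
        if declared is not None and declared > 0 and declared != len(frames):
            raise TrajectoryError(
                f"{path}: header declares {declared} frames but only "
                f"{len(frames)} could be read (truncated file?)"
            )
    if not frames:
        raise TrajectoryError(f"{path}: trajectory contains no frames")
    if frame_interval is None:
        # MDAnalysis reports dt in ps
        frame_interval = float(file_dt_ps) / 1000.0 if file_dt_ps else 1.0
    box = np.array(boxes) if len(boxes) == len(frames) else None
    return Trajectory(
        atom_table=list(structure),
        frames=np.array(frames),
        frame_interval=frame_interval,
        box=box,
    )


def _dcd_declared_frames(path: Path) -> int | None:
    """Frame count declared in the DCD header (nset), or None."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(12)
        if len(head) < 12 or head[4:8] != b"CORD":
            return None
        return struct.unpack("<i", head[8:12])[0]
    except OSError:
        return None


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as DCD or XTC (chosen by file extension)."""
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    # MDAnalysis writer dt is in ps
    with mda.Writer(str(path), traj.n_atoms, dt=traj.frame_interval * 1000.0) as w:
        for i in range(traj.n_frames):
            u.atoms.positions = traj.frames[i].astype(np.float32)
            if traj.box is not None:
                u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
            else:
                u.dimensions = [0.0, 0.0, 0.0, 90.0, 90.0, 90.0]
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# Feature tables (CSV)
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as comma-separated UTF-8 CSV with a header."""
    table.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table CSV; rejects non-monotone time columns."""
    path = Path(path)
    if not path.exists():
        raise FeatureTableError(f"no such feature table: {path}")
    df = pd.read_csv(path)
    try:
        return FeatureTable.from_frame(df)
    except FeatureTableError as exc:
        raise FeatureTableError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Replica registry (YAML)
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("force_field", "init_config", "voltage_mV", "replica", "duration_us")


def load_replica_registry(path: str | Path) -> list[ReplicaMeta]:
    """Load a YAML run registry into a list of :class:`ReplicaMeta`.

    The file holds a top-level ``replicas`` list; each entry carries the
    five design fields plus optional ``paths`` (input file locations) and
    ``n_events`` (recorded conduction events, for bookkeeping analyses).
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"no such registry file: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return []
    if isinstance(doc, dict):
        runs = doc.get("replicas", [])
    elif isinstance(doc, list):
        runs = doc
    else:
        raise RegistryError(f"{path}: registry must be a mapping or a list")
    return parse_registry_entries(runs, origin=str(path))


def parse_registry_entries(runs: Sequence[dict], origin: str = "registry") -> list[ReplicaMeta]:
    metas = []
    for i, run in enumerate(runs):
        if not isinstance(run, dict):
            raise RegistryError(f"{origin}: run #{i + 1} is not a mapping")
        missing = [k for k in _REQUIRED_KEYS if k not in run]
        if missing:
            raise RegistryError(
                f"{origin}: run #{i + 1} is missing field(s) {', '.join(missing)}"
            )
        metas.append(
            ReplicaMeta(
                force_field=str(run["force_field"]),
                init_config=str(run["init_config"]),
                voltage_mV=float(run["voltage_mV"]),
                replica=int(run["replica"]),
                duration_us=float(run["duration_us"]),
                paths=dict(run.get("paths", {})),
                n_events=None if run.get("n_events") is None else int(run["n_events"]),
            )
        )
    return metas


def total_duration_us(registry: Iterable[ReplicaMeta]) -> float:
    """Total simulated time of a registry in microseconds."""
    return float(sum(r.duration_us for r in registry))
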