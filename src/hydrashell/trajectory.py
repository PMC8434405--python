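"""Core trajectory data model, periodic geometry, and standard-format I/O.

Internal units follow the GROMACS convention: lengths in nm, times in ps.
Structure/trajectory files (PDB, GRO, XTC, DCD) are parsed through MDAnalysis
and converted to nm at this boundary. Only orthorhombic periodic boxes are
supported; triclinic boxes are rejected loudly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnalysisError,
    FormatError,
    InputError,
    ParameterError,
    TopologyError,
    UnsupportedBoxError,
)

ANGSTROM_PER_NM = 10.0

#: single-bond covalent radii (nm) used by the distance bond-inference heuristic
COVALENT_RADII_NM = {
    "H": 0.031,
    "C": 0.076,
    "N": 0.071,
    "O": 0.066,
    "P": 0.107,
    "S": 0.105,
    "F": 0.057,
    "CL": 0.102,
    "NA": 0.155,
    "MG": 0.139,
    "K": 0.196,
    "CA": 0.171,
    "FE": 0.132,
    "ZN": 0.122,
}

#: residue names recognised as water
WATER_RESIDUE_NAMES = {"HOH", "SOL", "WAT", "TIP3", "TIP", "SPC", "T3P", "H2O"}


def guess_element(atom_name: str) -> str:
    """Guess the chemical element from a PDB/GRO atom name.

    Strips leading digits, then tries a two-letter match against the known
    radius table before falling back to the first letter.
    """
    name = atom_name.strip().upper().lstrip("0123456789")
    if not name:
        raise TopologyError(f"cannot infer element from atom name {atom_name!r}")
    if len(name) >= 2 and name[:2] in COVALENT_RADII_NM and name[:2] not in {"CA", "CL", "NA", "MG"}:
        return name[:2]
    # two-letter ions only when the full name is exactly the symbol (avoid CA=Calpha)
    if name in {"CL", "NA", "MG", "FE", "ZN"}:
        return name
    return name[0]


@dataclass
class Topology:
    """Static per-atom metadata shared by all frames of a trajectory.

    Atom indices are 0-based and contiguous. ``bonds`` is an (n_bonds, 2)
    integer array; hydrogen/donor/acceptor flags feed the hydrogen-bond
    machinery (donor = N/O with at least one bonded H, acceptor = N/O).
    """

    atom_name: np.ndarray
    element: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    molecule_id: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    donor_flag: np.ndarray | None = None
    acceptor_flag: np.ndarray | None = None
    hydrogen_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.residue_id = np.asarray(self.residue_id, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        n = self.n_atoms
        for attr in ("donor_flag", "acceptor_flag", "hydrogen_flag"):
            v = getattr(self, attr)
            if v is None:
                setattr(self, attr, np.zeros(n, dtype=bool))
            else:
                setattr(self, attr, np.asarray(v, dtype=bool))
        if self.hydrogen_flag.sum() == 0 and n:
            self.hydrogen_flag = self.element == "H"
        lengths = {len(self.atom_name), len(self.element), len(self.residue_id),
                   len(self.residue_name), len(self.molecule_id)}
        if lengths != {n}:
            raise TopologyError("per-atom arrays have inconsistent lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def neighbors(self, index: int) -> np.ndarray:
        """Indices bonded to ``index``."""
        b = self.bonds
        return np.concatenate([b[b[:, 0] == index, 1], b[b[:, 1] == index, 0]])

    def bonded_hydrogens(self, index: int) -> np.ndarray:
        nb = self.neighbors(index)
        return nb[self.hydrogen_flag[nb]]

    def water_molecules(self) -> list[tuple[int, int, int]]:
        """Return (O, H1, H2) atom-index triples for every 3-site water.

        A molecule is a water when its residue name is a known water label or
        its composition is exactly one oxygen and two hydrogens.
        """
        out: list[tuple[int, int, int]] = []
        for mol in np.unique(self.molecule_id):
            idx = np.flatnonzero(self.molecule_id == mol)
            elems = sorted(self.element[idx])
            named = str(self.residue_name[idx[0]]).upper() in WATER_RESIDUE_NAMES
            if elems == ["H", "H", "O"] and (named or len(idx) == 3):
                o = idx[self.element[idx] == "O"][0]
                h1, h2 = idx[self.element[idx] == "H"]
                out.append((int(o), int(h1), int(h2)))
        return out

    def water_oxygens(self) -> np.ndarray:
        return np.array([o for o, _, _ in self.water_molecules()], dtype=int)


@dataclass
class Frame:
    """One coordinate snapshot: positions (n_atoms, 3) in nm, box (3, 3) lattice
    vectors in nm (or None for non-periodic data), time in ps."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3, 3)
            if np.any(np.diag(self.box) <= 0):
                raise ParameterError("periodic box diagonal must be strictly positive")


class Trajectory:
    """A time-ordered stack of frames over one topology.

    Coordinates are stored as a dense (n_frames, n_atoms, 3) array; ``frames``
    materialises :class:`Frame` views on demand. Sampling must be uniform:
    frame times are checked to be strictly increasing and equally spaced
    (within 1e-6 ps).
    """

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        box: np.ndarray | None,
        times: np.ndarray,
        metadata: dict | None = None,
    ) -> None:
        self.topology = topology
        self.coordinates = np.asarray(coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ParameterError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != topology.n_atoms:
            raise FormatError(
                f"coordinate frames carry {self.coordinates.shape[1]} atoms but the "
                f"topology declares {topology.n_atoms}"
            )
        self.box = None if box is None else np.asarray(box, dtype=float).reshape(3, 3)
        self.times = np.asarray(times, dtype=float)
        if len(self.times) != self.n_frames:
            raise ParameterError("times length must equal the number of frames")
        if self.n_frames >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ParameterError("frame times must be strictly increasing")
            if np.max(steps) - np.min(steps) > 1e-6:
                raise ParameterError("frame times must be uniformly spaced (within 1e-6 ps)")
        self.metadata = dict(metadata or {})

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def dt(self) -> float:
        """Uniform sampling interval in ps (0 for single-frame data)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        """Total simulated time covered, ps."""
        return float(self.times[-1] - self.times[0])

    @property
    def frames(self) -> list[Frame]:
        return [Frame(self.coordinates[i], self.box, float(self.times[i]))
                for i in range(self.n_frames)]

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def _box_edges(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float).reshape(3, 3)
    off = box - np.diag(np.diag(box))
    if np.any(np.abs(off) > 1e-9):
        raise UnsupportedBoxError("only orthorhombic (diagonal) boxes are supported")
    edges = np.diag(box)
    if np.any(edges <= 0):
        raise ParameterError("box edges must be strictly positive")
    return edges


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Displacement b - a wrapped into [-L/2, L/2) per component.

    ``a`` and ``b`` broadcast; ``box`` is a (3, 3) orthorhombic lattice.
    """
    edges = _box_edges(box)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - edges * np.floor(d / edges + 0.5)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.linalg.norm(minimum_image_displacement(a, b, box), axis=-1)


def wrap_coordinates(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap positions into [0, L) per component."""
    edges = _box_edges(box)
    return coords - edges * np.floor(coords / edges)


def unwrap_coordinates(traj: Trajectory, selection: Sequence[int] | None = None) -> Trajectory:
    """Undo periodic wrapping so displacements are continuous in time.

    Frame-to-frame steps of the output equal the minimum-image steps of the
    input; the first frame is unchanged. Reliable only when no atom moves
    half a box edge or more per frame — steps suspiciously close to L/2
    trigger a warning listing the flagged atoms.
    """
    if traj.box is None:
        return traj
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    edges = _box_edges(traj.box)
    wrapped = traj.coordinates[:, sel, :]
    steps = minimum_image_displacement(wrapped[:-1], wrapped[1:], traj.box)
    suspicious = np.abs(steps) > 0.495 * edges
    if np.any(suspicious):
        flagged = sorted(set(sel[np.unique(np.nonzero(suspicious)[1])].tolist()))
        warnings.warn(
            f"per-frame displacement within 1% of half the box edge for atoms {flagged}; "
            "unwrapping is unreliable (undersampled trajectory?)",
            RuntimeWarning,
            stacklevel=2,
        )
    unwrapped = np.concatenate([wrapped[:1], wrapped[:1] + np.cumsum(steps, axis=0)], axis=0)
    coords = traj.coordinates.copy()
    coords[:, sel, :] = unwrapped
    meta = dict(traj.metadata)
    meta["unwrapped"] = True
    return Trajectory(traj.topology, coords, traj.box, traj.times, meta)


# ---------------------------------------------------------------------------
# bond / flag inference
# ---------------------------------------------------------------------------

def infer_bonds(coordinates: np.ndarray, elements: np.ndarray,
                box: np.ndarray | None = None, scale: float = 1.2) -> np.ndarray:
    """Distance-heuristic connectivity: i-j bonded when their separation is
    below ``scale`` times the sum of covalent radii. O(n^2); intended for the
    small systems this package is exercised on, not for full solvated boxes
    (those should come with connectivity records)."""
    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    n = len(coords)
    radii = np.array([COVALENT_RADII_NM.get(str(e).upper(), 0.077) for e in elements])
    pairs = []
    for i in range(n - 1):
        if box is not None:
            d = minimum_image_distance(coords[i], coords[i + 1:], box)
        else:
            d = np.linalg.norm(coords[i + 1:] - coords[i], axis=-1)
        cut = scale * (radii[i] + radii[i + 1:])
        hits = np.flatnonzero(d < cut) + i + 1
        # never bond two hydrogens
        for j in hits:
            if elements[i] == "H" and elements[j] == "H":
                continue
            pairs.append((i, int(j)))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def assign_donor_acceptor_flags(top: Topology) -> None:
    """Populate hydrogen/donor/acceptor flags in place.

    Heuristic: N and O are acceptors; N/O with at least one bonded hydrogen
    are donors. Requires bonds.
    """
    top.hydrogen_flag = top.element == "H"
    polar = (top.element == "N") | (top.element == "O")
    top.acceptor_flag = polar.copy()
    donor = np.zeros(top.n_atoms, dtype=bool)
    if len(top.bonds):
        for i, j in top.bonds:
            if polar[i] and top.hydrogen_flag[j]:
                donor[i] = True
            if polar[j] and top.hydrogen_flag[i]:
                donor[j] = True
    top.donor_flag = donor


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_trajectory(coordinate_path: str, trajectory_path: str | None = None) -> Trajectory:
    """Read a PDB/GRO structure, optionally with an XTC/DCD trajectory.

    Elements are inferred from atom names when the file carries none; bonds
    come from CONECT records when present, otherwise from the covalent-radius
    distance heuristic on the first frame. Donor/acceptor/hydrogen flags are
    assigned from elements and bonds.
    """
    import MDAnalysis as mda

    try:
        if trajectory_path is None:
            u = mda.Universe(str(coordinate_path))
        else:
            u = mda.Universe(str(coordinate_path), str(trajectory_path))
    except (OSError, ValueError, EOFError) as exc:
        raise FormatError(f"cannot read {coordinate_path!r}"
                          f"{' with ' + str(trajectory_path) if trajectory_path else ''}: {exc}") from exc

    names = np.array([a.name for a in u.atoms], dtype=object)
    elements = np.array([guess_element(n) for n in names], dtype=object)
    resids = np.array([a.resid for a in u.atoms], dtype=int)
    resnames = np.array([a.resname for a in u.atoms], dtype=object)
    # molecule ids: residue-based (sufficient for protein + waters without TPR)
    molecule_id = np.unique(resids, return_inverse=True)[1]

    frames = []
    boxes = []
    times = []
    try:
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float) / ANGSTROM_PER_NM)
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                lx, ly, lz, alpha, beta, gamma = ts.dimensions
                if max(abs(alpha - 90), abs(beta - 90), abs(gamma - 90)) > 1e-3:
                    raise UnsupportedBoxError("only orthorhombic boxes are supported")
                boxes.append(np.diag([lx, ly, lz]) / ANGSTROM_PER_NM)
            else:
                boxes.append(None)
            times.append(float(ts.time))
    except (OSError, EOFError, ValueError) as exc:
        raise FormatError(
            f"trajectory read failed at frame {len(frames)}: {exc}") from exc

    coords = np.stack(frames)
    box = boxes[0]
    times = np.asarray(times, dtype=float)
    if len(times) >= 2 and np.any(np.diff(times) <= 0):
        times = np.arange(len(frames), dtype=float)  # readers without time stamps

    if hasattr(u, "bonds") and len(getattr(u, "bonds", [])) > 0:
        bonds = np.array([[b[0].index, b[1].index] for b in u.bonds], dtype=int)
    else:
        bonds = infer_bonds(coords[0], elements, box)

    top = Topology(names, elements, resids, resnames, molecule_id, bonds)
    assign_donor_acceptor_flags(top)
    return Trajectory(top, coords, box, times,
                      metadata={"coordinate_path": str(coordinate_path),
                                "trajectory_path": None if trajectory_path is None else str(trajectory_path)})


def write_series(table: dict[str, Sequence] | pd.DataFrame, path: str,
                 fmt: str = "csv", metadata: dict | None = None) -> None:
    """Write a named-column table as CSV/TSV/JSON with a metadata header.

    CSV/TSV files start with ``#``-prefixed comment lines carrying the tool
    version and any metadata entries; JSON output nests the table under
    ``"columns"`` with metadata alongside.
    """
    from . import __version__

    if isinstance(table, dict):
        lengths = {len(v) for v in table.values()}
        if len(lengths) > 1:
            raise ParameterError("all columns must have equal length")
        df = pd.DataFrame(table)
    else:
        df = table
    meta = {"tool": f"hydrashell {__version__}", **(metadata or {})}
    fmt = fmt.lower()
    try:
        if fmt in ("csv", "tsv"):
            sep = "," if fmt == "csv" else "\t"
            with open(path, "w") as fh:
                for k, v in meta.items():
                    fh.write(f"# {k}: {v}\n")
                df.to_csv(fh, sep=sep, index=False)
        elif fmt == "json":
            import json

            payload = {"metadata": meta,
                       "columns": {c: df[c].tolist() for c in df.columns}}
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
        else:
            raise ParameterError(f"unknown output format {fmt!r}")
    except OSError as exc:
        raise InputError(f"cannot write {path!r}: {exc}") from exc


def read_series(path: str, fmt: str = "csv") -> pd.DataFrame:
    """Read back a table written by :func:`write_series`."""
    fmt = fmt.lower()
    if fmt in ("csv", "tsv"):
        return pd.read_csv(path, sep="," if fmt == "csv" else "\t", comment="#")
    if fmt == "json":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["columns"])
    raise ParameterError(f"unknown input format {fmt!r}")
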