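"""Structure and trajectory containers plus PDB/XYZ readers and writers.

Containers are plain numpy-backed dataclasses; file parsing and writing
are delegated to MDAnalysis.  Units are Angstrom for coordinates, ps for
time and K for temperature throughout the package.

The canonical desk-scale trajectory format is the multi-model PDB
(MODEL/ENDMDL); multi-frame XYZ is accepted through the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FileFormatError, SelectionError
from .sequence import RegionMap

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSelection",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select_atoms",
]

# minimal element -> atomic mass (amu) table; pseudo-atoms default to 1.0
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "K": 39.098, "MG": 24.305, "CL": 35.45,
    "X": 1.0,
}


def element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name (first letter wins)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_index: int  # 1-based
    residue_name: str
    mass: float

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise FileFormatError(f"residue_index must be >=1, got {self.residue_index}")
        if not self.mass > 0:
            raise FileFormatError(f"atom mass must be positive, got {self.mass}")


@dataclass(frozen=True)
class Structure:
    """An ordered atom list with one coordinate frame (Angstrom)."""

    atoms: tuple[Atom, ...]
    coordinates: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.shape != (len(self.atoms), 3):
            raise FileFormatError(
                f"coordinate array {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise FileFormatError("non-finite coordinates")
        if len(self.atoms) == 0:
            raise FileFormatError("structure has zero atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms])

    @property
    def n_residues(self) -> int:
        return int(self.residue_indices.max())


@dataclass(frozen=True)
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``frame_interval`` is the time between saved frames in ps.
    """

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = 0.5

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise FileFormatError("trajectory needs >=1 frame of shape (n_atoms, 3)")
        if frames.shape[1:] != (self.topology.n_atoms, 3):
            raise FileFormatError(
                f"frame shape {frames.shape[1:]} does not match topology "
                f"({self.topology.n_atoms} atoms)"
            )
        if not self.frame_interval > 0:
            raise FileFormatError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom filter resolved against a topology + region map.

    ``region`` is one of ``whole``, ``core``, ``loop`` (all loops) or
    ``loop1``/``loop2``/``loop3``.  Heavy-atom-only is the default; set
    ``heavy_only=False`` to keep hydrogens.  ``names`` optionally
    whitelists PDB atom names.
    """

    region: str = "whole"
    heavy_only: bool = True
    names: tuple[str, ...] | None = None


def _universe_from_structure(structure: Structure):
    import MDAnalysis as mda

    n = structure.n_atoms
    resindices = structure.residue_indices - 1
    n_res = int(resindices.max()) + 1
    u = mda.Universe.empty(
        n, n_residues=n_res,
        atom_resindex=resindices,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in structure.atoms])
    resnames = [""] * n_res
    for a in structure.atoms:
        resnames[a.residue_index - 1] = a.residue_name
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.add_TopologyAttr("elements", [a.element for a in structure.atoms])
    u.atoms.positions = structure.coordinates
    return u


def _structure_from_universe(u) -> Structure:
    atoms = []
    for ag_atom in u.atoms:
        name = str(ag_atom.name)
        try:
            element = str(ag_atom.element) or element_from_name(name)
        except Exception:
            element = element_from_name(name)
        element = element.upper()
        mass = _ELEMENT_MASSES.get(element, 1.0)
        try:
            resname = str(ag_atom.resname)
        except Exception:
            resname = "UNK"
        atoms.append(
            Atom(
                name=name,
                element=element,
                residue_index=int(ag_atom.resid),
                residue_name=resname,
                mass=mass,
            )
        )
    return Structure(atoms=tuple(atoms), coordinates=u.atoms.positions.astype(float))


def _load_universe(path: Path):
    import MDAnalysis as mda

    if not path.exists():
        raise FileFormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FileFormatError(f"{path}: empty file")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path))
    except FileFormatError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise FileFormatError(f"{path}: cannot parse ({exc})") from exc


def read_structure(path: str | Path) -> Structure:
    """Read a single-model PDB or single-frame XYZ file.

    Atoms are returned in file order with elements inferred from atom
    names when the file does not state them.
    """
    path = Path(path)
    u = _load_universe(path)
    if u.atoms.n_atoms == 0:
        raise FileFormatError(f"{path}: zero atoms")
    return _structure_from_universe(u)


def read_trajectory(path: str | Path, frame_interval: float = 0.5) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ as a :class:`Trajectory`.

    All frames must carry the same atom count; the first frame defines
    the topology.
    """
    path = Path(path)
    _validate_constant_atom_count(path)
    u = _load_universe(path)
    if u.atoms.n_atoms == 0:
        raise FileFormatError(f"{path}: zero atoms")
    topology = _structure_from_universe(u)
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.positions.shape[0] != topology.n_atoms:
                raise FileFormatError(
                    f"{path}: frame {ts.frame} has {ts.positions.shape[0]} atoms, "
                    f"expected {topology.n_atoms}"
                )
            frames.append(ts.positions.astype(float).copy())
    traj = Trajectory(
        topology=replace(topology, coordinates=frames[0]),
        frames=np.stack(frames),
        frame_interval=frame_interval,
    )
    return traj


def _validate_constant_atom_count(path: Path) -> None:
    """Reject multi-model PDBs whose models differ in atom count.

    MDAnalysis silently truncates or pads such files, so the check is
    done on the raw records.
    """
    if path.suffix.lower() not in {".pdb", ".ent"}:
        return
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec in {"ATOM", "HETATM"}:
                if current is None:
                    current = 0
                current += 1
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current:
        counts.append(current)
    if len(set(counts)) > 1:
        raise FileFormatError(
            f"{path}: inconsistent atom counts across models: {sorted(set(counts))}"
        )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as single-model PDB or XYZ (by extension)."""
    write_trajectory(
        Trajectory(topology=structure, frames=structure.coordinates[None, :, :]),
        path,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames as multi-model PDB or multi-frame XYZ (by extension)."""
    import MDAnalysis as mda

    path = Path(path)
    u = _universe_from_structure(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as w:
            for frame in traj.frames:
                u.atoms.positions = frame
                w.write(u.atoms)


def select_atoms(
    structure: Structure,
    selection: AtomSelection,
    regions: RegionMap | None = None,
) -> np.ndarray:
    """Resolve a selection to a deterministic, ordered atom index array.

    ``regions`` maps 1-based residue indices to region labels and is
    required for any region other than ``whole``.  The union of the
    ``core`` and ``loop`` selections equals the ``whole`` selection.
    """
    n = structure.n_atoms
    keep = np.ones(n, dtype=bool)
    if selection.region != "whole":
        if regions is None:
            raise SelectionError("a RegionMap is required for region selections")
        if structure.n_residues > len(regions):
            raise SelectionError(
                f"region map covers {len(regions)} residues but the topology "
                f"has {structure.n_residues}"
            )
        wanted = set(regions.residues(selection.region))
        if not wanted:
            raise SelectionError(f"region {selection.region!r} has no residues")
        keep &= np.array(
            [a.residue_index in wanted for a in structure.atoms]
        )
    if selection.heavy_only:
        keep &= np.array([a.element != "H" for a in structure.atoms])
    if selection.names is not None:
        allowed = set(selection.names)
        keep &= np.array([a.name in allowed for a in structure.atoms])
    indices = np.flatnonzero(keep)
    if indices.size == 0:
        raise SelectionError(f"selection {selection} matches no atoms")
    return indices
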