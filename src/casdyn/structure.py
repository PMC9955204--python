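"""Structures, trajectories and the Cas9 domain map.

PDB reading/writing goes through biotite; binary trajectories (XTC/DCD)
are read through an mdtraj adapter.  Coordinates are Å everywhere inside
the package; nm-based inputs are converted at this boundary.

Residue numbering follows the 1-based author numbering of the PDB file,
matching the residue indices used throughout the Cas9 literature
(e.g. Gln768, His840).
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "TrajectoryEnsemble",
    "DomainMap",
    "CAS9_DOMAIN_MAP",
    "read_structure",
    "write_structure",
    "write_trajectory_pdb",
    "read_trajectory",
    "classify_residue",
    "domain_composition",
    "select_atoms",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Atom:
    name: str
    res_id: int
    res_name: str
    chain_id: str
    coord: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.res_id < 1:
            raise ValueError(f"residue index must be positive, got {self.res_id}")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Structure:
    """An ordered list of atom records (one model)."""

    atoms: list[Atom]

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def res_ids(self) -> np.ndarray:
        return np.array([a.res_id for a in self.atoms], dtype=int)

    def atom_index(self, res_id: int, atom_name: str, res_name: str | None = None) -> int:
        """Index of the unique atom matching the selector, or KeyError."""
        hits = [
            i for i, a in enumerate(self.atoms)
            if a.res_id == res_id and a.name == atom_name
            and (res_name is None or a.res_name == res_name)
        ]
        if len(hits) != 1:
            raise KeyError(
                f"selector (res {res_id}, atom {atom_name}, res_name {res_name}) "
                f"matched {len(hits)} atoms"
            )
        return hits[0]


@dataclass
class TrajectoryEnsemble:
    """Frames of coordinates over a fixed topology.

    ``frames`` is (n_frames, n_atoms, 3) in Å; ``frame_stride_ns`` is the
    time between consecutive frames (the study strides frames at 1 ns).
    """

    topology: Structure
    frames: np.ndarray
    frame_stride_ns: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({len(self.topology)} atoms)"
            )
        if self.frame_stride_ns <= 0:
            raise ValueError("frame_stride_ns must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


class DomainMap:
    """Label → inclusive 1-based residue ranges; ranges must not overlap."""

    def __init__(self, entries: dict[str, list[tuple[int, int]]]):
        seen: list[tuple[int, int, str]] = []
        for label, ranges in entries.items():
            for start, end in ranges:
                if start > end:
                    raise ValueError(f"{label}: range {start}-{end} has start > end")
                for s, e, other in seen:
                    if start <= e and s <= end:
                        raise ValueError(
                            f"range {start}-{end} ({label}) overlaps "
                            f"{s}-{e} ({other})"
                        )
                seen.append((start, end, label))
        self.entries = {k: [tuple(r) for r in v] for k, v in entries.items()}

    @classmethod
    def from_config(cls, mapping: dict[str, list[str]]) -> "DomainMap":
        """Parse config form: label → list of "start-end" strings."""
        entries: dict[str, list[tuple[int, int]]] = {}
        for label, ranges in mapping.items():
            parsed = []
            for r in ranges:
                start, _, end = str(r).partition("-")
                parsed.append((int(start), int(end or start)))
            entries[label] = parsed
        return cls(entries)


#: SpCas9 domain boundaries used throughout the analysis: the two nuclease
#: domains, the L1/L2 linkers connecting them, and the arginine-rich bridge.
CAS9_DOMAIN_MAP = DomainMap({
    "RuvC": [(1, 59), (718, 764), (917, 1098)],
    "bridge": [(60, 93)],
    "L1": [(765, 778)],
    "HNH": [(779, 906)],
    "L2": [(907, 916)],
})

_SOLVENT_RES = {"HOH", "WAT", "SOL", "TIP", "TIP3", "NA", "CL", "K", "MG", "ZN"}


def _structure_from_atom_array(arr) -> Structure:
    atoms = []
    for i in range(arr.array_length()):
        if arr.hetero[i] and arr.res_name[i] in _SOLVENT_RES:
            continue
        atoms.append(Atom(
            name=str(arr.atom_name[i]),
            res_id=int(arr.res_id[i]),
            res_name=str(arr.res_name[i]),
            chain_id=str(arr.chain_id[i]),
            coord=tuple(float(x) for x in arr.coord[i]),
        ))
    return Structure(atoms=atoms)


def read_structure(path: str | os.PathLike) -> Structure:
    """Read the first model of a PDB file.

    Hetero solvent/ion records are skipped; nucleic chains are retained
    (the pucker analysis needs them).  The first altloc is kept.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:  # annotate with the offending line when findable
        line_no = _find_bad_atom_line(path)
        suffix = f" (first malformed ATOM record at line {line_no})" if line_no else ""
        raise ValueError(f"cannot parse PDB file {path}: {exc}{suffix}") from exc
    return _structure_from_atom_array(arr)


def _find_bad_atom_line(path) -> int | None:
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                        int(line[22:26])
                    except ValueError:
                        return i
    except OSError:
        return None
    return None


def _to_atom_array(structure: Structure, coords: np.ndarray | None = None):
    import biotite.structure as struc

    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = structure.coords if coords is None else np.asarray(coords, dtype=float)
    for i, a in enumerate(structure.atoms):
        arr.atom_name[i] = a.name
        arr.res_id[i] = a.res_id
        arr.res_name[i] = a.res_name
        arr.chain_id[i] = a.chain_id
        arr.element[i] = a.name[0] if a.name[0].isalpha() else a.name[1]
    return arr


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a single-model PDB file."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile()
    f.set_structure(_to_atom_array(structure))
    f.write(str(path))


def write_trajectory_pdb(traj: TrajectoryEnsemble, path: str | os.PathLike) -> None:
    """Write a multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_frames, n_atoms, _ = traj.frames.shape
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = traj.frames
    template = _to_atom_array(traj.topology)
    for cat in ("atom_name", "res_id", "res_name", "chain_id", "element"):
        stack.set_annotation(cat, template.get_annotation(cat))
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_trajectory(
    paths,
    topology: Structure,
    frame_stride_ns: float = 1.0,
) -> TrajectoryEnsemble:
    """Read one or more trajectory files against a fixed topology.

    Multi-model PDB is read natively; ``.xtc``/``.dcd`` go through mdtraj.
    Frames are concatenated in the order the paths are given.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    all_frames: list[np.ndarray] = []
    for path in paths:
        ext = os.path.splitext(str(path))[1].lower()
        if ext in (".pdb", ".ent"):
            frames = _read_pdb_frames(path)
        elif ext in (".xtc", ".dcd"):
            frames = _read_binary_frames(path, topology)
        else:
            raise ValueError(f"unsupported trajectory format: {path}")
        for k, frame in enumerate(frames):
            if frame.shape[0] != len(topology):
                raise ValueError(
                    f"{path}: frame {k} has {frame.shape[0]} atoms, "
                    f"topology has {len(topology)}"
                )
        all_frames.append(frames)
    return TrajectoryEnsemble(
        topology=topology,
        frames=np.concatenate(all_frames, axis=0),
        frame_stride_ns=frame_stride_ns,
    )


def _read_pdb_frames(path) -> np.ndarray:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(altloc="first")
    coord = stack.coord
    if coord.ndim == 2:
        coord = coord[None]
    return np.asarray(coord, dtype=float)


def _read_binary_frames(path, topology: Structure) -> np.ndarray:
    import tempfile

    import mdtraj

    with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as tmp:
        tmp_path = tmp.name
    try:
        write_structure(topology, tmp_path)
        t = mdtraj.load(str(path), top=tmp_path)
    finally:
        os.unlink(tmp_path)
    return np.asarray(t.xyz, dtype=float) * 10.0  # nm → Å


# ---------------------------------------------------------------------------
# Domain classification


def classify_residue(domain_map: DomainMap, res_id: int) -> str:
    """Domain label of the unique range containing ``res_id``, else "unassigned"."""
    for label, ranges in domain_map.entries.items():
        for start, end in ranges:
            if start <= res_id <= end:
                return label
    return "unassigned"


def _round_half_up(x: float, decimals: int = 1) -> float:
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def domain_composition(res_ids, domain_map: DomainMap) -> dict[str, float]:
    """Percentage of the input residues per domain, one decimal (half-up).

    Residues outside every range are reported under "unassigned"; labels
    with zero share are omitted.
    """
    res_ids = list(res_ids)
    if not res_ids:
        raise ValueError("residue list is empty")
    counts: dict[str, int] = {}
    for r in res_ids:
        label = classify_residue(domain_map, int(r))
        counts[label] = counts.get(label, 0) + 1
    total = len(res_ids)
    return {
        label: _round_half_up(100.0 * c / total, 1)
        for label, c in counts.items()
    }


# ---------------------------------------------------------------------------
# Atom selection


def select_atoms(
    structure: Structure,
    selection: str = "CA",
    residue_range: tuple[int, int] | None = None,
    atom_names=None,
) -> np.ndarray:
    """Ascending atom indices for a named selection.

    ``selection`` is one of "CA", "backbone" (N/CA/C/O), "all", or "names"
    (then ``atom_names`` gives the accepted names).  ``residue_range``
    restricts to an inclusive 1-based residue interval.
    """
    if selection == "CA":
        accept = {"CA"}
    elif selection == "backbone":
        accept = set(BACKBONE_ATOMS)
    elif selection == "all":
        accept = None
    elif selection == "names":
        if not atom_names:
            raise ValueError("selection 'names' requires atom_names")
        accept = set(atom_names)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    idx = []
    for i, a in enumerate(structure.atoms):
        if accept is not None and a.name not in accept:
            continue
        if residue_range is not None and not (residue_range[0] <= a.res_id <= residue_range[1]):
            continue
        idx.append(i)
    if not idx:
        warnings.warn("selection matched no atoms", stacklevel=2)
    return np.array(idx, dtype=int)
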