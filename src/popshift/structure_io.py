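"""Structures, ensembles and ligand torsion trees.

Two fixed-column dialects are supported:

``pdb``
    Plain PDB ``ATOM``/``HETATM``/``MODEL``/``ENDMDL``/``TER``/``REMARK``
    records.  Partial charges default to zero and the atom type defaults to
    the element symbol.

``pdbq_charged``
    A PDB ``ATOM``/``HETATM`` line extended with a partial charge in columns
    71-76 (``%6.3f``, elementary charges) and an energy-table atom-type code
    in columns 78-79.  ``MODEL`` blocks are allowed.

Conformational ensembles are multi-model PDB files; a
``REMARK TIME_PS <number>`` line preceding each ``MODEL`` carries the
snapshot time in picoseconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation


class PDBParseError(ValueError):
    """A record could not be parsed under the requested dialect."""


class StructureError(ValueError):
    """A structural invariant is violated."""


DIALECTS = ("pdb", "pdbq_charged")

#: residue names treated as solvent
WATER_RESNAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "H2O", "DOD"}
#: residue names treated as monoatomic ions
ION_RESNAMES = {"MG", "NA", "K", "CL", "ZN", "CA", "MN", "FE", "CU", "NI", "CD", "SR", "CS"}

# single-bond covalent radii (Angstrom), used only for connectivity inference
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "MG": 1.41, "NA": 1.66,
    "K": 2.03, "CA": 1.76, "ZN": 1.22, "FE": 1.32, "MN": 1.39,
}
_DEFAULT_COVALENT_RADIUS = 0.75

_TWO_LETTER_ELEMENTS = {"MG", "CL", "NA", "ZN", "BR", "FE", "MN", "CA", "CD", "NI", "SR", "CS"}


@dataclass
class Atom:
    """One atom with coordinates, charge and an energy-table type code."""

    serial: int
    name: str
    element: str
    atom_type: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    partial_charge: float = 0.0
    occupancy: float = 1.0
    alt_loc: str = ""
    record: str = "ATOM"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise StructureError(f"atom {self.serial}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.serial}: non-finite position")
        if not math.isfinite(self.partial_charge):
            raise StructureError(f"atom {self.serial}: non-finite partial charge")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)


ROLES = ("receptor", "ligand", "ion", "water")


@dataclass
class Structure:
    """An ordered list of atoms with per-atom role labels.

    Roles partition the atoms into ``receptor``, ``ligand``, ``ion`` and
    ``water`` so that downstream stages (scoring, interaction analysis) can
    exclude solvent and metal ions without re-reading the file.
    """

    atoms: list[Atom]
    role_labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.atoms) == 0:
            raise StructureError("structure must contain at least one atom")
        if len(self.role_labels) != len(self.atoms):
            raise StructureError("role labels must cover all atoms")
        bad = set(self.role_labels) - set(ROLES)
        if bad:
            raise StructureError(f"unknown role labels: {sorted(bad)}")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("atom serials must be unique within a model")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def atom_types(self) -> list[str]:
        return [a.atom_type for a in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        atoms = [
            Atom(a.serial, a.name, a.element, a.atom_type, a.residue_name,
                 a.residue_number, a.chain_id, coords[i].copy(), a.partial_charge,
                 a.occupancy, a.alt_loc, a.record)
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, list(self.role_labels), dict(self.metadata))

    def role_indices(self, *roles: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.role_labels) if r in roles], dtype=int)

    def subset(self, indices: Iterable[int]) -> "Structure":
        idx = list(indices)
        if not idx:
            raise StructureError("cannot build an empty substructure")
        return Structure([self.atoms[i] for i in idx],
                         [self.role_labels[i] for i in idx],
                         dict(self.metadata))

    def geometric_center(self, indices: Iterable[int] | None = None) -> np.ndarray:
        c = self.coords
        if indices is not None:
            c = c[list(indices)]
        return c.mean(axis=0)


@dataclass
class EnsembleTrajectory:
    """Time-stamped multi-model coordinates with constant topology."""

    frames: list[tuple[float, Structure]]
    topology_constant: bool = True

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("trajectory must contain at least one frame")
        times = [t for t, _ in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise StructureError("frame times must be strictly increasing")
        if self.topology_constant:
            n0 = len(self.frames[0][1])
            names0 = [a.name for a in self.frames[0][1].atoms]
            for i, (_, s) in enumerate(self.frames):
                if len(s) != n0:
                    raise StructureError(
                        f"frame {i} has {len(s)} atoms, expected {n0} (constant topology)")
                if [a.name for a in s.atoms] != names0:
                    raise StructureError(f"frame {i} atom ordering differs from frame 0")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.frames], dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class TorsionTree:
    """Ligand as a rigid root plus rotatable bonds, each moving a subtree.

    Atom indices are 0-based positions in the ligand's atom list.  The moved
    set of an axis ``(a, b)`` contains the atoms strictly beyond ``b`` when
    walking away from ``a``; the axis atoms themselves never move.
    """

    root_atom_indices: frozenset[int]
    rotatable_bonds: list[tuple[tuple[int, int], frozenset[int]]]

    @property
    def n_tor(self) -> int:
        return len(self.rotatable_bonds)


# ---------------------------------------------------------------------------
# parsing


def _infer_element(name: str, residue_name: str) -> str:
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        return "X"
    if stripped in _TWO_LETTER_ELEMENTS and residue_name.strip().upper() == stripped:
        return stripped.capitalize()
    if stripped[:2] in _TWO_LETTER_ELEMENTS and residue_name.strip().upper() in ION_RESNAMES:
        return stripped[:2].capitalize()
    return stripped[0]


def _assign_role(atom: Atom) -> str:
    res = atom.residue_name.upper()
    if res in WATER_RESNAMES:
        return "water"
    if res in ION_RESNAMES:
        return "ion"
    if atom.record == "HETATM":
        return "ligand"
    return "receptor"


def _parse_atom_line(line: str, lineno: int, dialect: str) -> Atom:
    record = line[0:6].strip()
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip() if len(line) > 16 else ""
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() if len(line) > 21 else ""
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed {record or 'ATOM'} record: {exc}") from exc

    element_field = line[76:78].strip() if dialect == "pdb" and len(line) >= 78 else ""
    element = element_field.capitalize() if element_field else _infer_element(name, residue_name)

    partial_charge = 0.0
    atom_type = element
    if dialect == "pdbq_charged":
        try:
            charge_field = line[70:76].strip()
            partial_charge = float(charge_field) if charge_field else 0.0
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed partial charge column") from exc
        type_field = line[77:79].strip() if len(line) > 77 else ""
        if type_field:
            atom_type = type_field

    return Atom(serial, name, element, atom_type, residue_name, residue_number,
                chain_id, np.array([x, y, z]), partial_charge, occupancy, alt_loc, record)


def _collapse_alt_locs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom: highest occupancy, ties alphabetically first."""
    best: dict[tuple, tuple[int, Atom]] = {}
    order: list[tuple] = []
    for i, atom in enumerate(atoms):
        key = (atom.chain_id, atom.residue_number, atom.residue_name, atom.name)
        if key not in best:
            best[key] = (i, atom)
            order.append(key)
        else:
            _, incumbent = best[key]
            if (atom.occupancy > incumbent.occupancy
                    or (atom.occupancy == incumbent.occupancy
                        and (atom.alt_loc or "~") < (incumbent.alt_loc or "~"))):
                best[key] = (best[key][0], atom)
    return [best[key][1] for key in order]


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_structure(path: str | Path, dialect: str = "pdb") -> Structure:
    """Read a single-model structure.

    Multi-model files are rejected with a pointer to :func:`read_ensemble`.
    Alternate-location duplicates are collapsed to the conformer with the
    highest occupancy (ties broken alphabetically by alt-loc code).
    """
    _check_dialect(dialect)
    path = Path(path)
    atoms: list[Atom] = []
    n_models = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[0:6].strip()
        if rec == "MODEL":
            n_models += 1
            if n_models > 1:
                raise StructureError(
                    f"{path} contains multiple MODEL blocks; use read_ensemble")
        elif rec in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno, dialect))
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    atoms = _collapse_alt_locs(atoms)
    roles = [_assign_role(a) for a in atoms]
    return Structure(atoms, roles, {"source": str(path), "dialect": dialect})


def _format_atom_name(name: str, element: str) -> str:
    # standard PDB alignment: 1-2 letter elements start in column 14 unless
    # the name is four characters long
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def _format_atom_line(atom: Atom, dialect: str) -> str:
    record = atom.record if atom.record in ("ATOM", "HETATM") else "ATOM"
    name = _format_atom_name(atom.name, atom.element)
    x, y, z = atom.position
    line = (f"{record:<6}{atom.serial:>5} {name}{atom.alt_loc or '':1}"
            f"{atom.residue_name:>3} {atom.chain_id or '':1}{atom.residue_number:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}")
    if dialect == "pdbq_charged":
        line += f"    {atom.partial_charge:6.3f} {atom.atom_type:<2}"
    else:
        line += f"          {atom.element.upper():>2}"
    return line


def write_structure(s: Structure, path: str | Path, dialect: str = "pdb") -> None:
    """Write a structure; round-trips names, residues, positions and charges
    to three decimals."""
    _check_dialect(dialect)
    s.validate()
    lines = [_format_atom_line(a, dialect) for a in s.atoms]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ensemble(path: str | Path, dialect: str = "pdb") -> EnsembleTrajectory:
    """Read a multi-model PDB file as a trajectory.

    Snapshot times come from ``REMARK TIME_PS`` lines preceding each
    ``MODEL``; when absent, times 0, 1, 2, ... are assigned with a warning.
    """
    _check_dialect(dialect)
    path = Path(path)
    models: list[list[Atom]] = []
    times: list[float | None] = []
    pending_time: float | None = None
    current: list[Atom] | None = None
    saw_model = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[0:6].strip()
        if rec == "REMARK":
            fields = line.split()
            if len(fields) >= 3 and fields[1] == "TIME_PS":
                try:
                    pending_time = float(fields[2])
                except ValueError as exc:
                    raise PDBParseError(f"line {lineno}: malformed TIME_PS remark") from exc
        elif rec == "MODEL":
            saw_model = True
            current = []
            models.append(current)
            times.append(pending_time)
            pending_time = None
        elif rec == "ENDMDL":
            current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                if saw_model:
                    raise PDBParseError(f"line {lineno}: ATOM record outside MODEL block")
                current = []
                models.append(current)
                times.append(pending_time)
            current.append(_parse_atom_line(line, lineno, dialect))
    if not models or not models[0]:
        raise PDBParseError(f"{path}: no coordinates found")

    if any(t is None for t in times):
        if any(t is not None for t in times):
            warnings.warn(f"{path}: incomplete TIME_PS annotation; assigning unit-spaced times")
        else:
            warnings.warn(f"{path}: no TIME_PS annotation; assigning unit-spaced times")
        times = [float(i) for i in range(len(models))]

    n0 = len(models[0])
    for i, m in enumerate(models):
        if len(m) != n0:
            raise StructureError(
                f"{path}: model {i + 1} has {len(m)} atoms, expected {n0}")

    frames = []
    for t, atoms in zip(times, models):
        atoms = _collapse_alt_locs(atoms)
        roles = [_assign_role(a) for a in atoms]
        frames.append((float(t), Structure(atoms, roles, {"source": str(path)})))
    return EnsembleTrajectory(frames)


def write_ensemble(traj: EnsembleTrajectory, path: str | Path,
                   dialect: str = "pdb") -> None:
    """Write a trajectory as a multi-model file with TIME_PS remarks."""
    _check_dialect(dialect)
    lines: list[str] = []
    for i, (t, s) in enumerate(traj.frames, start=1):
        lines.append(f"REMARK TIME_PS {t:g}")
        lines.append(f"MODEL {i:>8}")
        lines.extend(_format_atom_line(a, dialect) for a in s.atoms)
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# connectivity and torsion trees


def infer_bonds(s: Structure, indices: Sequence[int] | None = None) -> list[tuple[int, int]]:
    """Distance-rule connectivity: atoms i, j are bonded iff
    ``d < 0.6 * (r_cov_i + r_cov_j) + 0.6`` Angstrom."""
    if indices is None:
        indices = list(range(len(s)))
    coords = s.coords[list(indices)]
    radii = np.array([
        COVALENT_RADII.get(s.atoms[i].element.upper(), _DEFAULT_COVALENT_RADIUS)
        for i in indices
    ])
    if len(indices) < 2:
        return []
    d = squareform(pdist(coords))
    cut = 0.6 * (radii[:, None] + radii[None, :]) + 0.6
    bonds = []
    for a in range(len(indices)):
        for b in range(a + 1, len(indices)):
            if 0.1 < d[a, b] < cut[a, b]:
                bonds.append((indices[a], indices[b]))
    return bonds


def build_torsion_tree(s: Structure, bonds: Sequence[tuple[int, int]],
                       root_atom: int | None = None,
                       ligand_indices: Sequence[int] | None = None) -> TorsionTree:
    """Build a torsion tree from requested rotatable bonds.

    Connectivity within the ligand is inferred by the covalent distance rule.
    Each requested bond must be a real, non-ring bond; its moved set holds the
    atoms strictly beyond the distal axis atom (as seen from the root), so
    rotating a bond never moves the axis atoms themselves.
    """
    if ligand_indices is None:
        lig = s.role_indices("ligand")
        ligand_indices = list(lig) if len(lig) else list(range(len(s)))
    ligand_indices = list(ligand_indices)
    graph = nx.Graph()
    graph.add_nodes_from(ligand_indices)
    graph.add_edges_from(infer_bonds(s, ligand_indices))
    if len(ligand_indices) > 1 and not nx.is_connected(graph):
        raise StructureError("ligand graph is disconnected; cannot build torsion tree")

    root = ligand_indices[0] if root_atom is None else root_atom
    if root not in graph:
        raise StructureError(f"root atom {root} is not a ligand atom")

    rotatable: list[tuple[tuple[int, int], frozenset[int]]] = []
    for a, b in bonds:
        if not graph.has_edge(a, b):
            raise StructureError(f"atoms {a} and {b} are not bonded")
        g2 = graph.copy()
        g2.remove_edge(a, b)
        if nx.has_path(g2, a, b):
            raise StructureError(f"bond ({a}, {b}) lies in a ring; not rotatable")
        comp_a = nx.node_connected_component(g2, a)
        comp_b = nx.node_connected_component(g2, b)
        # orient the axis so the first atom is on the root side
        if root in comp_a:
            axis, moved = (a, b), frozenset(comp_b) - {b}
        elif root in comp_b:
            axis, moved = (b, a), frozenset(comp_a) - {a}
        else:  # pragma: no cover - unreachable on a connected graph
            raise StructureError("root atom separated from both axis atoms")
        if not moved:
            raise StructureError(f"bond {axis} is terminal; rotating it moves no atoms")
        rotatable.append((axis, moved))

    moved_union: set[int] = set()
    for _, moved in rotatable:
        moved_union |= moved
    root_set = frozenset(ligand_indices) - moved_union
    return TorsionTree(root_set, rotatable)


def rotate_torsion(coords: np.ndarray, tree: TorsionTree, bond_index: int,
                   angle_deg: float) -> np.ndarray:
    """Rotate one torsion's moved set about its axis; returns new coordinates."""
    (a, b), moved = tree.rotatable_bonds[bond_index]
    coords = np.array(coords, dtype=float)
    axis = coords[b] - coords[a]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise StructureError("degenerate torsion axis (coincident atoms)")
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm)
    idx = sorted(moved)
    coords[idx] = rot.apply(coords[idx] - coords[b]) + coords[b]
    return coords


def apply_torsions(coords: np.ndarray, tree: TorsionTree,
                   angles_deg: Sequence[float]) -> np.ndarray:
    """Apply all torsions root-outward (larger moved sets first)."""
    if len(angles_deg) != tree.n_tor:
        raise StructureError("torsion angle count does not match n_tor")
    order = sorted(range(tree.n_tor),
                   key=lambda k: -len(tree.rotatable_bonds[k][1]))
    out = np.array(coords, dtype=float)
    for k in order:
        if angles_deg[k] != 0.0:
            out = rotate_torsion(out, tree, k, angles_deg[k])
    return out
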