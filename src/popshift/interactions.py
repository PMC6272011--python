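"""Geometric interaction profile of a bound pose.

Hydrogen bonds and nonbonded contacts across the ligand/receptor boundary,
detected with configurable geometric criteria (donor-acceptor distance and
D-H...A angle for hydrogen bonds; a heavy-atom distance cutoff for
contacts).  Metal ions and waters are excluded by default.  A pair reported
as a hydrogen bond never reappears in the contact list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from popshift.energy import EnergyParameters
from popshift.structure_io import Structure, infer_bonds


@dataclass(frozen=True)
class HBond:
    donor_index: int
    acceptor_index: int
    hydrogen_index: int | None
    distance: float          # donor-acceptor, Angstrom
    angle: float | None      # D-H...A, degrees (None without explicit H)
    donor_is_ligand: bool


@dataclass(frozen=True)
class Contact:
    ligand_index: int
    receptor_index: int
    residue_id: tuple[str, int, str]
    distance: float


@dataclass
class InteractionReport:
    hbonds: list[HBond]
    contacts: list[Contact]
    excluded_roles: frozenset[str] = frozenset({"ion", "water"})

    def contacts_by_residue(self) -> dict[tuple[str, int, str], list[Contact]]:
        grouped: dict[tuple[str, int, str], list[Contact]] = {}
        for c in self.contacts:
            grouped.setdefault(c.residue_id, []).append(c)
        return grouped


def _boundary_indices(complex_structure: Structure,
                      include_ions: bool, include_waters: bool):
    roles = ["receptor"]
    if include_ions:
        roles.append("ion")
    if include_waters:
        roles.append("water")
    rec = complex_structure.role_indices(*roles)
    lig = complex_structure.role_indices("ligand")
    if len(rec) == 0 or len(lig) == 0:
        raise ValueError("complex must contain both receptor and ligand atoms")
    return rec, lig


def _hbond_roles(p: EnergyParameters, structure: Structure, indices: np.ndarray):
    """Acceptor heavy atoms and donor heavy atoms (with attached polar H).

    A heavy atom donates if its type class is donor/both, or if a
    donor-class hydrogen is covalently attached to it.
    """
    acceptors = []
    donors: dict[int, int | None] = {}
    index_set = set(int(i) for i in indices)
    bonds = infer_bonds(structure, sorted(index_set))
    attached_h: dict[int, int] = {}
    for a, b in bonds:
        ta = structure.atoms[a].atom_type
        tb = structure.atoms[b].atom_type
        ca = p.types[ta].hb_class if ta in p.types else "none"
        cb = p.types[tb].hb_class if tb in p.types else "none"
        if ca in ("donor", "both") and structure.atoms[a].element.upper() == "H":
            attached_h[b] = a
        if cb in ("donor", "both") and structure.atoms[b].element.upper() == "H":
            attached_h[a] = b
    for i in indices:
        atom = structure.atoms[i]
        if atom.element.upper() == "H":
            continue
        cls = p.types[atom.atom_type].hb_class if atom.atom_type in p.types else "none"
        if cls in ("acceptor", "both"):
            acceptors.append(int(i))
        if cls in ("donor", "both") or int(i) in attached_h:
            donors[int(i)] = attached_h.get(int(i))
    return donors, acceptors


def detect_hbonds(complex_structure: Structure, p: EnergyParameters,
                  max_da_distance: float = 3.5,
                  min_dha_angle: float = 120.0,
                  include_ions: bool = False,
                  include_waters: bool = False) -> list[HBond]:
    """Donor-acceptor pairs across the ligand/receptor boundary.

    Requires D-A distance <= ``max_da_distance`` and, when the donor
    hydrogen is present, a D-H...A angle >= ``min_dha_angle``.
    """
    rec, lig = _boundary_indices(complex_structure, include_ions, include_waters)
    coords = complex_structure.coords
    rec_donors, rec_acceptors = _hbond_roles(p, complex_structure, rec)
    lig_donors, lig_acceptors = _hbond_roles(p, complex_structure, lig)

    def angle_ok(donor: int, hydrogen: int | None, acceptor: int):
        if hydrogen is None:
            return True, None
        dh = coords[donor] - coords[hydrogen]
        ah = coords[acceptor] - coords[hydrogen]
        cosang = np.dot(dh, ah) / (np.linalg.norm(dh) * np.linalg.norm(ah))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return ang >= min_dha_angle, ang

    found = []
    for donors, acceptors, donor_is_ligand in (
            (lig_donors, rec_acceptors, True),
            (rec_donors, lig_acceptors, False)):
        for donor, hydrogen in sorted(donors.items()):
            for acceptor in acceptors:
                d = float(np.linalg.norm(coords[donor] - coords[acceptor]))
                if d > max_da_distance:
                    continue
                ok, ang = angle_ok(donor, hydrogen, acceptor)
                if not ok:
                    continue
                found.append(HBond(donor, acceptor, hydrogen, d, ang, donor_is_ligand))
    found.sort(key=lambda h: (h.distance, h.donor_index, h.acceptor_index))
    return found


def detect_contacts(complex_structure: Structure, p: EnergyParameters,
                    cutoff: float = 3.9,
                    hbonds: list[HBond] | None = None,
                    include_ions: bool = False,
                    include_waters: bool = False) -> list[Contact]:
    """Cross-boundary heavy-atom pairs within ``cutoff``, grouped by residue.

    Pairs already reported as hydrogen bonds are excluded; pass the hbond
    list detected with the same structure (computed with default criteria
    when omitted).
    """
    rec, lig = _boundary_indices(complex_structure, include_ions, include_waters)
    if hbonds is None:
        hbonds = detect_hbonds(complex_structure, p,
                               include_ions=include_ions,
                               include_waters=include_waters)
    hb_pairs = {frozenset((h.donor_index, h.acceptor_index)) for h in hbonds}

    rec = [i for i in rec if complex_structure.atoms[i].element.upper() != "H"]
    lig = [i for i in lig if complex_structure.atoms[i].element.upper() != "H"]
    d = cdist(complex_structure.coords[lig], complex_structure.coords[rec])
    contacts = []
    for a, li in enumerate(lig):
        for b, ri in enumerate(rec):
            if d[a, b] > cutoff:
                continue
            if frozenset((li, ri)) in hb_pairs:
                continue
            contacts.append(Contact(li, ri, complex_structure.atoms[ri].residue_id,
                                    float(d[a, b])))
    contacts.sort(key=lambda c: (c.residue_id, c.distance, c.ligand_index))
    return contacts


def interaction_report(complex_structure: Structure, p: EnergyParameters,
                       max_da_distance: float = 3.5,
                       min_dha_angle: float = 120.0,
                       contact_cutoff: float = 3.9,
                       include_ions: bool = False,
                       include_waters: bool = False) -> InteractionReport:
    """Full hydrogen-bond + contact profile with the exclusivity rule applied."""
    hbonds = detect_hbonds(complex_structure, p, max_da_distance, min_dha_angle,
                           include_ions, include_waters)
    contacts = detect_contacts(complex_structure, p, contact_cutoff, hbonds,
                               include_ions, include_waters)
    excluded = set()
    if not include_ions:
        excluded.add("ion")
    if not include_waters:
        excluded.add("water")
    return InteractionReport(hbonds, contacts, frozenset(excluded))
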