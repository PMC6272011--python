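"""Synthetic fixtures with known ground truth.

Statistical stand-ins for the crystal structures and simulation
trajectories the pipeline analyses in production:

* :func:`make_toy_complex` — a rigid spherical pocket with four charged
  anchor sites and a matching zwitterion-like chain ligand whose score
  landscape is smooth and whose optimum is certified by exhaustive
  translation enumeration;
* :func:`make_ensemble` — noisy conformational ensembles, optionally
  two-state so the rescored ΔG distribution is bimodal with known modes;
* :func:`make_rotamer_trajectory` — chi1..chi4 series drawn from mixtures
  of peaked circular (von Mises) components, realized as side-chain
  coordinates through an ideal-geometry template;
* :func:`make_score_samples` — ΔG draws from a Gaussian mixture with a
  controlled mode.

Every generator is a pure function of its spec and seed.  The pocket is
built from small probe atoms (energy-table type H, 2 Å equilibrium
distance) so that the pair potential is already smooth at the 2 Å approach
distance used in grid validation; the fixtures are statistical stand-ins
and make no attempt at force-field realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import vonmises

from popshift.energy import EnergyParameters, pair_energy, score_pose
from popshift.docking import IDENTITY_QUAT, Pose
from popshift.rotamers import DihedralSeries, wrap_angle
from popshift.structure_io import (Atom, EnsembleTrajectory, Structure,
                                   StructureError, TorsionTree, build_torsion_tree)


@dataclass
class PocketSpec:
    """Spherical-shell pocket with an ion-cradle binding site.

    Each atom of the as-built ligand rests in a downward hemispherical
    cradle of magnesium-type sites placed at the Mg-probe pair-potential
    minimum (1.65 Å for the defaults).  Mg is the smallest, deepest type in
    the parameter table, so the cradle supplies both binding depth and
    stiff, nearly isotropic confinement while every approach of 2 Å or
    more stays in the smooth attractive tail of the pair potential — the
    regime where affinity grids interpolate faithfully.  The cradle bottom
    carries a weak charge; the ``++--`` registry is unique (no shift or
    end-to-end flip of the chain pairs the charges attractively), so it
    fixes the in-plane position and orientation.  The cradle shell also
    blocks the mirror-image approach from below.
    """

    n_shell_atoms: int = 48
    cavity_radius: float = 8.0        # Angstrom
    atom_type: str = "H"
    shell_charge: float = 0.05        # alternating +/- on the shell
    anchor_charges: tuple = (-0.50, -0.50, 0.50, 0.50)
    site_type: str = "Mg"
    site_radius: float = 1.65         # cradle distance from each ligand atom
    site_rings: tuple = ((0.0, 1), (45.0, 4), (25.0, 4))  # (polar deg, count)
    # solid slab under the cradle: fills the space beneath the binding site
    # so the concave underside of the cradle layer is not itself a
    # competitive nesting surface
    slab_z: tuple = (-2.9, -4.1)      # z levels of the slab layers
    slab_spacing: float = 1.4         # lateral lattice spacing
    slab_radius: float = 4.3          # lateral extent


@dataclass
class LigandSpec:
    """Zig-zag chain ligand with alternating charges."""

    n_atoms: int = 4
    atom_type: str = "H"              # small probe type; element is carbon
    charges: tuple = (0.25, 0.25, -0.25, -0.25)
    bond_length: float = 1.45         # Angstrom
    bond_angle: float = 109.5         # degrees
    rotatable_bonds: tuple = ((1, 2),)


@dataclass
class EnsembleSpec:
    n_frames: int = 200
    noise_sd: float = 0.05            # Angstrom, isotropic per atom
    dt_ps: float = 100.0
    two_state: dict | None = None     # {"translation": 3-vec, "probability": p}


#: default chi mixture: three well-separated rotamer states, kappa = 50
DEFAULT_ROTAMER_MIXTURE = (
    {"mean": (-70.0, 180.0, 65.0, 90.0), "kappa": 50.0, "weight": 1.0 / 3.0},
    {"mean": (-170.0, 65.0, -85.0, 180.0), "kappa": 50.0, "weight": 1.0 / 3.0},
    {"mean": (60.0, -60.0, 180.0, 0.0), "kappa": 50.0, "weight": 1.0 / 3.0},
)

#: default ΔG mixture: dominant tight-binding state plus a weak shoulder
DEFAULT_SCORE_MIXTURE = (
    {"mean": -11.0, "sd": 0.5, "weight": 0.7},
    {"mean": -6.0, "sd": 0.5, "weight": 0.3},
)


@dataclass
class SyntheticSpec:
    """Bundle of generator settings; a pure function of (spec, seed)."""

    seed: int = 0
    pocket: PocketSpec = field(default_factory=PocketSpec)
    ligand: LigandSpec = field(default_factory=LigandSpec)
    ensemble: EnsembleSpec = field(default_factory=EnsembleSpec)
    rotamer_mixture: tuple = DEFAULT_ROTAMER_MIXTURE
    spectrum_mixture: tuple = DEFAULT_SCORE_MIXTURE


def _check_mixture(mixture, keys) -> None:
    if not mixture:
        raise ValueError("mixture must contain at least one component")
    total = sum(c["weight"] for c in mixture)
    if abs(total - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    for c in mixture:
        for k in keys:
            if k not in c:
                raise ValueError(f"mixture component missing {k!r}")
        if c.get("sd", 1.0) <= 0 or c.get("kappa", 1.0) <= 0:
            raise ValueError("sds and concentrations must be positive")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistributed unit vectors."""
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _zigzag_chain(n: int, bond_length: float, bond_angle_deg: float) -> np.ndarray:
    """Planar zig-zag chain in the xy-plane, centered at the origin."""
    half = math.radians(bond_angle_deg) / 2.0
    step = np.array([bond_length * math.sin(half), bond_length * math.cos(half), 0.0])
    pts = [np.zeros(3)]
    for k in range(1, n):
        pts.append(pts[-1] + step * np.array([1.0, (-1.0) ** (k + 1), 1.0]))
    coords = np.array(pts)
    return coords - coords.mean(axis=0)


def make_toy_complex(spec: SyntheticSpec | None = None, seed: int | None = None,
                     p: EnergyParameters | None = None,
                     scan_half_width: float = 2.0,
                     scan_step: float = 0.25):
    """Build (receptor, ligand, torsion tree, certified optimum pose, score).

    Shell atoms sit on a sphere of ``cavity_radius``; four anchor atoms sit
    directly below the as-built ligand atoms at ``anchor_offset`` with
    charges complementary to the ligand's, so the as-built placement is in
    the optimum's basin.  The returned optimum is certified by an exhaustive
    translation scan at ``scan_step`` resolution within ±``scan_half_width``
    of the build position.
    """
    spec = spec or SyntheticSpec()
    if seed is None:
        seed = spec.seed
    p = p or EnergyParameters.default()
    pk, lg = spec.pocket, spec.ligand

    lig_coords = _zigzag_chain(lg.n_atoms, lg.bond_length, lg.bond_angle)
    lig_extent = float(np.max(np.linalg.norm(lig_coords, axis=1)))
    if lig_extent + 2.0 >= pk.cavity_radius:
        raise ValueError("ligand does not fit in the cavity with clearance")
    if len(lg.charges) != lg.n_atoms:
        raise ValueError("ligand charge list must match atom count")
    if len(pk.anchor_charges) != lg.n_atoms:
        raise ValueError("anchor charges must pair with ligand atoms")

    shell = _fibonacci_sphere(pk.n_shell_atoms) * pk.cavity_radius
    rec_atoms = []
    serial = 1
    for i, pos in enumerate(shell):
        rec_atoms.append(Atom(serial, f"S{i + 1}", "H", pk.atom_type, "PKT", 1, "A",
                              pos, pk.shell_charge * (-1.0) ** i))
        serial += 1
    k = 0
    for i, lpos in enumerate(lig_coords):
        for polar_deg, n_az in pk.site_rings:
            polar = math.radians(polar_deg)
            for j in range(n_az):
                phi = 2.0 * math.pi * j / n_az + (math.pi / n_az) * (i % 2)
                d = np.array([math.sin(polar) * math.cos(phi),
                              math.sin(polar) * math.sin(phi),
                              -math.cos(polar)])
                k += 1
                # the straight-down site of each cradle carries the charge
                charge = pk.anchor_charges[i] if polar_deg == 0.0 else 0.0
                rec_atoms.append(Atom(serial, f"M{k}", "Mg", pk.site_type, "CRD",
                                      2, "A", lpos + pk.site_radius * d, charge))
                serial += 1
    k = 0
    lattice = np.arange(-pk.slab_radius, pk.slab_radius + 1e-9, pk.slab_spacing)
    for z in pk.slab_z:
        for sx in lattice:
            for sy in lattice:
                if math.hypot(sx, sy) > pk.slab_radius:
                    continue
                k += 1
                rec_atoms.append(Atom(serial, f"S{k}", "Mg", pk.site_type, "SLB",
                                      3, "A", np.array([sx, sy, z]), 0.0))
                serial += 1
    receptor = Structure(rec_atoms, ["receptor"] * len(rec_atoms),
                         {"generator": "make_toy_complex", "seed": seed})

    lig_atoms = [
        Atom(i + 1, f"L{i + 1}", "C", lg.atom_type, "LIG", 1, "L",
             lig_coords[i], lg.charges[i], record="HETATM")
        for i in range(lg.n_atoms)
    ]
    ligand = Structure(lig_atoms, ["ligand"] * lg.n_atoms,
                       {"generator": "make_toy_complex", "seed": seed})
    tree = build_torsion_tree(ligand, list(lg.rotatable_bonds))

    offset = _scan_translations(receptor, ligand, p, scan_half_width, scan_step)
    opt_coords = lig_coords + offset
    opt_score = score_pose(receptor, ligand.with_coords(opt_coords), tree, p)
    pose = Pose(offset, IDENTITY_QUAT.copy(), np.zeros(tree.n_tor), opt_coords)
    return receptor, ligand, tree, pose, opt_score


def _scan_translations(receptor: Structure, ligand: Structure,
                       p: EnergyParameters, half_width: float,
                       step: float) -> np.ndarray:
    """Exhaustive rigid translation scan; returns the best offset.

    Vectorized: pair energies are evaluated for all (receptor atom, ligand
    atom, offset) distances at once.
    """
    ax = np.arange(-half_width, half_width + step / 2.0, step)
    offsets = np.array(np.meshgrid(ax, ax, ax, indexing="ij")).reshape(3, -1).T
    rec_xyz = receptor.coords
    lig_xyz = ligand.coords
    rec_q = receptor.charges
    lig_q = ligand.charges
    rec_types = receptor.atom_types
    lig_types = ligand.atom_types

    totals = np.zeros(len(offsets))
    for i, rt in enumerate(rec_types):
        for j, lt in enumerate(lig_types):
            d = np.linalg.norm(lig_xyz[j] + offsets - rec_xyz[i], axis=1)
            np.maximum(d, p.r_min, out=d)
            vdw, hb, el, ds = pair_energy(rt, lt, rec_q[i], lig_q[j], d, p)
            totals += vdw + hb + el + ds
    return offsets[int(np.argmin(totals))].copy()


def make_ensemble(receptor: Structure, ligand: Structure,
                  n_frames: int | None = None, noise_sd: float | None = None,
                  two_state: dict | None = None, seed: int = 0,
                  dt_ps: float = 100.0,
                  spec: EnsembleSpec | None = None) -> EnsembleTrajectory:
    """Noisy ensemble of the complex: base coordinates plus isotropic
    Gaussian noise; under ``two_state`` each frame independently adopts the
    displaced pose B with the stated probability, making the rescored ΔG
    distribution bimodal."""
    spec = spec or EnsembleSpec()
    n_frames = spec.n_frames if n_frames is None else n_frames
    noise_sd = spec.noise_sd if noise_sd is None else noise_sd
    two_state = spec.two_state if two_state is None else two_state
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")

    rng = np.random.default_rng(seed)
    base_atoms = receptor.atoms + ligand.atoms
    # re-serial so the merged complex keeps unique serials
    merged_atoms = []
    for k, a in enumerate(base_atoms, start=1):
        merged_atoms.append(Atom(k, a.name, a.element, a.atom_type, a.residue_name,
                                 a.residue_number, a.chain_id, a.position.copy(),
                                 a.partial_charge, a.occupancy, a.alt_loc, a.record))
    roles = list(receptor.role_labels) + list(ligand.role_labels)
    template = Structure(merged_atoms, roles, {"generator": "make_ensemble"})
    base = template.coords
    n_rec = len(receptor)

    pose_b = None
    p_b = 0.0
    if two_state is not None:
        p_b = float(two_state["probability"])
        if "coords" in two_state:
            pose_b = np.asarray(two_state["coords"], dtype=float)
        else:
            pose_b = base[n_rec:] + np.asarray(two_state["translation"], dtype=float)

    frames = []
    for i in range(n_frames):
        coords = base.copy()
        if pose_b is not None and rng.uniform() < p_b:
            coords[n_rec:] = pose_b
        coords += rng.normal(scale=noise_sd, size=coords.shape) if noise_sd > 0 else 0.0
        frames.append((dt_ps * (i + 1), template.with_coords(coords)))
    return EnsembleTrajectory(frames)


# ---------------------------------------------------------------------------
# rotamer trajectories

# ideal internal coordinates of an arginine-like side chain; only the
# dihedrals matter to the analyses, bond lengths/angles are fixed
_SIDECHAIN_ATOMS = ("N", "CA", "CB", "CG", "CD", "NE", "CZ")
_SIDECHAIN_BONDS = {"CB-CG": 1.52, "CG-CD": 1.52, "CD-NE": 1.46, "NE-CZ": 1.33}
_SIDECHAIN_ANGLES = {"CA-CB-CG": 114.1, "CB-CG-CD": 111.3,
                     "CG-CD-NE": 111.5, "CD-NE-CZ": 124.2}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (z-matrix) placement of atom d from a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _realize_sidechain(chi: np.ndarray) -> dict[str, np.ndarray]:
    """Coordinates of an ideal arginine-like side chain at the given chi."""
    coords = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
    }
    # CB at the ideal N-CA-CB angle in the xy-plane
    ang = math.radians(180.0 - 111.0)
    coords["CB"] = coords["CA"] + 1.53 * np.array([math.cos(ang), math.sin(ang), 0.0])
    chain = [("CG", "N", "CA", "CB", _SIDECHAIN_BONDS["CB-CG"],
              _SIDECHAIN_ANGLES["CA-CB-CG"]),
             ("CD", "CA", "CB", "CG", _SIDECHAIN_BONDS["CG-CD"],
              _SIDECHAIN_ANGLES["CB-CG-CD"]),
             ("NE", "CB", "CG", "CD", _SIDECHAIN_BONDS["CD-NE"],
              _SIDECHAIN_ANGLES["CG-CD-NE"]),
             ("CZ", "CG", "CD", "NE", _SIDECHAIN_BONDS["NE-CZ"],
              _SIDECHAIN_ANGLES["CD-NE-CZ"])]
    for (name, a, b, c, bond, angle), torsion in zip(chain, chi):
        coords[name] = _place_atom(coords[a], coords[b], coords[c],
                                   bond, angle, torsion)
    return coords


def make_rotamer_trajectory(mixture=DEFAULT_ROTAMER_MIXTURE, n_frames: int = 900,
                            seed: int = 0, dt_ps: float = 100.0,
                            residue_id: tuple[str, int, str] = ("A", 1, "ARG")):
    """Draw chi series from a circular mixture and realize coordinates.

    Per frame a component is chosen by weight and each chi is drawn from a
    von Mises distribution around the component mean.  Returns
    ``(DihedralSeries, frame coordinate dicts, component labels)``; the
    coordinates come from an ideal side-chain template so re-measuring the
    dihedrals reproduces the drawn angles.
    """
    _check_mixture(mixture, ("mean", "kappa", "weight"))
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    arity = len(mixture[0]["mean"])
    if any(len(c["mean"]) != arity for c in mixture):
        raise ValueError("all mixture components must share chi arity")

    rng = np.random.default_rng(seed)
    weights = np.array([c["weight"] for c in mixture])
    labels = rng.choice(len(mixture), size=n_frames, p=weights)
    chi = np.empty((n_frames, arity))
    for i, lab in enumerate(labels):
        comp = mixture[lab]
        for k in range(arity):
            draw = vonmises.rvs(comp["kappa"], loc=math.radians(comp["mean"][k]),
                                random_state=rng)
            chi[i, k] = wrap_angle(math.degrees(draw))

    times = dt_ps * (np.arange(n_frames) + 1)
    quadruples = [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
                  ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")][:arity]
    series = DihedralSeries(residue_id, chi, times, quadruples)
    coords = [_realize_sidechain(row) for row in chi] if arity == 4 else None
    return series, coords, labels


def rotamer_trajectory_as_ensemble(series: DihedralSeries,
                                   coords: list[dict[str, np.ndarray]]) -> EnsembleTrajectory:
    """Package realized side-chain frames as an ensemble for the extraction
    and clustering entry points that read trajectories."""
    chain, resnum, resname = series.residue_id
    frames = []
    for t, frame_coords in zip(series.frame_times, coords):
        atoms = []
        for k, name in enumerate(_SIDECHAIN_ATOMS, start=1):
            element = name[0]
            atoms.append(Atom(k, name, element, element, resname, resnum, chain,
                              frame_coords[name]))
        frames.append((float(t), Structure(atoms, ["receptor"] * len(atoms))))
    return EnsembleTrajectory(frames)


def make_score_samples(mixture=DEFAULT_SCORE_MIXTURE, n: int = 500,
                       seed: int = 0) -> np.ndarray:
    """i.i.d. ΔG draws (kcal/mol) from a Gaussian mixture."""
    _check_mixture(mixture, ("mean", "sd", "weight"))
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.array([c["weight"] for c in mixture])
    labels = rng.choice(len(mixture), size=n, p=weights)
    means = np.array([mixture[k]["mean"] for k in labels])
    sds = np.array([mixture[k]["sd"] for k in labels])
    return means + rng.normal(size=n) * sds
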