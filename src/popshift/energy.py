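"""Semi-empirical pairwise binding free-energy function and affinity grids.

The functional form is the AutoDock4-family scoring function: weighted
Lennard-Jones 12-6 dispersion/repulsion, a 12-10 hydrogen-bond well between
donor and acceptor atom types, screened Coulomb electrostatics with a
sigmoidal distance-dependent dielectric, a Gaussian-shell pairwise
desolvation term, and a torsional entropy penalty proportional to the number
of active rotatable bonds:

    ΔG = W_vdw Σ (A_ij/r^12 − B_ij/r^6)
       + W_hbond Σ (C_ij/r^12 − D_ij/r^10)
       + W_elec Σ q_i q_j · 332.06 / (ε(r) r)
       + W_desolv Σ (S_i V_j + S_j V_i) e^{−r²/2σ²}
       + W_tor · N_tor

Pair coefficients derive from per-type equilibrium distances and well
depths: A = ε r_eq^12, B = 2 ε r_eq^6 (minimum −ε at r_eq), and
C = 5 ε_hb r_hb^12, D = 6 ε_hb r_hb^10 for the 12-10 well.

Grids tabulate each term on a regular lattice per ligand atom type so a
pose can be scored by trilinear interpolation instead of an explicit pair
sum; the two routes agree exactly at grid nodes.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.distance import cdist

from popshift.structure_io import Structure, TorsionTree

#: gas constant, kcal/(mol K)
R_GAS = 1.9872e-3
#: default absolute temperature, K
T_DEFAULT = 298.15
#: Coulomb conversion factor, kcal Angstrom / (mol e^2)
ELEC_CONST = 332.06

HB_CLASSES = ("none", "donor", "acceptor", "both")


class ParameterError(ValueError):
    """Invalid energy parameters or unknown atom type."""


class OutOfBoxError(ValueError):
    """A ligand atom lies outside the grid box."""


@dataclass(frozen=True)
class TypeParams:
    """Per-atom-type nonbonded parameters."""

    type: str
    r_eq: float        # self-pair equilibrium distance, Angstrom
    eps: float         # well depth, kcal/mol
    vol: float         # solvation volume, Angstrom^3
    solpar: float      # solvation parameter
    hb_class: str = "none"
    hb_r_eq: float = 0.0
    hb_eps: float = 0.0


@dataclass
class EnergyParameters:
    """Scoring-function parameters: per-type table, term weights, dielectric
    model, desolvation width and thermodynamic constants."""

    types: dict[str, TypeParams]
    w_vdw: float = 0.1662
    w_hbond: float = 0.1209
    w_elec: float = 0.1406
    w_desolv: float = 0.1322
    w_tor: float = 0.2983
    sigma: float = 3.5            # desolvation Gaussian width, Angstrom
    a_eps: float = -8.5525        # sigmoidal dielectric parameters
    eps0: float = 78.4
    k_eps: float = 7.7839
    lambda_eps: float = 0.003627
    r_gas: float = R_GAS
    temperature: float = T_DEFAULT
    elec_const: float = ELEC_CONST
    energy_clamp: float = 1.0e5   # per-term upper clamp, kcal/mol
    r_min: float = 0.01           # minimum pair distance, Angstrom

    def __post_init__(self) -> None:
        for w in (self.w_vdw, self.w_hbond, self.w_elec, self.w_desolv, self.w_tor):
            if w < 0:
                raise ParameterError("term weights must be nonnegative")
        if self.sigma <= 0:
            raise ParameterError("desolvation width sigma must be positive")
        self._pair_cache: dict[tuple[str, str], tuple] = {}

    @classmethod
    def from_table(cls, path: str | Path, **overrides) -> "EnergyParameters":
        """Load a plain-text per-type parameter table.

        Rows: ``type r_eq eps vol solpar hb_class hb_r_eq hb_eps``; ``#``
        starts a comment.
        """
        types: dict[str, TypeParams] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 8:
                raise ParameterError(f"{path}:{lineno}: expected 8 fields, got {len(fields)}")
            t, r_eq, eps, vol, solpar, hb, hb_r, hb_e = fields
            if hb not in HB_CLASSES:
                raise ParameterError(f"{path}:{lineno}: unknown hbond class {hb!r}")
            types[t] = TypeParams(t, float(r_eq), float(eps), float(vol),
                                  float(solpar), hb, float(hb_r), float(hb_e))
        return cls(types, **overrides)

    @classmethod
    def default(cls, **overrides) -> "EnergyParameters":
        """Parameters from the bundled standard atom-type table."""
        with importlib.resources.as_file(
                importlib.resources.files("popshift") / "data" / "standard.par") as p:
            return cls.from_table(p, **overrides)

    # -- type-pair coefficients --------------------------------------------

    def require_type(self, t: str) -> TypeParams:
        try:
            return self.types[t]
        except KeyError:
            raise ParameterError(f"atom type {t!r} not in the active parameter table") from None

    def is_hbond_pair(self, ti: str, tj: str) -> bool:
        ci = self.require_type(ti).hb_class
        cj = self.require_type(tj).hb_class
        donor_i = ci in ("donor", "both")
        donor_j = cj in ("donor", "both")
        acc_i = ci in ("acceptor", "both")
        acc_j = cj in ("acceptor", "both")
        return (donor_i and acc_j) or (donor_j and acc_i)

    def pair_coefficients(self, ti: str, tj: str):
        """(A, B, C, D, desolv_prefactor) for a type pair, cached."""
        key = (ti, tj)
        cached = self._pair_cache.get(key)
        if cached is not None:
            return cached
        pi, pj = self.require_type(ti), self.require_type(tj)
        r_eq = 0.5 * (pi.r_eq + pj.r_eq)
        eps = math.sqrt(pi.eps * pj.eps)
        a = eps * r_eq ** 12
        b = 2.0 * eps * r_eq ** 6
        c = d = 0.0
        if self.is_hbond_pair(ti, tj):
            # the acceptor side carries the 12-10 well parameters
            acc = pj if pj.hb_class in ("acceptor", "both") else pi
            if acc.hb_r_eq > 0 and acc.hb_eps > 0:
                c = 5.0 * acc.hb_eps * acc.hb_r_eq ** 12
                d = 6.0 * acc.hb_eps * acc.hb_r_eq ** 10
        desolv_pref = pi.solpar * pj.vol + pj.solpar * pi.vol
        out = (a, b, c, d, desolv_pref)
        self._pair_cache[key] = out
        self._pair_cache[(tj, ti)] = (a, b, c, d, desolv_pref)
        return out


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-term binding free energies (kcal/mol) summing to ``total_dg``."""

    vdw: float
    hbond: float
    elec: float
    desolv: float
    torsional_penalty: float
    warnings: tuple[str, ...] = ()

    @property
    def total_dg(self) -> float:
        return self.vdw + self.hbond + self.elec + self.desolv + self.torsional_penalty

    def as_dict(self) -> dict:
        return {
            "vdw": self.vdw,
            "hbond": self.hbond,
            "elec": self.elec,
            "desolv": self.desolv,
            "torsional_penalty": self.torsional_penalty,
            "total_dg": self.total_dg,
        }


def dielectric(r, p: EnergyParameters):
    """Sigmoidal distance-dependent dielectric ε(r), monotone nondecreasing.

    ε(r) = A + (ε0 − A) / (1 + k exp(−λ (ε0 − A) r))
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be nonnegative")
    b = p.eps0 - p.a_eps
    out = p.a_eps + b / (1.0 + p.k_eps * np.exp(-p.lambda_eps * b * r))
    return out if out.shape else float(out)


def pair_energy(type_i: str, type_j: str, q_i: float, q_j: float, r,
                p: EnergyParameters):
    """Per-term pairwise energies (vdw, hbond, elec, desolv), vectorized in r.

    Distances are floored at ``p.r_min`` and each term is clamped at
    ``p.energy_clamp`` so clashed geometries stay finite.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    rc = np.maximum(r, p.r_min)
    a, b, c, d, desolv_pref = p.pair_coefficients(type_i, type_j)
    inv2 = 1.0 / (rc * rc)
    inv6 = inv2 ** 3
    inv10 = inv6 * inv2 ** 2
    inv12 = inv6 * inv6
    vdw = p.w_vdw * (a * inv12 - b * inv6)
    if c or d:
        hbond = p.w_hbond * (c * inv12 - d * inv10)
    else:
        hbond = np.zeros_like(rc)
    elec = p.w_elec * q_i * q_j * p.elec_const / (dielectric(rc, p) * rc)
    desolv = p.w_desolv * desolv_pref * np.exp(-rc * rc / (2.0 * p.sigma ** 2))
    clamp = p.energy_clamp
    vdw = np.minimum(vdw, clamp)
    hbond = np.minimum(hbond, clamp)
    elec = np.minimum(elec, clamp)
    desolv = np.minimum(desolv, clamp)
    if vdw.shape:
        return vdw, hbond, elec, desolv
    return float(vdw), float(hbond), float(elec), float(desolv)


def _receptor_indices(receptor: Structure, include_ions: bool,
                      include_waters: bool) -> np.ndarray:
    roles = ["receptor"]
    if include_ions:
        roles.append("ion")
    if include_waters:
        roles.append("water")
    idx = receptor.role_indices(*roles)
    if len(idx) == 0:
        raise ParameterError("no receptor atoms selected for scoring")
    return idx


def score_pose(receptor: Structure, ligand: Structure,
               tree: TorsionTree | None, p: EnergyParameters,
               include_ions: bool = False,
               include_waters: bool = False) -> ScoreBreakdown:
    """Sum pairwise energies over all receptor-ligand atom pairs.

    No distance cutoff is applied.  Ions and waters carried in the receptor
    structure are excluded by default.  Atom pairs closer than ``p.r_min``
    are scored with clamped energies and flagged in the breakdown warnings.
    """
    rec_idx = _receptor_indices(receptor, include_ions, include_waters)
    lig_idx = np.arange(len(ligand))

    rec_types = [receptor.atoms[i].atom_type for i in rec_idx]
    lig_types = [ligand.atoms[i].atom_type for i in lig_idx]
    for t in set(rec_types) | set(lig_types):
        p.require_type(t)

    rec_xyz = receptor.coords[rec_idx]
    lig_xyz = ligand.coords
    rec_q = receptor.charges[rec_idx]
    lig_q = ligand.charges

    dmat = cdist(rec_xyz, lig_xyz)
    warnings_list: list[str] = []
    clash = np.argwhere(dmat < p.r_min)
    for ri, li in clash:
        warnings_list.append(
            f"clash: receptor atom {receptor.atoms[rec_idx[ri]].serial} / "
            f"ligand atom {ligand.atoms[li].serial} at r={dmat[ri, li]:.4f} A")
    dmat = np.maximum(dmat, p.r_min)

    vdw = hbond = elec = desolv = 0.0
    # group pairs by (receptor type, ligand type) for vectorized evaluation
    rec_by_type: dict[str, np.ndarray] = {}
    for t in set(rec_types):
        rec_by_type[t] = np.array([k for k, tt in enumerate(rec_types) if tt == t])
    lig_by_type: dict[str, np.ndarray] = {}
    for t in set(lig_types):
        lig_by_type[t] = np.array([k for k, tt in enumerate(lig_types) if tt == t])

    for rt, rrows in rec_by_type.items():
        for lt, lcols in lig_by_type.items():
            r = dmat[np.ix_(rrows, lcols)].ravel()
            qprod = np.outer(rec_q[rrows], lig_q[lcols]).ravel()
            a, b, c, d, desolv_pref = p.pair_coefficients(rt, lt)
            inv2 = 1.0 / (r * r)
            inv6 = inv2 ** 3
            inv12 = inv6 * inv6
            vdw += np.minimum(p.w_vdw * (a * inv12 - b * inv6), p.energy_clamp).sum()
            if c or d:
                inv10 = inv6 * inv2 ** 2
                hbond += np.minimum(p.w_hbond * (c * inv12 - d * inv10),
                                    p.energy_clamp).sum()
            elec += np.minimum(
                p.w_elec * qprod * p.elec_const / (dielectric(r, p) * r),
                p.energy_clamp).sum()
            desolv += np.minimum(
                p.w_desolv * desolv_pref * np.exp(-r * r / (2.0 * p.sigma ** 2)),
                p.energy_clamp).sum()

    n_tor = tree.n_tor if tree is not None else 0
    return ScoreBreakdown(float(vdw), float(hbond), float(elec), float(desolv),
                          p.w_tor * n_tor, tuple(warnings_list))


# ---------------------------------------------------------------------------
# affinity grids


@dataclass
class GridBox:
    """Regular lattice of per-term receptor fields for fast pose scoring.

    ``vdw_maps``, ``hbond_maps`` and ``desolv_maps`` are keyed by ligand atom
    type; ``elec_map`` is the screened electrostatic potential per unit
    ligand charge.  Term weights are baked into the map values.
    """

    center: np.ndarray
    spacing: float
    npts: tuple[int, int, int]
    vdw_maps: dict[str, np.ndarray]
    hbond_maps: dict[str, np.ndarray]
    desolv_maps: dict[str, np.ndarray]
    elec_map: np.ndarray
    _interp_cache: dict = field(default_factory=dict, repr=False)

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.center[k] + (np.arange(self.npts[k]) - (self.npts[k] - 1) / 2.0)
            * self.spacing
            for k in range(3)
        )

    @property
    def lower(self) -> np.ndarray:
        return np.array([ax[0] for ax in self.axes])

    @property
    def upper(self) -> np.ndarray:
        return np.array([ax[-1] for ax in self.axes])

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= self.lower + margin) & (pts <= self.upper - margin),
                      axis=1)

    def interpolator(self, kind: str, atom_type: str | None = None):
        key = (kind, atom_type)
        if key not in self._interp_cache:
            if kind == "elec":
                values = self.elec_map
            else:
                values = {"vdw": self.vdw_maps, "hbond": self.hbond_maps,
                          "desolv": self.desolv_maps}[kind][atom_type]
            self._interp_cache[key] = RegularGridInterpolator(
                self.axes, values, method="linear", bounds_error=True)
        return self._interp_cache[key]


def make_grid_box(receptor: Structure, spacing: float,
                  npts: Sequence[int], p: EnergyParameters,
                  ligand_types: Iterable[str],
                  center: Sequence[float] | None = None,
                  center_selection: Sequence[int] | None = None,
                  include_ions: bool = False,
                  include_waters: bool = False) -> GridBox:
    """Tabulate per-type affinity, electrostatic and desolvation fields.

    ``center`` gives an explicit box center; otherwise the geometric center
    of ``center_selection`` (default: all scored receptor atoms) is used.
    The box edge along each axis is ``(npts - 1) * spacing``.
    """
    npts = tuple(int(n) for n in npts)
    if spacing <= 0:
        raise ParameterError("grid spacing must be positive")
    if len(npts) != 3 or any(n < 2 for n in npts):
        raise ParameterError("npts must be three integers >= 2")
    rec_idx = _receptor_indices(receptor, include_ions, include_waters)
    if center is None:
        sel = list(center_selection) if center_selection is not None else list(rec_idx)
        if not sel:
            raise ParameterError("empty selection for geometric box center")
        center = receptor.geometric_center(sel)
    center = np.asarray(center, dtype=float)

    ligand_types = sorted(set(ligand_types))
    for t in ligand_types:
        p.require_type(t)

    axes = tuple(
        center[k] + (np.arange(npts[k]) - (npts[k] - 1) / 2.0) * spacing
        for k in range(3)
    )
    shape = npts
    vdw_maps = {t: np.zeros(shape) for t in ligand_types}
    hbond_maps = {t: np.zeros(shape) for t in ligand_types}
    desolv_maps = {t: np.zeros(shape) for t in ligand_types}
    elec_map = np.zeros(shape)

    for i in rec_idx:
        atom = receptor.atoms[i]
        ax2 = (axes[0] - atom.position[0]) ** 2
        ay2 = (axes[1] - atom.position[1]) ** 2
        az2 = (axes[2] - atom.position[2]) ** 2
        r2 = ax2[:, None, None] + ay2[None, :, None] + az2[None, None, :]
        r = np.sqrt(r2)
        np.maximum(r, p.r_min, out=r)
        inv2 = 1.0 / (r * r)
        inv6 = inv2 ** 3
        inv12 = inv6 * inv6
        gauss = np.exp(-r * r / (2.0 * p.sigma ** 2))
        elec_map += np.minimum(
            p.w_elec * atom.partial_charge * p.elec_const / (dielectric(r, p) * r),
            p.energy_clamp)
        for t in ligand_types:
            a, b, c, d, desolv_pref = p.pair_coefficients(t, atom.atom_type)
            vdw_maps[t] += np.minimum(p.w_vdw * (a * inv12 - b * inv6),
                                      p.energy_clamp)
            if c or d:
                inv10 = inv6 * inv2 ** 2
                hbond_maps[t] += np.minimum(p.w_hbond * (c * inv12 - d * inv10),
                                            p.energy_clamp)
            desolv_maps[t] += np.minimum(p.w_desolv * desolv_pref * gauss,
                                         p.energy_clamp)

    return GridBox(center, float(spacing), npts, vdw_maps, hbond_maps,
                   desolv_maps, elec_map)


def grid_score(box: GridBox, ligand: Structure, tree: TorsionTree | None,
               p: EnergyParameters) -> ScoreBreakdown:
    """Score a ligand pose by trilinear interpolation of the grid maps.

    Matches :func:`score_pose` exactly at grid nodes.  A ligand atom outside
    the box raises :class:`OutOfBoxError` naming the atom.
    """
    coords = ligand.coords
    inside = box.contains(coords)
    if not np.all(inside):
        k = int(np.argmin(inside))
        atom = ligand.atoms[k]
        raise OutOfBoxError(
            f"ligand atom {atom.serial} ({atom.name}) at "
            f"{np.round(coords[k], 3).tolist()} lies outside the grid box")

    vdw = hbond = elec = desolv = 0.0
    by_type: dict[str, list[int]] = {}
    for k, atom in enumerate(ligand.atoms):
        by_type.setdefault(atom.atom_type, []).append(k)
    charges = ligand.charges
    for t, idx in by_type.items():
        if t not in box.vdw_maps:
            raise ParameterError(f"no grid maps for ligand atom type {t!r}")
        pts = coords[idx]
        vdw += float(box.interpolator("vdw", t)(pts).sum())
        if np.any(box.hbond_maps[t]):
            hbond += float(box.interpolator("hbond", t)(pts).sum())
        desolv += float(box.interpolator("desolv", t)(pts).sum())
        elec += float((charges[idx] * box.interpolator("elec")(pts)).sum())

    n_tor = tree.n_tor if tree is not None else 0
    return ScoreBreakdown(vdw, hbond, elec, desolv, p.w_tor * n_tor)


def save_grid(box: GridBox, path: str | Path) -> None:
    """Persist grid maps as plain text: a header (center, spacing, npts, map
    names) followed by node values in x-fastest order."""
    lines = [
        f"CENTER {box.center[0]:.6f} {box.center[1]:.6f} {box.center[2]:.6f}",
        f"SPACING {box.spacing:.6f}",
        f"NPTS {box.npts[0]} {box.npts[1]} {box.npts[2]}",
    ]
    maps: list[tuple[str, np.ndarray]] = [("elec", box.elec_map)]
    for t in sorted(box.vdw_maps):
        maps.append((f"vdw:{t}", box.vdw_maps[t]))
        maps.append((f"hbond:{t}", box.hbond_maps[t]))
        maps.append((f"desolv:{t}", box.desolv_maps[t]))
    lines.append("MAPS " + " ".join(name for name, _ in maps))
    for name, values in maps:
        lines.append(f"MAP {name}")
        # x-fastest: transpose so x varies quickest in the flattened order
        lines.extend(f"{v:.9g}" for v in values.transpose(2, 1, 0).ravel())
    Path(path).write_text("\n".join(lines) + "\n")


def load_grid(path: str | Path) -> GridBox:
    lines = Path(path).read_text().splitlines()
    center = np.array([float(x) for x in lines[0].split()[1:4]])
    spacing = float(lines[1].split()[1])
    npts = tuple(int(x) for x in lines[2].split()[1:4])
    n_nodes = npts[0] * npts[1] * npts[2]
    vdw_maps: dict[str, np.ndarray] = {}
    hbond_maps: dict[str, np.ndarray] = {}
    desolv_maps: dict[str, np.ndarray] = {}
    elec_map = np.zeros(npts)
    i = 4
    while i < len(lines):
        assert lines[i].startswith("MAP ")
        name = lines[i].split()[1]
        vals = np.array([float(v) for v in lines[i + 1:i + 1 + n_nodes]])
        arr = vals.reshape(npts[2], npts[1], npts[0]).transpose(2, 1, 0)
        if name == "elec":
            elec_map = arr
        else:
            kind, t = name.split(":")
            {"vdw": vdw_maps, "hbond": hbond_maps, "desolv": desolv_maps}[kind][t] = arr
        i += 1 + n_nodes
    return GridBox(center, spacing, npts, vdw_maps, hbond_maps, desolv_maps, elec_map)


def delta_g_to_ki(dg: float, temperature: float = T_DEFAULT) -> float:
    """Boltzmann conversion of a binding free energy to an inhibition
    constant in molar units: Ki = exp(ΔG / RT)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(dg / (R_GAS * temperature))
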