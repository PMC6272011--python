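"""Side-chain chi dihedral extraction, circular statistics and rotamer
clustering.

A rotamer is the discrete conformational state defined by the successive
side-chain torsions chi1..chi4 (four for arginine).  Frames from one or
several trajectories are pooled, pairwise distances are measured with a
periodic root-mean-square dihedral deviation, and average-linkage
agglomerative clustering cut at a fixed angle yields the rotamer states and
their populations.  Cluster centroids are medoid frames, so the reported
centroid dihedrals always belong to an actually sampled conformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from popshift.structure_io import EnsembleTrajectory, StructureError

#: chi atom-name quadruples per residue type (extend via the
#: ``definitions`` argument of :func:`extract_chi_series`)
CHI_DEFINITIONS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "MET": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "SD"),
        ("CB", "CG", "SD", "CE"),
    ],
}


@dataclass
class DihedralSeries:
    """Per-frame chi tuples (degrees, in (-180, 180]) for one residue."""

    residue_id: tuple[str, int, str]
    chi: np.ndarray               # (n_frames, n_chi) degrees
    frame_times: np.ndarray       # ps
    atom_quadruples: list[tuple[str, str, str, str]]

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.chi.ndim != 2:
            raise ValueError("chi must be a (n_frames, n_chi) array")
        if np.any(self.chi <= -180.0) or np.any(self.chi > 180.0):
            raise ValueError("chi angles must lie in (-180, 180]")
        if self.chi.shape[1] != len(self.atom_quadruples):
            raise ValueError("chi arity must match the atom quadruples")
        if len(self.frame_times) != self.chi.shape[0]:
            raise ValueError("frame time count must match chi rows")

    @property
    def n_frames(self) -> int:
        return self.chi.shape[0]


@dataclass
class RotamerClustering:
    """Partition of pooled frames into rotamer clusters.

    Cluster ids are dense from 1 and numbered by decreasing population.
    """

    assignments: np.ndarray                 # (n_frames,) cluster ids
    centroids: list[tuple[int, np.ndarray]]  # (frame index, chi tuple) per cluster
    populations: np.ndarray                 # fraction per cluster
    linkage_cutoff: float                   # degrees

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        self.populations = np.asarray(self.populations, dtype=float)
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")
        ids = sorted(set(self.assignments.tolist()))
        if ids != list(range(1, len(self.centroids) + 1)):
            raise ValueError("cluster ids must be dense from 1")
        for cid, (frame, _) in enumerate(self.centroids, start=1):
            if self.assignments[frame] != cid:
                raise ValueError(f"centroid frame of cluster {cid} not in its cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def wrap_angle(a):
    """Map angles (degrees) into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out if out.shape else float(out)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion of p1-p2-p3-p4 about p2-p3, degrees in (-180, 180].

    IUPAC sign convention via the standard atan2 construction: looking from
    p2 to p3, a clockwise rotation of p4 relative to p1 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-9:
            raise ValueError("consecutive points coincide; dihedral undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("three consecutive points are collinear; dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def extract_chi_series(traj: EnsembleTrajectory,
                       residue_id: tuple[str, int, str],
                       definitions: dict | None = None) -> DihedralSeries:
    """Measure the chi dihedrals of one residue in every frame.

    ``residue_id`` is (chain, residue number, residue name); the chi atom
    quadruples come from the built-in table unless overridden.
    """
    chain, resnum, resname = residue_id
    defs = (definitions or CHI_DEFINITIONS).get(resname.upper())
    if defs is None:
        raise StructureError(f"no chi definitions for residue type {resname!r}")

    chis = []
    for i, (_, frame) in enumerate(traj.frames):
        atom_map = {
            a.name: a.position
            for a in frame.atoms
            if a.chain_id == chain and a.residue_number == resnum
            and a.residue_name.upper() == resname.upper()
        }
        if not atom_map:
            raise StructureError(f"frame {i}: residue {residue_id} not found")
        row = []
        for quad in defs:
            for name in quad:
                if name not in atom_map:
                    raise StructureError(
                        f"frame {i}: residue {residue_id} is missing atom {name}")
            row.append(dihedral(*(atom_map[name] for name in quad)))
        chis.append(row)
    return DihedralSeries(residue_id, np.array(chis), traj.times, list(defs))


def angular_histogram(angles: Sequence[float], bin_width: float = 10.0,
                      peak_fraction: float = 0.25):
    """Circular histogram on (-180, 180] with wraparound-aware peaks.

    Returns (bin centers, densities, peaks).  Density integrates to 1 over
    the 360-degree circle.  Peaks are plateau-aware circular local maxima at
    or above ``peak_fraction`` of the global maximum; each peak is reported
    as the circular mean angle of its plateau bins.  A flat distribution has
    no peak.
    """
    angles = np.asarray(list(angles), dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle list")
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError("bin width must divide 360")
    wrapped = wrap_angle(angles)
    # histogram the circle on [-180, 180); +180 is identified with -180
    folded = np.where(wrapped == 180.0, -180.0, wrapped)
    n_bins = int(round(360.0 / bin_width))
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    densities, _ = np.histogram(folded, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    threshold = peak_fraction * densities.max()
    peaks: list[float] = []
    if densities.max() > 0:
        # maximal circular runs of equal density
        visited = np.zeros(n_bins, dtype=bool)
        for start in range(n_bins):
            if visited[start]:
                continue
            run = [start]
            visited[start] = True
            nxt = (start + 1) % n_bins
            while nxt != start and densities[nxt] == densities[start]:
                run.append(nxt)
                visited[nxt] = True
                nxt = (nxt + 1) % n_bins
            prev = (start - 1) % n_bins
            while prev not in run and densities[prev] == densities[start]:
                run.insert(0, prev)
                visited[prev] = True
                prev = (prev - 1) % n_bins
            if len(run) == n_bins:
                continue  # flat: no peak
            left = (run[0] - 1) % n_bins
            right = (run[-1] + 1) % n_bins
            d = densities[start]
            if d >= threshold and d > densities[left] and d > densities[right]:
                rad = np.radians(centers[run])
                mean = np.degrees(np.arctan2(np.mean(np.sin(rad)),
                                             np.mean(np.cos(rad))))
                peaks.append(float(wrap_angle(mean)))
    return centers, densities, sorted(peaks)


def dihedral_rmsd(chi_a: Sequence[float], chi_b: Sequence[float]) -> float:
    """Periodic RMS deviation between two chi tuples, degrees.

    Each component difference is reduced to the shorter arc,
    min(|d|, 360 - |d|), before averaging.
    """
    a = np.asarray(chi_a, dtype=float)
    b = np.asarray(chi_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("chi tuples must have equal length")
    d = np.abs(a - b) % 360.0
    d = np.minimum(d, 360.0 - d)
    return float(np.sqrt(np.mean(d * d)))


def _pairwise_dihedral_rmsd(chi: np.ndarray) -> np.ndarray:
    """Condensed periodic-RMSD distance matrix over frames."""
    d = np.abs(chi[:, None, :] - chi[None, :, :]) % 360.0
    d = np.minimum(d, 360.0 - d)
    full = np.sqrt(np.mean(d * d, axis=2))
    return squareform(full, checks=False)


def cluster_rotamers(series_list: Sequence[DihedralSeries],
                     cutoff: float = 40.0) -> RotamerClustering:
    """Pool frames from all series and cluster them into rotamer states.

    Average-linkage agglomerative clustering under the periodic dihedral
    RMSD, cut at ``cutoff`` degrees.  The centroid of a cluster is its
    medoid frame; clusters are numbered by decreasing population.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not series_list:
        raise ValueError("at least one dihedral series is required")
    arity = series_list[0].chi.shape[1]
    if any(s.chi.shape[1] != arity for s in series_list):
        raise ValueError("all series must share the same chi arity")
    chi = np.vstack([s.chi for s in series_list])
    n = chi.shape[0]
    if n == 1:
        return RotamerClustering(np.array([1]), [(0, chi[0].copy())],
                                 np.array([1.0]), cutoff)

    condensed = _pairwise_dihedral_rmsd(chi)
    z = linkage(condensed, method="average")
    raw = fcluster(z, t=cutoff, criterion="distance")

    full = squareform(condensed, checks=False)
    # order clusters by decreasing population; break ties by first frame
    labels = sorted(set(raw.tolist()))
    stats = []
    for lab in labels:
        members = np.flatnonzero(raw == lab)
        stats.append((len(members), -members[0], lab, members))
    stats.sort(key=lambda s: (-s[0], s[1]))

    assignments = np.zeros(n, dtype=int)
    centroids: list[tuple[int, np.ndarray]] = []
    populations = []
    for new_id, (count, _, _, members) in enumerate(stats, start=1):
        assignments[members] = new_id
        sub = full[np.ix_(members, members)]
        medoid = members[int(np.argmin(sub.sum(axis=1)))]
        centroids.append((int(medoid), chi[medoid].copy()))
        populations.append(count / n)
    return RotamerClustering(assignments, centroids, np.array(populations), cutoff)


def match_to_reference(clustering: RotamerClustering,
                       references: Sequence[dict],
                       centroid_coords: Sequence[dict] | None = None) -> list[dict]:
    """Pair each cluster centroid with its nearest reference conformation.

    Each reference is a dict with a ``name``, optionally ``chi`` (a tuple of
    degrees) and optionally ``coords`` (atom name -> 3-vector).  Matching
    uses the periodic dihedral metric when chi tuples are available;
    otherwise the Cartesian side-chain RMSD.  When centroid coordinates are
    supplied (one dict per cluster), the heavy-atom RMSD to the matched
    reference is reported alongside the dihedral RMSD.
    """
    if not references:
        raise ValueError("at least one reference is required")
    out = []
    for cid, (frame, chi) in enumerate(clustering.centroids, start=1):
        best = None
        for ref in references:
            dihedral_dist = None
            cart_dist = None
            if "chi" in ref and ref["chi"] is not None:
                dihedral_dist = dihedral_rmsd(chi, ref["chi"])
            if ("coords" in ref and ref["coords"] is not None
                    and centroid_coords is not None):
                cc = centroid_coords[cid - 1]
                shared = sorted(set(cc) & set(ref["coords"]))
                shared = [name for name in shared if not name.startswith("H")]
                if shared:
                    a = np.array([cc[name] for name in shared], dtype=float)
                    b = np.array([ref["coords"][name] for name in shared], dtype=float)
                    cart_dist = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
                else:
                    warnings.warn(
                        f"cluster {cid} / reference {ref.get('name')}: no shared "
                        "heavy atoms; falling back to the dihedral metric")
            key = dihedral_dist if dihedral_dist is not None else cart_dist
            if key is None:
                raise ValueError(
                    f"reference {ref.get('name')!r} offers neither chi nor "
                    "comparable coordinates")
            if best is None or key < best["distance"]:
                best = {
                    "cluster": cid,
                    "reference": ref.get("name"),
                    "distance": key,
                    "dihedral_rmsd_deg": dihedral_dist,
                    "cartesian_rmsd_A": cart_dist,
                }
        out.append(best)
    return out
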