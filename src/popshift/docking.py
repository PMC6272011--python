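"""Three evaluation tiers for a ligand in a rigid pocket.

* :func:`rescore` — score the pose exactly as given (tier 1);
* :func:`refine` — stochastic local descent confined to small bounds around
  the input pose (tier 2);
* :func:`dock` — multi-start search over the grid box: random placements,
  each followed by local descent, pooled and clustered by pose RMSD (tier 3).

A pose is parameterized as a rigid-body translation, a unit quaternion
applied about the ligand centroid, and one angle per rotatable bond.  The
identity pose reproduces the input coordinates.  All randomness flows from a
single integer seed recorded in the results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from popshift.energy import (EnergyParameters, GridBox, OutOfBoxError,
                             ScoreBreakdown, grid_score, score_pose)
from popshift.structure_io import Structure, StructureError, TorsionTree, apply_torsions


class RoleError(ValueError):
    """Structure role labels do not match the operation's expectations."""


class SearchFailure(RuntimeError):
    """The search could not produce a valid pose."""


@dataclass
class Pose:
    """Rigid-body + torsional transform and the coordinates it realizes."""

    translation: np.ndarray
    quaternion: np.ndarray          # scalar-last (x, y, z, w), unit norm
    torsion_angles: np.ndarray      # degrees, length n_tor
    coords: np.ndarray              # realized ligand coordinates

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        self.torsion_angles = np.asarray(self.torsion_angles, dtype=float)
        if abs(np.linalg.norm(self.quaternion) - 1.0) > 1e-9:
            raise ValueError("quaternion must have unit norm")


IDENTITY_QUAT = np.array([0.0, 0.0, 0.0, 1.0])


def apply_pose(ref_coords: np.ndarray, tree: TorsionTree | None,
               translation: np.ndarray, quaternion: np.ndarray,
               torsion_angles: Sequence[float]) -> np.ndarray:
    """Realize coordinates: torsions root-outward, then rotation about the
    centroid of the torsioned coordinates, then translation."""
    coords = np.array(ref_coords, dtype=float)
    if tree is not None and tree.n_tor:
        coords = apply_torsions(coords, tree, torsion_angles)
    rot = Rotation.from_quat(np.asarray(quaternion, dtype=float))
    centroid = coords.mean(axis=0)
    coords = rot.apply(coords - centroid) + centroid
    return coords + np.asarray(translation, dtype=float)


@dataclass
class DockingResult:
    """Ranked, RMSD-clustered poses with their score breakdowns."""

    poses: list[tuple[Pose, ScoreBreakdown]]
    settings: dict
    seed: int

    def __post_init__(self) -> None:
        totals = [sb.total_dg for _, sb in self.poses]
        if any(t2 < t1 for t1, t2 in zip(totals, totals[1:])):
            raise ValueError("docking result must be sorted by total_dg ascending")

    @property
    def best(self) -> tuple[Pose, ScoreBreakdown]:
        return self.poses[0]


def rescore(receptor: Structure, ligand: Structure, tree: TorsionTree | None,
            p: EnergyParameters, **kwargs) -> ScoreBreakdown:
    """Tier 1: score the input pose as given.

    Identical to :func:`popshift.energy.score_pose` after validating that the
    ligand structure is labeled as ligand and the receptor carries none.
    """
    if any(r != "ligand" for r in ligand.role_labels):
        raise RoleError("all ligand atoms must carry the 'ligand' role label")
    if any(r == "ligand" for r in receptor.role_labels):
        raise RoleError("receptor structure must not contain ligand-labeled atoms")
    return score_pose(receptor, ligand, tree, p, **kwargs)


@dataclass
class RefineBounds:
    """Confinement of the refine tier around the input pose."""

    max_translation: float = 1.0   # Angstrom
    max_rotation: float = 15.0     # degrees
    max_torsion: float = 15.0      # degrees per rotatable bond

    def __post_init__(self) -> None:
        if min(self.max_translation, self.max_rotation, self.max_torsion) <= 0:
            raise ValueError("refine bounds must be positive")


def _clip_norm(v: np.ndarray, max_norm: float) -> np.ndarray:
    n = np.linalg.norm(v)
    if n > max_norm:
        return v * (max_norm / n)
    return v


def _descent(objective: Callable[[np.ndarray], float], x0: np.ndarray,
             scales: np.ndarray, lower: np.ndarray, upper: np.ndarray,
             trans_slice: slice, rot_slice: slice,
             max_translation: float, max_rotation_rad: float,
             iterations: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Accept-if-better stochastic descent with adaptive step size.

    The state vector packs translation, a rotation vector (radians) and
    torsion deltas (degrees).  Translation and rotation-vector norms are
    clipped to their bounds; torsions are clipped elementwise.
    """
    x = x0.copy()
    fx = objective(x)
    step = 1.0
    accepts = rejects = 0
    n_tor = x.shape[0] - 6
    blocks = [trans_slice, rot_slice] + ([slice(6, 6 + n_tor)] if n_tor else [])
    for it in range(iterations):
        # blockwise proposals (translation, rotation or torsions) mix with
        # occasional joint moves; acceptance stays workable in flat regions
        cand = x.copy()
        if it % 4 == 3:
            cand = cand + rng.normal(size=x.shape) * scales * step
        else:
            blk = blocks[rng.integers(len(blocks))]
            if blk.start >= 6 and rng.uniform() < 0.3:
                # barrier-crossing move: resample torsions uniformly
                cand[blk] = rng.uniform(lower[blk], upper[blk])
            elif blk.start == 3 and rng.uniform() < 0.2:
                # barrier-crossing move: resample the orientation uniformly
                cand[blk] = Rotation.random(rng=rng).as_rotvec()
            else:
                cand[blk] = (cand[blk]
                             + rng.normal(size=cand[blk].shape) * scales[blk] * step)
        cand = np.clip(cand, lower, upper)
        cand[trans_slice] = _clip_norm(cand[trans_slice], max_translation)
        cand[rot_slice] = _clip_norm(cand[rot_slice], max_rotation_rad)
        fc = objective(cand)
        if fc < fx:
            x, fx = cand, fc
            accepts += 1
            rejects = 0
            if accepts >= 3:
                step = min(step * 1.6, 6.0)
                accepts = 0
        else:
            rejects += 1
            accepts = 0
            if rejects >= 6:
                step = max(step * 0.7, 1e-4)
                rejects = 0
    return x, fx


def _polish(objective: Callable[[np.ndarray], float], x: np.ndarray,
            fx: float, rounds: int = 6, maxiter: int = 800) -> tuple[np.ndarray, float]:
    """Deterministic restarted-simplex polish of a descent endpoint.

    The trilinearly interpolated objective is piecewise linear, where a
    single Nelder-Mead run tends to collapse prematurely; restarting with a
    fresh simplex from the incumbent until no improvement remains is the
    standard remedy.
    """
    from scipy.optimize import minimize

    for _ in range(rounds):
        res = minimize(objective, x, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-12})
        if math.isfinite(res.fun) and res.fun < fx - 1e-12:
            x, fx = np.asarray(res.x, dtype=float), float(res.fun)
        else:
            break
    return x, fx


def _make_objective(receptor: Structure | None, box: GridBox | None,
                    ligand: Structure, tree: TorsionTree | None,
                    p: EnergyParameters, ref_coords: np.ndarray,
                    n_tor: int) -> Callable[[np.ndarray], float]:
    def objective(x: np.ndarray) -> float:
        t = x[0:3]
        rv = x[3:6]
        tor = x[6:6 + n_tor]
        angle = np.linalg.norm(rv)
        quat = Rotation.from_rotvec(rv).as_quat() if angle > 0 else IDENTITY_QUAT
        coords = apply_pose(ref_coords, tree, t, quat, tor)
        trial = ligand.with_coords(coords)
        try:
            if box is not None:
                sb = grid_score(box, trial, tree, p)
            else:
                sb = score_pose(receptor, trial, tree, p)
        except OutOfBoxError:
            return math.inf
        return sb.total_dg

    return objective


def _pose_from_state(x: np.ndarray, ref_coords: np.ndarray,
                     tree: TorsionTree | None, n_tor: int) -> Pose:
    t = x[0:3]
    rv = x[3:6]
    tor = x[6:6 + n_tor]
    quat = Rotation.from_rotvec(rv).as_quat() if np.linalg.norm(rv) > 0 else IDENTITY_QUAT
    quat = quat / np.linalg.norm(quat)
    coords = apply_pose(ref_coords, tree, t, quat, tor)
    return Pose(t.copy(), quat, tor.copy(), coords)


def refine(receptor: Structure | None, ligand: Structure,
           tree: TorsionTree | None, p: EnergyParameters,
           bounds: RefineBounds | None = None, seed: int = 0,
           iterations: int = 300,
           box: GridBox | None = None) -> tuple[Pose, ScoreBreakdown]:
    """Tier 2: local stochastic descent confined to ``bounds`` around the
    input pose.  The returned score never exceeds the input score and the
    result is deterministic for a given seed."""
    if iterations <= 0:
        raise ValueError("iteration budget must be positive")
    if bounds is None:
        bounds = RefineBounds()
    if receptor is None and box is None:
        raise ValueError("refine needs a receptor or a grid box")
    n_tor = tree.n_tor if tree is not None else 0
    ref_coords = ligand.coords
    objective = _make_objective(receptor, box, ligand, tree, p, ref_coords, n_tor)

    max_rot_rad = math.radians(bounds.max_rotation)
    x0 = np.zeros(6 + n_tor)
    scales = np.concatenate([
        np.full(3, 0.25 * bounds.max_translation),
        np.full(3, 0.25 * max_rot_rad),
        np.full(n_tor, 0.25 * bounds.max_torsion),
    ])
    lower = np.concatenate([np.full(3, -bounds.max_translation),
                            np.full(3, -max_rot_rad),
                            np.full(n_tor, -bounds.max_torsion)])
    upper = -lower
    rng = np.random.default_rng(seed)
    x, _ = _descent(objective, x0, scales, lower, upper, slice(0, 3), slice(3, 6),
                    bounds.max_translation, max_rot_rad, iterations, rng)
    pose = _pose_from_state(x, ref_coords, tree, n_tor)
    trial = ligand.with_coords(pose.coords)
    sb = grid_score(box, trial, tree, p) if box is not None \
        else score_pose(receptor, trial, tree, p)
    start = grid_score(box, ligand, tree, p) if box is not None \
        else score_pose(receptor, ligand, tree, p)
    if sb.total_dg > start.total_dg:  # descent is accept-if-better; keep the start
        pose = _pose_from_state(x0, ref_coords, tree, n_tor)
        sb = start
    return pose, sb


def dock(box: GridBox, ligand: Structure, tree: TorsionTree | None,
         p: EnergyParameters, n_runs: int = 20, iterations: int = 500,
         seed: int = 0, n_poses: int = 10, cluster_rmsd: float = 2.0,
         sample_radius: float | None = None,
         max_placement_attempts: int = 200,
         deep_polish_top: int = 5) -> DockingResult:
    """Tier 3: multi-start search over the grid box.

    Each restart draws a random translation inside a sampling sphere around
    the box center, a random orientation and random torsions, then runs the
    accept-if-better descent kernel on the grid score with bounds spanning
    the box.  Results are pooled, greedily clustered by pose RMSD in the
    fixed receptor frame, and cluster-best poses are ranked by total ΔG.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n_tor = tree.n_tor if tree is not None else 0
    ref_coords = ligand.coords
    ref_centroid = ref_coords.mean(axis=0)
    lig_radius = float(np.max(np.linalg.norm(ref_coords - ref_centroid, axis=1)))
    half_extent = float(np.min((box.upper - box.lower) / 2.0))
    if sample_radius is None:
        sample_radius = max(half_extent - lig_radius - box.spacing, 0.5)

    objective = _make_objective(None, box, ligand, tree, p, ref_coords, n_tor)
    max_rot_rad = math.pi
    max_trans = half_extent + lig_radius
    scales = np.concatenate([
        np.full(3, 0.5), np.full(3, 0.35), np.full(n_tor, 12.0)])
    lower = np.concatenate([np.full(3, -max_trans), np.full(3, -max_rot_rad),
                            np.full(n_tor, -180.0)])
    upper = -lower

    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    pool: list[tuple[Pose, float]] = []
    placement_failures = 0
    for run, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        x0 = None
        for _ in range(max_placement_attempts):
            # uniform point in the sampling sphere, relative to the box center
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            radius = sample_radius * rng.uniform() ** (1.0 / 3.0)
            t = box.center + u * radius - ref_centroid
            rv = Rotation.random(rng=rng).as_rotvec()
            tor = rng.uniform(-180.0, 180.0, size=n_tor)
            cand = np.concatenate([t, rv, tor])
            if math.isfinite(objective(cand)):
                x0 = cand
                break
        if x0 is None:
            placement_failures += 1
            continue
        x, fx = _descent(objective, x0, scales, lower, upper, slice(0, 3),
                         slice(3, 6), max_trans, max_rot_rad, iterations, rng)
        x, fx = _polish(objective, x, fx, rounds=2, maxiter=400)
        pool.append(((x, rng), fx))

    # deep-polish the most promising restarts by basin hopping: random
    # kicks large enough to cross sub-basin barriers, each followed by a
    # restarted simplex descent, accepted only on improvement
    pool.sort(key=lambda item: item[1])
    kick = np.concatenate([np.full(3, 0.45), np.full(3, 0.25),
                           np.full(n_tor, 12.0)])
    deep = []
    for (x, rng), fx in pool[:deep_polish_top]:
        x, fx = _polish(objective, x, fx)
        for _ in range(8):
            cand = x + rng.normal(size=x.shape) * kick
            cand = np.clip(cand, lower, upper)
            fc = objective(cand)
            cand, fc = _polish(objective, cand, fc, rounds=3, maxiter=600)
            if fc < fx:
                x, fx = cand, fc
        deep.append((x, fx))
    pool = deep + [(x, fx) for (x, _), fx in pool[deep_polish_top:]]
    pool = [(_pose_from_state(x, ref_coords, tree, n_tor), fx) for x, fx in pool]

    if not pool:
        raise SearchFailure(
            f"no in-box placement found in {n_runs} runs "
            f"({placement_failures} placement failures)")

    pool.sort(key=lambda item: item[1])
    # greedy energy-ordered clustering: a pose joins the first cluster whose
    # representative it matches within cluster_rmsd, else founds a new one
    reps: list[tuple[Pose, float]] = []
    for pose, fx in pool:
        if not any(pose_rmsd(pose.coords, rep.coords) <= cluster_rmsd
                   for rep, _ in reps):
            reps.append((pose, fx))

    ranked = []
    for pose, _ in reps[:n_poses]:
        sb = grid_score(box, ligand.with_coords(pose.coords), tree, p)
        ranked.append((pose, sb))

    settings = {
        "n_runs": n_runs, "iterations": iterations, "n_poses": n_poses,
        "cluster_rmsd": cluster_rmsd, "sample_radius": sample_radius,
        "placement_failures": placement_failures,
    }
    return DockingResult(ranked, settings, seed)


def pose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
              mapping: Sequence[tuple[int, int]] | None = None) -> float:
    """RMSD between two conformations in the fixed receptor frame.

    No superposition and no symmetry equivalences are applied; the default
    mapping is the identity.  Callers restrict to heavy atoms by passing the
    corresponding coordinate rows or an explicit mapping.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if mapping is not None:
        mapping = list(mapping)
        if not mapping:
            raise ValueError("mapping must contain at least one atom pair")
        ia, ib = zip(*mapping)
        a, b = a[list(ia)], b[list(ib)]
    if a.shape != b.shape or a.size == 0:
        raise ValueError("coordinate sets must be non-empty and congruent")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
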