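"""Free-energy spectra from conformational ensembles.

Snapshots are sampled on a time lattice anchored at the window end (so the
final frame of a "last n ns" window is always included), each snapshot is
rescored with the pairwise energy function, and the scores are histogrammed
into a probability density over ΔG.  The mode of that density is the most
probable binding free energy of the ensemble; the minimum sampled score is
the best-tail ΔG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from popshift.energy import EnergyParameters, ScoreBreakdown, T_DEFAULT, delta_g_to_ki, score_pose
from popshift.structure_io import EnsembleTrajectory, Structure, StructureError, TorsionTree


@dataclass
class FreeEnergySpectrum:
    """Binned probability density over binding free energies."""

    bin_edges: np.ndarray        # kcal/mol, ascending
    densities: np.ndarray        # probability per kcal/mol
    sample_scores: np.ndarray    # kcal/mol
    most_probable_dg: float
    best_dg: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        self.sample_scores = np.asarray(self.sample_scores, dtype=float)
        if np.any(self.densities < 0):
            raise ValueError("densities must be nonnegative")
        widths = np.diff(self.bin_edges)
        if abs(float(self.densities @ widths) - 1.0) > 1e-9:
            raise ValueError("densities must integrate to 1")
        # the mode is a bin center, so the minimum sample can sit up to half
        # a bin above it when both fall in the modal bin
        if self.best_dg > self.most_probable_dg + 0.5 * widths.max() + 1e-12:
            raise ValueError("best_dg must not exceed most_probable_dg")

    @property
    def n_samples(self) -> int:
        return len(self.sample_scores)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def sample_snapshots(traj: EnsembleTrajectory, interval_ps: float,
                     window: tuple[float, float],
                     time_tol: float = 1e-6) -> list[tuple[float, Structure]]:
    """Frames on the interval lattice anchored at the window end.

    Selects frames with time in ``(t_start, t_end]`` lying on the lattice
    ``t_end - k * interval_ps``; for a trajectory that covers the window the
    count is ``floor((t_end - t_start) / interval_ps)``.
    """
    if interval_ps <= 0:
        raise ValueError("sampling interval must be positive")
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError("window end must exceed window start")
    if interval_ps > t_end - t_start:
        raise ValueError("sampling interval exceeds the window length")
    times = traj.times
    if t_start < times[0] - time_tol and t_end > times[-1] + time_tol:
        raise ValueError("window extends beyond the trajectory span")
    selected = []
    for t, s in traj.frames:
        if not (t_start < t <= t_end + time_tol):
            continue
        k = (t_end - t) / interval_ps
        if abs(k - round(k)) <= time_tol:
            selected.append((t, s))
    if not selected:
        raise ValueError("no snapshots fall on the sampling lattice inside the window")
    return selected


def _resolve_selection(frame: Structure, selection) -> np.ndarray:
    """A selection is a role name, a list of role names, or explicit indices."""
    if isinstance(selection, str):
        return frame.role_indices(selection)
    selection = list(selection)
    if selection and isinstance(selection[0], str):
        return frame.role_indices(*selection)
    return np.asarray(selection, dtype=int)


def rescore_ensemble(frames: Sequence[tuple[float, Structure]],
                     receptor_selection, ligand_selection,
                     p: EnergyParameters,
                     tree: TorsionTree | None = None,
                     include_ions: bool = False,
                     include_waters: bool = False) -> list[ScoreBreakdown]:
    """One score breakdown per frame, in frame order.

    Selections (role names or explicit atom indices) must resolve to the
    same atom count in every frame.
    """
    if not frames:
        raise ValueError("empty frame list")
    breakdowns = []
    n_rec = n_lig = None
    for i, (_, frame) in enumerate(frames):
        rec_idx = _resolve_selection(frame, receptor_selection)
        lig_idx = _resolve_selection(frame, ligand_selection)
        if len(rec_idx) == 0 or len(lig_idx) == 0:
            raise StructureError(f"frame {i}: empty receptor or ligand selection")
        if n_rec is None:
            n_rec, n_lig = len(rec_idx), len(lig_idx)
        elif (len(rec_idx), len(lig_idx)) != (n_rec, n_lig):
            raise StructureError(
                f"frame {i}: selection resolves to {len(rec_idx)}/{len(lig_idx)} atoms, "
                f"expected {n_rec}/{n_lig}")
        receptor = frame.subset(rec_idx)
        ligand = frame.subset(lig_idx)
        breakdowns.append(score_pose(receptor, ligand, tree, p,
                                     include_ions=include_ions,
                                     include_waters=include_waters))
    return breakdowns


def build_spectrum(scores: Sequence[float], bin_width: float = 0.5) -> FreeEnergySpectrum:
    """Histogram scores into a normalized density on a fixed bin lattice.

    Bin centers sit at integer multiples of ``bin_width`` (so spectra of
    different ligands share the same lattice and a sample at, say, exactly
    -5.0 kcal/mol falls in the bin centered on -5.0).  The most probable ΔG
    is the center of the maximal-density bin; ties break toward the more
    negative bin.  Non-finite scores are dropped with a warning reporting
    the count.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("at least one score is required")
    finite = np.isfinite(scores)
    if not np.all(finite):
        warnings.warn(f"rejected {int((~finite).sum())} non-finite scores")
        scores = scores[finite]
        if scores.size == 0:
            raise ValueError("all scores are non-finite")

    k_lo = int(np.floor(scores.min() / bin_width + 0.5))
    k_hi = int(np.floor(scores.max() / bin_width + 0.5))
    edges = (np.arange(k_lo, k_hi + 2) - 0.5) * bin_width
    densities, edges = np.histogram(scores, bins=edges, density=True)
    # np.argmax returns the first (most negative) maximal bin: the tie-break
    mode_bin = int(np.argmax(densities))
    most_probable = float(0.5 * (edges[mode_bin] + edges[mode_bin + 1]))
    return FreeEnergySpectrum(edges, densities, scores, most_probable,
                              float(scores.min()))


def spectrum_report(spectrum: FreeEnergySpectrum,
                    temperature: float = T_DEFAULT) -> dict:
    """Headline numbers and a plot-ready (bin center, density) table."""
    ki = delta_g_to_ki(spectrum.most_probable_dg, temperature)
    table = pd.DataFrame({
        "bin_center": spectrum.bin_centers,
        "density": spectrum.densities,
    })
    return {
        "most_probable_dg": spectrum.most_probable_dg,
        "best_dg": spectrum.best_dg,
        "ki_molar": ki,
        "ki_nanomolar": ki * 1e9,
        "n_samples": spectrum.n_samples,
        "temperature": temperature,
        "table": table,
    }
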