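#!/usr/bin/env python
"""Optional external validation against a user-prepared crystal complex.

The packaged acceptance checks run entirely on synthetic systems.  For users
who have prepared a real cleavage-complex structure (for example PDB entry
3QX3 split into receptor and ligand, protonated and charged with their own
tooling, saved in the charged pdbq dialect), this script runs the three
evaluation tiers against it and reports ΔG, Ki and the pose RMSD between the
docked best mode and the input (crystallographic) pose.

Nothing is downloaded and no reference values are asserted; the output is a
report for the user's own judgement.

Usage::

    python scripts/validate_external.py --receptor receptor.pdbq \
        --ligand ligand.pdbq [--bonds i,j ...] [--npts 100,100,100] \
        [--spacing 0.375] [--runs 20] [--seed 0] [--out report.json]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from popshift.docking import dock, pose_rmsd, refine, rescore
from popshift.energy import EnergyParameters, delta_g_to_ki, make_grid_box
from popshift.structure_io import build_torsion_tree, read_structure


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--receptor", required=True, type=Path)
    parser.add_argument("--ligand", required=True, type=Path)
    parser.add_argument("--bonds", nargs="*", default=[],
                        help="rotatable bonds as 0-based i,j ligand atom pairs")
    parser.add_argument("--npts", default="100,100,100")
    parser.add_argument("--spacing", type=float, default=0.375)
    parser.add_argument("--runs", type=int, default=20)
    parser.add_argument("--iterations", type=int, default=500)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    params = EnergyParameters.default()
    receptor = read_structure(args.receptor, "pdbq_charged")
    ligand = read_structure(args.ligand, "pdbq_charged")
    bonds = [tuple(int(x) for x in pair.split(",")) for pair in args.bonds]
    tree = build_torsion_tree(ligand, bonds)

    report: dict = {"receptor": str(args.receptor), "ligand": str(args.ligand),
                    "n_tor": tree.n_tor, "seed": args.seed}

    crystal = rescore(receptor, ligand, tree, params)
    report["rescore"] = {**crystal.as_dict(),
                         "ki_molar": delta_g_to_ki(crystal.total_dg)}

    refined_pose, refined = refine(receptor, ligand, tree, params, seed=args.seed)
    report["refine"] = {**refined.as_dict(),
                        "rmsd_to_input_A": pose_rmsd(refined_pose.coords,
                                                     ligand.coords)}

    npts = tuple(int(x) for x in args.npts.split(","))
    # box centered on the geometric center of the nucleic-acid selection when
    # present, else on all receptor atoms
    dna = [i for i, a in enumerate(receptor.atoms)
           if a.residue_name.strip() in {"DA", "DT", "DG", "DC", "A", "T", "G", "C"}]
    box = make_grid_box(receptor, args.spacing, npts, params,
                        ligand_types=set(ligand.atom_types),
                        center_selection=dna or None)
    result = dock(box, ligand, tree, params, n_runs=args.runs,
                  iterations=args.iterations, seed=args.seed)
    best_pose, best_sb = result.best
    report["dock"] = {**best_sb.as_dict(),
                      "ki_molar": delta_g_to_ki(best_sb.total_dg),
                      "rmsd_to_input_A": pose_rmsd(best_pose.coords, ligand.coords),
                      "n_modes": len(result.poses)}

    text = json.dumps(report, indent=2)
    if args.out:
        args.out.write_text(text)
    print(text)


if __name__ == "__main__":
    main()
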