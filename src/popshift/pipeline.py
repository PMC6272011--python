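"""End-to-end orchestration: dock, pick modes, build an ensemble, construct
the free-energy spectrum and the rotamer report from one validated config,
with a machine-readable run manifest.

The manifest echoes every stage's parameters and the run seed, and records
sha256 checksums of the files each stage writes, so a run can be reproduced
from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from popshift import synthetic
from popshift.docking import dock
from popshift.energy import EnergyParameters, make_grid_box
from popshift.interactions import interaction_report
from popshift.rotamers import cluster_rotamers
from popshift.spectrum import build_spectrum, rescore_ensemble, spectrum_report
from popshift.structure_io import (Atom, Structure, build_torsion_tree,
                                   read_structure, write_ensemble, write_structure)

logger = logging.getLogger("popshift.pipeline")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``receptor`` / ``ligand`` are optional pdbq_charged input paths; when
    absent the synthetic toy complex is generated instead.  Unknown keys are
    rejected at validation time.
    """

    seed: int = 0
    outdir: str = "popshift_run"
    receptor: str | None = None
    ligand: str | None = None
    stages: tuple = ("synth", "dock", "ensemble", "spectrum", "rotamer", "interactions")
    grid: dict = field(default_factory=lambda: {"spacing": 0.375, "npts": [61, 61, 61]})
    search: dict = field(default_factory=lambda: {"n_runs": 20, "iterations": 500,
                                                  "n_poses": 3})
    ensemble: dict = field(default_factory=lambda: {"n_frames": 200, "noise_sd": 0.05,
                                                    "two_state": None, "dt_ps": 100.0})
    spectrum: dict = field(default_factory=lambda: {"bin_width": 0.5})
    rotamer: dict = field(default_factory=lambda: {"cutoff": 40.0, "n_frames": 300})
    interactions: dict = field(default_factory=lambda: {"max_da_distance": 3.5,
                                                        "min_dha_angle": 120.0,
                                                        "contact_cutoff": 3.9})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        cfg = cls(**data)
        for path_key in ("receptor", "ligand"):
            path = getattr(cfg, path_key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{path_key} file does not exist: {path}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration must be a mapping")
        return cls.from_dict(data)



def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``<outdir>/manifest.json``); a
    stage failure is recorded in the manifest before the exception
    propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = EnergyParameters.default()
    manifest: dict = {"seed": config.seed, "stages": {}, "headline": {},
                      "config": {f.name: getattr(config, f.name) for f in fields(config)}}

    def record(stage: str, status: str, outputs: dict | None = None,
               params: dict | None = None, **extra) -> None:
        entry = {"status": status, "params": params or {}, "outputs": {}, **extra}
        for name, path in (outputs or {}).items():
            entry["outputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}
        manifest["stages"][stage] = entry

    def finish(status: str) -> None:
        manifest["status"] = status
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    current = None
    try:
        # --- structures -------------------------------------------------
        current = "synth"
        if config.receptor and config.ligand:
            receptor = read_structure(config.receptor, "pdbq_charged")
            ligand = read_structure(config.ligand, "pdbq_charged")
            tree = build_torsion_tree(ligand, [])
            optimum = None
            record("synth", "skipped (file inputs)",
                   params={"receptor": config.receptor, "ligand": config.ligand})
        else:
            receptor, ligand, tree, optimum, opt_score = synthetic.make_toy_complex(
                synthetic.SyntheticSpec(seed=config.seed))
            rec_path = outdir / "receptor.pdbq"
            lig_path = outdir / "ligand.pdbq"
            write_structure(receptor, rec_path, "pdbq_charged")
            write_structure(ligand, lig_path, "pdbq_charged")
            record("synth", "ok", {"receptor": rec_path, "ligand": lig_path},
                   {"seed": config.seed},
                   optimum_dg=opt_score.total_dg)
        logger.info("stage synth done")

        # --- docking ----------------------------------------------------
        best_ligand = ligand
        if "dock" in config.stages:
            current = "dock"
            grid = dict(config.grid)
            box = make_grid_box(receptor, grid.get("spacing", 0.375),
                                grid.get("npts", [61, 61, 61]), p,
                                ligand_types=set(ligand.atom_types),
                                center=grid.get("center"))
            search = dict(config.search)
            result = dock(box, ligand, tree, p,
                          n_runs=search.get("n_runs", 20),
                          iterations=search.get("iterations", 500),
                          n_poses=search.get("n_poses", 3),
                          deep_polish_top=search.get("deep_polish_top", 5),
                          seed=int(seeds[0].generate_state(1)[0] % (2 ** 31)))
            best_pose, best_sb = result.best
            best_ligand = ligand.with_coords(best_pose.coords)
            dock_json = outdir / "docking.json"
            dock_json.write_text(json.dumps({
                "seed": result.seed,
                "settings": result.settings,
                "poses": [
                    {"rank": i + 1, "total_dg": sb.total_dg, **sb.as_dict()}
                    for i, (_, sb) in enumerate(result.poses)
                ],
            }, indent=2, default=_json_default))
            record("dock", "ok", {"result": dock_json}, result.settings,
                   best_dg=best_sb.total_dg, n_modes=len(result.poses))
            manifest["headline"]["dock_best_dg"] = best_sb.total_dg
            logger.info("stage dock done: best ΔG %.3f", best_sb.total_dg)

        # --- ensemble + spectrum ---------------------------------------
        if "ensemble" in config.stages or "spectrum" in config.stages:
            current = "ensemble"
            ens_cfg = dict(config.ensemble)
            traj = synthetic.make_ensemble(
                receptor, best_ligand,
                n_frames=ens_cfg.get("n_frames", 200),
                noise_sd=ens_cfg.get("noise_sd", 0.05),
                two_state=ens_cfg.get("two_state"),
                dt_ps=ens_cfg.get("dt_ps", 100.0),
                seed=int(seeds[1].generate_state(1)[0] % (2 ** 31)))
            traj_path = outdir / "ensemble.pdb"
            write_ensemble(traj, traj_path, "pdbq_charged")
            record("ensemble", "ok", {"trajectory": traj_path}, ens_cfg,
                   n_frames=traj.n_frames)

            current = "spectrum"
            breakdowns = rescore_ensemble(traj.frames, "receptor", "ligand", p,
                                          tree=tree)
            spect = build_spectrum([sb.total_dg for sb in breakdowns],
                                   bin_width=config.spectrum.get("bin_width", 0.5))
            report = spectrum_report(spect, p.temperature)
            tsv_path = outdir / "spectrum.tsv"
            report["table"].to_csv(tsv_path, sep="\t", index=False)
            sidecar = outdir / "spectrum.json"
            sidecar.write_text(json.dumps({
                "most_probable_dg": report["most_probable_dg"],
                "best_dg": report["best_dg"],
                "ki_molar": report["ki_molar"],
                "n_samples": report["n_samples"],
                "seed": config.seed,
            }, indent=2, default=_json_default))
            record("spectrum", "ok", {"spectrum": tsv_path, "summary": sidecar},
                   config.spectrum, most_probable_dg=report["most_probable_dg"])
            manifest["headline"]["most_probable_dg"] = report["most_probable_dg"]
            manifest["headline"]["ki_molar"] = report["ki_molar"]
            logger.info("stage spectrum done: mode ΔG %.3f", report["most_probable_dg"])

        # --- rotamer analysis -------------------------------------------
        if "rotamer" in config.stages:
            current = "rotamer"
            rot_cfg = dict(config.rotamer)
            series, coords, _ = synthetic.make_rotamer_trajectory(
                n_frames=rot_cfg.get("n_frames", 300),
                seed=int(seeds[2].generate_state(1)[0] % (2 ** 31)))
            clustering = cluster_rotamers([series], cutoff=rot_cfg.get("cutoff", 40.0))
            rot_path = outdir / "rotamer_report.json"
            rot_path.write_text(json.dumps({
                "n_clusters": clustering.n_clusters,
                "populations": clustering.populations.tolist(),
                "centroids": [
                    {"cluster": i + 1, "frame": f, "chi": c.tolist()}
                    for i, (f, c) in enumerate(clustering.centroids)
                ],
                "linkage_cutoff": clustering.linkage_cutoff,
            }, indent=2, default=_json_default))
            record("rotamer", "ok", {"report": rot_path}, rot_cfg,
                   n_clusters=clustering.n_clusters)
            manifest["headline"]["rotamer_clusters"] = clustering.n_clusters

        # --- interaction profile ----------------------------------------
        if "interactions" in config.stages:
            current = "interactions"
            merged_atoms = []
            for k, a in enumerate(receptor.atoms + best_ligand.atoms, start=1):
                merged_atoms.append(Atom(k, a.name, a.element, a.atom_type,
                                         a.residue_name, a.residue_number, a.chain_id,
                                         a.position.copy(), a.partial_charge,
                                         a.occupancy, a.alt_loc, a.record))
            complex_structure = Structure(
                merged_atoms,
                list(receptor.role_labels) + list(best_ligand.role_labels))
            rep = interaction_report(complex_structure, p, **config.interactions)
            int_path = outdir / "interactions.json"
            int_path.write_text(json.dumps({
                "hbonds": [
                    {"donor": h.donor_index, "acceptor": h.acceptor_index,
                     "distance": h.distance, "angle": h.angle}
                    for h in rep.hbonds
                ],
                "contacts": [
                    {"ligand_atom": c.ligand_index, "receptor_atom": c.receptor_index,
                     "residue": list(c.residue_id), "distance": c.distance}
                    for c in rep.contacts
                ],
                "excluded_roles": sorted(rep.excluded_roles),
            }, indent=2, default=_json_default))
            record("interactions", "ok", {"report": int_path}, config.interactions,
                   n_hbonds=len(rep.hbonds), n_contacts=len(rep.contacts))
    except Exception as exc:
        record(current or "setup", f"failed: {exc}")
        finish("failed")
        raise

    finish("ok")
    return manifest
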