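"""End-to-end orchestration: simulate -> concatenate -> RMSF -> cluster ->
MDS -> meta-clusters -> H-bonds -> energies, with plain-text intermediates
and a JSON run manifest (parameters, seeds, file checksums) sufficient to
reproduce the run."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import Selection, Trajectory, concatenate_trajectories, select_atoms, write_multimodel_pdb, write_sidecar
from .superpose import pairwise_rmsd_matrix, rmsf, superpose_trajectory
from .cluster import Clustering, cluster_composition, daura_cluster
from .ordination import group_metaclusters, metacluster_occupancy, nonmetric_mds
from .interactions import energy_histogram, energy_series, hbond_count_series, hbond_histogram
from .synthetic import default_study_plans, generate_loop_ensemble

log = logging.getLogger("loopconf")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Every tunable parameter of a full pipeline run.

    Defaults carry the analysis parameters of the study this package
    reproduces: 0.2 nm cluster cut-off, 0.35 nm / 30 degree hydrogen-bond
    criteria, 1.4 nm short-range energy cut-off, 100 and 10 kJ/mol
    histogram bins, top-25 clusters embedded.
    """

    output_dir: str = "pipeline_out"
    seed: int = 1234
    n_frames_per_system: int = 600
    loop_select: str = "resid 7-14"
    flanking_select: str = "name CA and resid 1-6 15-20"
    scaffold_select: str = "resid 1-6 15-20"
    cluster_cutoff: float = 0.2          # nm
    top_k_clusters: int = 25
    mds_max_iter: int = 500
    mds_tol: float = 1e-6
    mds_restarts: int = 4
    metacluster_threshold: float = 0.45  # embedding units (~nm after scaling)
    hbond_dist_cutoff: float = 0.35      # nm
    hbond_angle_cutoff: float = 30.0     # degrees
    hbond_angle_convention: str = "ADH"
    energy_cutoff: float = 1.4           # nm
    energy_bin_coarse: float = 100.0     # kJ/mol
    energy_bin_fine: float = 10.0        # kJ/mol
    noise_sigma: float = 0.02            # nm
    rigid_motion: bool = True
    write_matrix_limit: int = 2500       # skip the matrix CSV above this n

    def validate(self) -> None:
        positive = {
            "n_frames_per_system": self.n_frames_per_system,
            "cluster_cutoff": self.cluster_cutoff,
            "top_k_clusters": self.top_k_clusters,
            "mds_max_iter": self.mds_max_iter,
            "mds_tol": self.mds_tol,
            "metacluster_threshold": self.metacluster_threshold,
            "hbond_dist_cutoff": self.hbond_dist_cutoff,
            "hbond_angle_cutoff": self.hbond_angle_cutoff,
            "energy_cutoff": self.energy_cutoff,
            "energy_bin_coarse": self.energy_bin_coarse,
            "energy_bin_fine": self.energy_bin_fine,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        for name in ("loop_select", "flanking_select", "scaffold_select"):
            if not getattr(self, name).strip():
                raise ConfigError(f"{name} must be a non-empty selection")


def load_config(path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML mapping (file) plus keyword overrides.

    Keys mirror the RunConfig fields; unknown keys are rejected so typos
    never silently fall back to defaults.
    """
    import yaml

    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update(overrides)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.6f", lineterminator="\n")


def clustering_to_json(clustering: Clustering, path: Path) -> None:
    payload = {
        "cutoff_nm": clustering.cutoff,
        "total_frames": clustering.total_frames,
        "clusters": [
            {"rank": r, "center_frame": c.center_frame, "size": c.size,
             "members": list(c.members)}
            for r, c in enumerate(clustering.clusters)
        ],
    }
    path.write_text(json.dumps(payload, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on the bundled synthetic study plan; return the manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    parameters = asdict(config)
    parameters.pop("output_dir")   # not scientific; keeps manifests comparable
    manifest: dict = {
        "package_version": __version__,
        "parameters": parameters,
        "stages": {},
    }

    # -- simulate -----------------------------------------------------------
    stage = "simulate"
    log.info("stage %s: 3 systems x %d frames, seed %d",
             stage, config.n_frames_per_system, config.seed)
    system, plans = default_study_plans(
        n_frames=config.n_frames_per_system, seed=config.seed,
        rigid_motion=config.rigid_motion, noise_sigma=config.noise_sigma,
    )
    parts, label_rows = [], []
    for plan in plans:
        traj, states = generate_loop_ensemble(plan)
        parts.append((traj, plan.system_label))
        for t, s in enumerate(states):
            label_rows.append((plan.system_label, t, int(s)))
    write_sidecar(system.topology, out / "topology.sidecar")
    _write_csv(pd.DataFrame(label_rows, columns=["system", "frame", "true_state"]),
               out / "true_states.csv")

    ensemble = concatenate_trajectories(parts)
    labels = ensemble.system_labels()
    loop_sel = select_atoms(ensemble.topology, config.loop_select, "loop")
    flank_sel = select_atoms(ensemble.topology, config.flanking_select, "flanking-CA")
    scaffold_sel = select_atoms(ensemble.topology, config.scaffold_select, "scaffold")
    all_sel = Selection(tuple(range(ensemble.topology.n_atoms)), "all")

    # -- RMSF (per system, fitted to that system's first frame) -------------
    stage = "rmsf"
    for traj, label in parts:
        values = rmsf(traj, flank_sel, all_sel)
        df = pd.DataFrame({
            "residue_number": [a.residue_number for a in traj.topology.atoms],
            "atom_name": [a.name for a in traj.topology.atoms],
            "rmsf_nm": values,
        })
        _write_csv(df, out / f"rmsf_{label}.csv")
    log.info("stage %s: wrote per-system RMSF tables", stage)

    # -- RMSD matrix + clustering -------------------------------------------
    stage = "cluster"
    fitted = superpose_trajectory(ensemble, ensemble.frames[0], flank_sel)
    matrix = pairwise_rmsd_matrix(fitted, None, loop_sel)
    if ensemble.n_frames <= config.write_matrix_limit:
        np.savetxt(out / "rmsd_matrix.csv", matrix, fmt="%.5f", delimiter=",")
    clustering = daura_cluster(matrix, config.cluster_cutoff)
    clustering_to_json(clustering, out / "clustering.json")
    ranks = clustering.labels()
    _write_csv(pd.DataFrame({
        "frame": np.arange(ensemble.n_frames),
        "time_ps": ensemble.times(),
        "system": labels,
        "cluster": ranks,
    }), out / "membership.csv")
    composition = cluster_composition(clustering, labels)
    _write_csv(composition, out / "cluster_composition.csv", index=True)
    k = min(config.top_k_clusters, clustering.n_clusters)
    centers = [c.center_frame for c in clustering.clusters[:k]]
    center_traj = Trajectory(ensemble.topology, [fitted.frames[i] for i in centers])
    write_multimodel_pdb(center_traj, all_sel, out / "cluster_centers.pdb")
    log.info("stage %s: %d clusters at %.2f nm (top %d centers exported)",
             stage, clustering.n_clusters, config.cluster_cutoff, k)

    # -- MDS + meta-clusters -------------------------------------------------
    stage = "mds"
    center_dist = matrix[np.ix_(centers, centers)]
    embedding = nonmetric_mds(center_dist, dim=2, seed=config.seed,
                              max_iter=config.mds_max_iter, tol=config.mds_tol,
                              n_restarts=config.mds_restarts)
    meta = group_metaclusters(embedding, config.metacluster_threshold)
    emb_df = pd.DataFrame({
        "cluster": np.arange(k),
        "center_frame": centers,
        "x": embedding.points[:, 0],
        "y": embedding.points[:, 1],
        "metacluster": meta.assignment,
        "size": [clustering.clusters[i].size for i in range(k)],
    })
    _write_csv(emb_df, out / "embedding.csv")
    occupancy = metacluster_occupancy(meta, clustering, labels)
    _write_csv(occupancy, out / "metacluster_occupancy.csv", index=True)
    log.info("stage %s: stress %.4g, %d meta-clusters",
             stage, embedding.stress, meta.n_metaclusters)

    # -- hydrogen bonds ------------------------------------------------------
    stage = "hbonds"
    hb_series = hbond_count_series(
        ensemble, loop_sel, scaffold_sel,
        config.hbond_dist_cutoff, config.hbond_angle_cutoff,
        config.hbond_angle_convention,
    )
    _write_csv(pd.DataFrame({
        "frame": np.arange(ensemble.n_frames),
        "system": labels,
        "n_hbonds": hb_series,
    }), out / "hbond_series.csv")
    hb_hist = hbond_histogram(hb_series)
    _write_csv(pd.DataFrame(sorted(hb_hist.items()), columns=["n_hbonds", "frames"]),
               out / "hbond_histogram.csv")

    # -- non-bonded energies -------------------------------------------------
    stage = "energies"
    e_df = energy_series(ensemble, loop_sel, scaffold_sel, config.energy_cutoff)
    e_df.insert(2, "system", labels)
    _write_csv(e_df, out / "energy_series.csv")
    for tag, width in (("coarse", config.energy_bin_coarse),
                       ("fine", config.energy_bin_fine)):
        hist = energy_histogram(e_df["e_total"].to_numpy(), width)
        _write_csv(pd.DataFrame(sorted(hist.items()),
                                columns=["bin_left_kjmol", "frames"]),
                   out / f"energy_histogram_{tag}.csv")

    # -- manifest ------------------------------------------------------------
    manifest["stages"] = {
        "cluster": {"n_clusters": clustering.n_clusters,
                    "cutoff_nm": config.cluster_cutoff},
        "mds": {"stress": embedding.stress, "seed": embedding.seed,
                "iterations": embedding.iterations,
                "n_metaclusters": meta.n_metaclusters,
                "metacluster_threshold": config.metacluster_threshold,
                "angle_convention": config.hbond_angle_convention},
    }
    checksums = {}
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            checksums[p.name] = _sha256(p)
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str) + "\n")
    return manifest
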