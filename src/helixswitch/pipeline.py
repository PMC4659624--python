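"""End-to-end orchestration of the two analysis workflows.

* **Pose pipeline** — cluster docking poses, fingerprint and classify the
  cluster representatives against the conserved receptor positions, and
  report the screw parameters between every pair of representatives.
* **Trajectory pipeline** — align frames onto a reference, compute the
  rotation/RMSD/distance/tilt traces with running averages, call the
  helix-switch event, and report the interface (including water counts)
  at the start and end of the trajectory.

Reports are tidy CSV/TSV plus JSON; every threshold that shaped a report is
echoed into it, so no hidden defaults leak into the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .geometry import fit_helix_axis, screw_about_axis
from .interface_analysis import HBondCriteria, CationPiCriteria, interface_report
from .model_io import (
    StructureModel,
    Trajectory,
    assign_generic_numbers,
    load_anchors,
    read_structure,
    select,
    write_structure,
)
from .pose_analysis import (
    PoseSet,
    classify_pose,
    contact_fingerprint,
    pairwise_rmsd_matrix,
    single_linkage_cluster,
)
from .trajectory_metrics import (
    SwitchCriteria,
    align_frames,
    detect_switch,
    distance_series,
    rmsd_series,
    rotation_series,
    running_average,
    tilt_series,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pose_pipeline", "run_traj_pipeline", "run_simulate"]


class ConfigError(ValueError):
    """User-facing configuration problem (exit code 1 in the CLI)."""


@dataclass
class RunConfig:
    """Configuration for both pipelines; unused fields may stay None."""

    # inputs
    receptor: Optional[str] = None
    poses: Optional[str] = None
    traj: Optional[str] = None
    reference: Optional[str] = None
    target: Optional[str] = None
    anchors: Optional[str] = None
    times: Optional[str] = None  # sidecar CSV: frame,time_ns
    dt: Optional[float] = None  # ns; alternative to the sidecar
    # selections
    peptide_selection: str = "chain P"
    receptor_selection: str = "chain R"
    helix_selection: str = "chain P and backbone"
    align_selection: str = "chain R and backbone"
    # thresholds
    cluster_cutoff: float = 1.5  # Å, single-linkage cut height
    hbond_d_max: float = 3.5
    cation_pi_d_max: float = 6.0
    cation_pi_angle_max: float = 45.0
    water_cutoff: float = 3.5
    rmsd_switch: float = 2.0
    min_persist_fraction: float = 0.8
    smooth_window: int = 5
    membrane_normal: tuple = (0.0, 0.0, 1.0)
    # distance groups: list of {"a": sel, "b": sel, "mode": ...}
    distance_groups: list = field(default_factory=list)
    # output
    out: str = "out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def updated(self, **overrides) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)

    def validate_paths(self, required: list[str]) -> None:
        for name in required:
            value = getattr(self, name)
            if value is None:
                raise ConfigError(f"config field {name!r} is required")
            if not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        for thr in ("cluster_cutoff", "hbond_d_max", "water_cutoff", "rmsd_switch"):
            if getattr(self, thr) <= 0:
                raise ConfigError(f"threshold {thr} must be positive")

    def thresholds_dict(self) -> dict:
        return {
            "cluster_cutoff_A": self.cluster_cutoff,
            "hbond_d_max_A": self.hbond_d_max,
            "cation_pi_d_max_A": self.cation_pi_d_max,
            "cation_pi_angle_max_deg": self.cation_pi_angle_max,
            "water_cutoff_A": self.water_cutoff,
            "rmsd_switch_A": self.rmsd_switch,
            "min_persist_fraction": self.min_persist_fraction,
            "smooth_window": self.smooth_window,
        }


class _OutputTracker:
    """Removes partial outputs if the pipeline fails midway."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.written: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.out_dir / name
        self.written.append(p)
        return p

    def cleanup(self):
        for p in self.written:
            p.unlink(missing_ok=True)


def _as_model_list(models) -> list[StructureModel]:
    return models if isinstance(models, list) else [models]


def run_pose_pipeline(config: RunConfig) -> dict:
    """Cluster poses, classify representatives, report inter-pose screws.

    Writes ``clusters.csv`` (rank, size, representative), ``states.csv``
    (per-representative state label and register shift),
    ``fingerprints.tsv`` and, for >1 cluster, ``screw_pairs.csv``.
    """
    config.validate_paths(["poses", "receptor", "anchors"])
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    tracker = _OutputTracker(out_dir)
    try:
        poses = PoseSet(_as_model_list(read_structure(config.poses)))
        receptor = read_structure(config.receptor)
        if isinstance(receptor, list):
            raise ConfigError("receptor file must contain a single model")
        numbering = assign_generic_numbers(None, load_anchors(config.anchors))

        if len(poses) > 1:
            dist = pairwise_rmsd_matrix(poses, selection="backbone")
            clusters = single_linkage_cluster(dist, config.cluster_cutoff)
            assignment = clusters.assignment
            sizes = clusters.sizes
            reps = clusters.representatives
        else:
            assignment = np.array([0])
            sizes = np.array([1])
            reps = np.array([0])

        pd.DataFrame(
            {
                "rank": np.arange(len(sizes)),
                "size": sizes,
                "representative": reps,
            }
        ).to_csv(tracker.path("clusters.csv"), index=False)

        hb = HBondCriteria(d_max=config.hbond_d_max)
        cp = CationPiCriteria(
            d_max=config.cation_pi_d_max, angle_max=config.cation_pi_angle_max
        )
        from .pose_analysis import ContactCriteria

        criteria = ContactCriteria(hbond=hb, cation_pi=cp)
        state_rows = []
        fp_rows = []
        for rank, rep in enumerate(reps):
            fp = contact_fingerprint(receptor, poses.poses[rep], numbering, criteria)
            state, shift = classify_pose(fp)
            state_rows.append(
                {
                    "rank": rank,
                    "representative": int(rep),
                    "state": state,
                    "register_shift": shift,
                    "n_contacts": len(fp.contacts),
                }
            )
            for c in sorted(fp.contacts, key=lambda c: (c.peptide_res_seq, c.receptor_label)):
                fp_rows.append(
                    {
                        "rank": rank,
                        "peptide_res_seq": c.peptide_res_seq,
                        "receptor_position": c.receptor_label,
                        "interaction": c.interaction,
                        "distance_A": round(c.distance, 3),
                        "bw_mapped": c.bw_mapped,
                    }
                )
        pd.DataFrame(state_rows).to_csv(tracker.path("states.csv"), index=False)
        pd.DataFrame(fp_rows).to_csv(tracker.path("fingerprints.tsv"), sep="\t", index=False)

        screw_rows = []
        if len(reps) > 1:
            axis_pose = select(poses.poses[reps[0]], "backbone")
            axis = fit_helix_axis(select(axis_pose, "name CA").coords)
            for i in range(len(reps)):
                for j in range(len(reps)):
                    if i == j:
                        continue
                    sp = screw_about_axis(
                        poses.poses[reps[i]], poses.poses[reps[j]], axis, "backbone"
                    )
                    screw_rows.append(
                        {"rank_from": i, "rank_to": j, **sp.to_csv_row()}
                    )
            pd.DataFrame(screw_rows).to_csv(tracker.path("screw_pairs.csv"), index=False)

        report = {
            "n_poses": len(poses),
            "n_clusters": int(len(sizes)),
            "sizes": [int(s) for s in sizes],
            "states": state_rows,
            "screw_pairs": screw_rows,
            "thresholds": config.thresholds_dict(),
        }
        with open(tracker.path("pose_report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("pose pipeline: %d poses -> %d clusters", len(poses), len(sizes))
        return report
    except Exception:
        tracker.cleanup()
        raise


def _read_times(config: RunConfig, n_frames: int) -> np.ndarray:
    if config.times is not None:
        df = pd.read_csv(config.times)
        if not {"frame", "time_ns"} <= set(df.columns):
            raise ConfigError("times sidecar needs columns frame,time_ns")
        if len(df) != n_frames:
            raise ConfigError(
                f"times sidecar has {len(df)} rows for {n_frames} frames"
            )
        return df.sort_values("frame")["time_ns"].to_numpy(dtype=float)
    if config.dt is not None:
        return config.dt * np.arange(n_frames)
    raise ConfigError("either a times sidecar or dt is required")


def run_traj_pipeline(config: RunConfig) -> dict:
    """Align a trajectory, compute Fig-style metric traces, call the switch.

    Writes ``series.csv`` (tidy: metric,time_ns,value,smoothed),
    ``switch.json`` and ``interface_start.json`` / ``interface_end.json``
    with before/after water counts.
    """
    config.validate_paths(["traj", "reference"])
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    tracker = _OutputTracker(out_dir)
    try:
        frames = _as_model_list(read_structure(config.traj))
        reference = read_structure(config.reference)
        if isinstance(reference, list):
            raise ConfigError("reference file must contain a single model")
        target = reference
        if config.target is not None:
            target = read_structure(config.target)
            if isinstance(target, list):
                raise ConfigError("target file must contain a single model")
        times = _read_times(config, len(frames))
        traj = Trajectory(frames, times)
        traj = align_frames(traj, reference, config.align_selection)

        ref_helix = select(reference, config.helix_selection)
        series = [
            rotation_series(traj, config.helix_selection, ref_helix),
            rmsd_series(traj, config.helix_selection, target),
            tilt_series(traj, config.helix_selection, np.asarray(config.membrane_normal)),
        ]
        for k, grp in enumerate(config.distance_groups):
            s = distance_series(traj, grp["a"], grp["b"], grp.get("mode", "centroid"))
            s.name = f"distance_{k}"
            series.append(s)
        series = [running_average(s, config.smooth_window) for s in series]
        pd.concat([s.to_frame() for s in series]).to_csv(
            tracker.path("series.csv"), index=False
        )

        criteria = SwitchCriteria(
            rmsd_switch=config.rmsd_switch,
            min_persist_fraction=config.min_persist_fraction,
            smooth_window=config.smooth_window,
        )
        event = detect_switch(series[0], series[1], criteria)

        numbering = None
        if config.anchors is not None:
            numbering = assign_generic_numbers(None, load_anchors(config.anchors))
        interface = {}
        for tag, frame in (("start", traj.frames[0]), ("end", traj.frames[-1])):
            rec = select(frame, config.receptor_selection)
            pep = select(frame, config.peptide_selection)
            if not rec.atoms or not pep.atoms:
                raise ConfigError(
                    "receptor/peptide selections resolved to no atoms in the trajectory"
                )
            rep = interface_report(
                rec,
                pep,
                scene=frame,
                sel_a=config.receptor_selection,
                sel_b=config.peptide_selection,
                water_cutoff=config.water_cutoff,
                hbond_criteria=HBondCriteria(d_max=config.hbond_d_max),
                cation_pi_criteria=CationPiCriteria(
                    d_max=config.cation_pi_d_max, angle_max=config.cation_pi_angle_max
                ),
            )
            interface[tag] = rep.to_dict()
            with open(tracker.path(f"interface_{tag}.json"), "w") as fh:
                json.dump(
                    {**rep.to_dict(), "thresholds": config.thresholds_dict()},
                    fh,
                    indent=2,
                )

        if event.detected and numbering is not None:
            last = traj.frames[-1]
            fp = contact_fingerprint(
                select(last, config.receptor_selection),
                select(last, config.peptide_selection),
                numbering,
            )
            event.final_state = classify_pose(fp)[0]

        with open(tracker.path("switch.json"), "w") as fh:
            json.dump(event.to_dict(), fh, indent=2)

        report = {
            "n_frames": len(traj),
            "switch": event.to_dict(),
            "interface": interface,
            "thresholds": config.thresholds_dict(),
            "series": {s.name: {"final": float(s.values[-1])} for s in series},
        }
        logger.info(
            "traj pipeline: %d frames, switch detected=%s", len(traj), event.detected
        )
        return report
    except Exception:
        tracker.cleanup()
        raise


def run_simulate(spec_path: str | Path, out: str | Path, seed: int | None = None) -> dict:
    """Generate synthetic inputs from a YAML spec and write them to disk.

    Spec schema: ``kind`` is one of ``switch_trajectory``, ``pose_set``,
    ``register_pose_set`` or ``interface_scene``; remaining keys are the
    corresponding generator's parameters.  The seed used is logged and
    returned.
    """
    spec_path = Path(spec_path)
    if not spec_path.exists():
        raise ConfigError(f"spec file does not exist: {spec_path}")
    with open(spec_path) as fh:
        data = yaml.safe_load(fh) or {}
    kind = data.pop("kind", None)
    if seed is not None:
        data["seed"] = seed
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def save_anchors(path: Path):
        synthetic.scene_anchor_table().to_csv(path, index=False)

    try:
        if kind == "switch_trajectory":
            helix_kwargs = data.pop("helix", {})
            if helix_kwargs:
                raise ConfigError(
                    "switch trajectories use the built-in scene peptide; "
                    "'helix' overrides are not supported"
                )
            spec = synthetic.SwitchTrajectorySpec(**data)
            res = synthetic.make_switch_trajectory(spec)
            write_structure(res.trajectory.frames, out_dir / "frames.pdb")
            write_structure(res.reference, out_dir / "reference.pdb")
            write_structure(res.target, out_dir / "target.pdb")
            pd.DataFrame(
                {"frame": np.arange(len(res.trajectory)), "time_ns": res.trajectory.times}
            ).to_csv(out_dir / "times.csv", index=False)
            res.truth.to_csv(out_dir / "truth.csv", index=False)
            save_anchors(out_dir / "anchors.csv")
            written = {
                k: str(out_dir / v)
                for k, v in {
                    "frames": "frames.pdb",
                    "reference": "reference.pdb",
                    "target": "target.pdb",
                    "times": "times.csv",
                    "truth": "truth.csv",
                    "anchors": "anchors.csv",
                }.items()
            }
            used_seed = spec.seed
        elif kind == "pose_set":
            sizes = tuple(data.pop("sizes", (11, 6, 3)))
            poses, labels = synthetic.make_pose_set(
                k_centers=data.pop("k_centers", len(sizes)), sizes=sizes, **data
            )
            write_structure(poses.poses, out_dir / "poses.pdb")
            pd.DataFrame({"pose": np.arange(len(poses)), "planted_cluster": labels}).to_csv(
                out_dir / "labels.csv", index=False
            )
            written = {"poses": str(out_dir / "poses.pdb"), "labels": str(out_dir / "labels.csv")}
            used_seed = data.get("seed", 0)
        elif kind == "register_pose_set":
            poses, labels, scene = synthetic.make_register_pose_set(**data)
            write_structure(poses.poses, out_dir / "poses.pdb")
            write_structure(scene.receptor, out_dir / "receptor.pdb")
            pd.DataFrame({"pose": np.arange(len(poses)), "planted_register": labels}).to_csv(
                out_dir / "labels.csv", index=False
            )
            save_anchors(out_dir / "anchors.csv")
            written = {
                "poses": str(out_dir / "poses.pdb"),
                "receptor": str(out_dir / "receptor.pdb"),
                "labels": str(out_dir / "labels.csv"),
                "anchors": str(out_dir / "anchors.csv"),
            }
            used_seed = data.get("seed", 0)
        elif kind == "interface_scene":
            spec = synthetic.InterfaceSceneSpec(**data)
            scene = synthetic.make_interface_scene(spec)
            write_structure(scene.scene, out_dir / "scene.pdb")
            write_structure(scene.receptor, out_dir / "receptor.pdb")
            write_structure(scene.peptide, out_dir / "peptide.pdb")
            pd.DataFrame(
                sorted(scene.expected_contacts),
                columns=["peptide_res_seq", "receptor_position", "interaction"],
            ).to_csv(out_dir / "expected_contacts.csv", index=False)
            save_anchors(out_dir / "anchors.csv")
            written = {
                "scene": str(out_dir / "scene.pdb"),
                "receptor": str(out_dir / "receptor.pdb"),
                "peptide": str(out_dir / "peptide.pdb"),
                "expected_contacts": str(out_dir / "expected_contacts.csv"),
                "anchors": str(out_dir / "anchors.csv"),
            }
            used_seed = spec.seed
        else:
            raise ConfigError(
                f"unknown spec kind {kind!r}; expected switch_trajectory, "
                f"pose_set, register_pose_set or interface_scene"
            )
    except TypeError as exc:
        raise ConfigError(f"invalid generator parameters: {exc}") from exc
    logger.info("simulate kind=%s seed=%s -> %s", kind, used_seed, sorted(written))
    return {"kind": kind, "seed": used_seed, "files": written}
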