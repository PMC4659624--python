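"""Per-frame metric traces and helix-switch event detection.

Reproduces the standard trajectory observables for the α5 helix-switch:
rotation of the peptide about its helix axis, backbone RMSD to a reference
pose (without re-superposing the peptide — position within the crevice is the
signal), landmark distances such as the C-cap tyrosine ring centroid to
R\\ :sup:`3.50`, helix tilt against the membrane plane, centred running
averages, and the switch call itself.

A switch is called when the smoothed RMSD to the target (X-ray-like) pose
drops below a threshold and stays below it for most of the remaining
trajectory — the operational form of a transition to a conformation that is
maintained for the rest of the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import (
    HelixAxis,
    fit_helix_axis,
    kabsch_superpose,
    rmsd,
    screw_about_axis,
    tilt_angle,
)
from .model_io import StructureModel, Trajectory, select

__all__ = [
    "TimeSeriesMetric",
    "SwitchCriteria",
    "SwitchEvent",
    "align_frames",
    "rotation_series",
    "rmsd_series",
    "distance_series",
    "running_average",
    "detect_switch",
    "tilt_series",
]


@dataclass
class TimeSeriesMetric:
    """A per-frame metric trace with optional running-average smoothing."""

    name: str
    times: np.ndarray  # ns
    values: np.ndarray
    units: str
    smoothed: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if len(self.smoothed) != len(self.values):
                raise ValueError("smoothed trace must match values length")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"metric": self.name, "time_ns": self.times, "value": self.values}
        )
        df["smoothed"] = self.smoothed if self.smoothed is not None else np.nan
        return df


@dataclass(frozen=True)
class SwitchCriteria:
    rmsd_switch: float = 2.0  # Å to the target pose
    min_persist_fraction: float = 0.8  # of frames after onset
    smooth_window: int = 5  # frames, odd


@dataclass
class SwitchEvent:
    detected: bool
    onset_time: Optional[float]  # ns
    onset_index: Optional[int]
    criteria: SwitchCriteria
    final_state: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "detected": self.detected,
            "onset_time_ns": self.onset_time,
            "onset_index": self.onset_index,
            "final_state": self.final_state,
            "criteria": {
                "rmsd_switch_A": self.criteria.rmsd_switch,
                "min_persist_fraction": self.criteria.min_persist_fraction,
                "smooth_window": self.criteria.smooth_window,
            },
        }


def align_frames(
    traj: Trajectory,
    reference: StructureModel,
    align_selection: str = "backbone",
) -> Trajectory:
    """Superpose every frame onto the reference by Kabsch on a selection.

    Removes global receptor motion so that peptide metrics become
    receptor-frame quantities; pure transformation, atom identity unchanged.
    """
    ref_sel = select(reference, align_selection)
    if not ref_sel.atoms:
        raise ValueError(f"alignment selection {align_selection!r} empty in reference")
    ref_keys = [a.key for a in ref_sel.atoms]
    ref_coords = ref_sel.coords
    aligned = []
    for i, frame in enumerate(traj.frames):
        fr_sel = select(frame, align_selection)
        if [a.key for a in fr_sel.atoms] != ref_keys:
            raise ValueError(
                f"alignment selection mismatch between reference and frame {i}"
            )
        transform, _ = kabsch_superpose(fr_sel.coords, ref_coords)
        aligned.append(frame.with_coords(transform.apply(frame.coords)))
    return Trajectory(aligned, traj.times.copy())


def rotation_series(
    traj: Trajectory,
    helix_selection: str,
    reference_pose: StructureModel,
    per_frame_axis: bool = False,
) -> TimeSeriesMetric:
    """Rotation of the helix about its axis relative to the reference (degrees).

    The axis is fitted once on the reference pose Cα and held fixed so that
    frame-to-frame rotation stays well defined even if the helix bends
    slightly; ``per_frame_axis`` refits on every frame instead.
    """
    ref_sel = select(reference_pose, helix_selection)
    ref_ca = select(ref_sel, "name CA")
    axis = fit_helix_axis(ref_ca.coords)
    values = []
    for frame in traj.frames:
        if per_frame_axis:
            frame_ca = select(select(frame, helix_selection), "name CA")
            axis_i = fit_helix_axis(frame_ca.coords)
        else:
            axis_i = axis
        sp = screw_about_axis(ref_sel, select(frame, helix_selection), axis_i, None)
        values.append(sp.angle)
    return TimeSeriesMetric(
        "helix_rotation",
        traj.times,
        np.array(values),
        "degrees",
        params={"selection": helix_selection, "per_frame_axis": per_frame_axis},
    )


def rmsd_series(
    traj: Trajectory,
    selection: str,
    reference_pose: StructureModel,
) -> TimeSeriesMetric:
    """Per-frame RMSD (Å) to the reference pose, without re-superposition."""
    ref = select(reference_pose, selection)
    if not ref.atoms:
        raise ValueError(f"selection {selection!r} empty in reference")
    ref_keys = [a.key for a in ref.atoms]
    values = []
    for i, frame in enumerate(traj.frames):
        sub = select(frame, selection)
        if [a.key for a in sub.atoms] != ref_keys:
            raise ValueError(f"selection mismatch at frame {i}")
        values.append(rmsd(sub.coords, ref.coords, superpose=False))
    return TimeSeriesMetric(
        "rmsd", traj.times, np.array(values), "A", params={"selection": selection}
    )


def _group_point(model: StructureModel, spec: str, mode: str) -> np.ndarray:
    sub = select(model, spec)
    if not sub.atoms:
        raise ValueError(f"group selection {spec!r} matched no atoms")
    if mode == "atom":
        if len(sub.atoms) != 1:
            raise ValueError(
                f"mode 'atom' requires exactly one atom, {spec!r} matched {len(sub.atoms)}"
            )
        return sub.coords[0]
    return sub.coords.mean(0)


def distance_series(
    traj: Trajectory,
    group_a: str,
    group_b: str,
    mode: str = "centroid",
) -> TimeSeriesMetric:
    """Per-frame distance (Å) between two atom groups.

    ``mode``: "centroid" (e.g. the six-atom phenyl-ring centre), "min"
    (closest heavy-atom pair), or "atom" (single named atom on each side).
    """
    if mode not in ("centroid", "min", "atom"):
        raise ValueError(f"unknown mode {mode!r}")
    values = []
    for frame in traj.frames:
        if mode == "min":
            a = select(frame, group_a)
            b = select(frame, group_b)
            if not a.atoms or not b.atoms:
                raise ValueError("group selection matched no atoms")
            diff = a.coords[:, None, :] - b.coords[None, :, :]
            values.append(float(np.sqrt((diff**2).sum(-1)).min()))
        else:
            pa = _group_point(frame, group_a, mode)
            pb = _group_point(frame, group_b, mode)
            values.append(float(np.linalg.norm(pa - pb)))
    return TimeSeriesMetric(
        "distance",
        traj.times,
        np.array(values),
        "A",
        params={"group_a": group_a, "group_b": group_b, "mode": mode},
    )


def running_average(series: TimeSeriesMetric, window: int) -> TimeSeriesMetric:
    """Centred moving mean; edges use shrunken windows (no padding invented)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(series.values):
        raise ValueError(
            f"window {window} longer than series ({len(series.values)} frames)"
        )
    smoothed = (
        pd.Series(series.values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return TimeSeriesMetric(
        series.name,
        series.times,
        series.values,
        series.units,
        smoothed=smoothed,
        params={**series.params, "window": window},
    )


def detect_switch(
    rotation: TimeSeriesMetric | None,
    rmsd_metric: TimeSeriesMetric,
    criteria: SwitchCriteria | None = None,
) -> SwitchEvent:
    """Call a helix-switch from the RMSD-to-target trace.

    Detected iff the smoothed RMSD drops below ``rmsd_switch`` at some onset
    and remains below for at least ``min_persist_fraction`` of the frames
    after the onset; the onset is the first such frame.  The rotation trace
    is accepted for grid validation (both series must share the time grid).
    """
    criteria = criteria or SwitchCriteria()
    if rotation is not None and not np.array_equal(rotation.times, rmsd_metric.times):
        raise ValueError("rotation and rmsd series are on different time grids")
    n = len(rmsd_metric.values)
    if n < criteria.smooth_window:
        raise ValueError("series shorter than the smoothing window")
    smoothed = running_average(rmsd_metric, criteria.smooth_window).smoothed
    below = smoothed < criteria.rmsd_switch
    # fraction of frames below threshold from each index to the end
    tail_below = np.cumsum(below[::-1])[::-1]
    remaining = n - np.arange(n)
    persist = tail_below / remaining
    ok = below & (persist >= criteria.min_persist_fraction)
    if not ok.any():
        return SwitchEvent(False, None, None, criteria)
    onset = int(np.argmax(ok))
    return SwitchEvent(True, float(rmsd_metric.times[onset]), onset, criteria)


def tilt_series(
    traj: Trajectory,
    helix_selection: str,
    membrane_normal: np.ndarray = (0.0, 0.0, 1.0),
) -> TimeSeriesMetric:
    """Per-frame helix tilt (degrees) against the membrane plane.

    The axis is refitted on every frame; the membrane normal defaults to the
    z-axis of the input frame, the usual MD box convention.
    """
    normal = np.asarray(membrane_normal, dtype=float)
    values = []
    for frame in traj.frames:
        ca = select(select(frame, helix_selection), "name CA")
        axis = fit_helix_axis(ca.coords)
        values.append(tilt_angle(axis, normal))
    return TimeSeriesMetric(
        "tilt",
        traj.times,
        np.array(values),
        "degrees",
        params={"selection": helix_selection, "normal": list(map(float, normal))},
    )
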