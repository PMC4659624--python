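"""Rigid-body superposition, helix-axis fitting and screw-motion decomposition.

The α5 C-terminal helix repositions between the GDP-bound intermediate and the
nucleotide-free receptor–G-protein complex by a screw-like motion: a rotation
about its own helix axis combined with a translation along it.  This module
provides the mathematical core for quantifying that motion:

* :func:`kabsch_superpose` — weighted least-squares rigid superposition
  (proper rotations only);
* :func:`fit_helix_axis` — total-least-squares axis through sliding centroids
  of four consecutive Cα atoms (one helical turn ≈ 3.6 residues), with rise
  and twist per residue;
* :func:`screw_about_axis` — the restricted best fit over the motion family
  {rotate θ about a fixed axis, translate d along it}, the operational
  definition of "rotation around the helix axis" used for pose-to-pose and
  frame-to-frame comparisons;
* :func:`chasles_decompose` — the free screw (Chasles) decomposition of an
  arbitrary proper rigid transform, provided as a cross-check.

Angles are degrees in (−180, 180], right-hand rule about the N→C axis
direction; distances in Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import StructureModel, select

__all__ = [
    "RigidTransform",
    "HelixAxis",
    "ScrewParameters",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "rmsd",
    "fit_helix_axis",
    "screw_about_axis",
    "chasles_decompose",
    "recompose",
    "tilt_angle",
]


class DegenerateGeometryError(ValueError):
    """Raised when the input geometry does not determine a unique answer."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: x ↦ R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9:
            raise ValueError("rotation is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant differs from +1 (reflection?)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass(frozen=True)
class HelixAxis:
    """A fitted axis line (point + unit direction, oriented N→C).

    ``rise_per_residue`` (Å) and ``twist_per_residue`` (degrees) are set for
    genuine helix fits and ``None`` for free screw axes.  ``fit_rmsd`` is the
    RMS distance of the sliding-window centroids from the fitted line.
    """

    point: np.ndarray
    direction: np.ndarray
    rise_per_residue: Optional[float] = None
    twist_per_residue: Optional[float] = None
    fit_rmsd: Optional[float] = None
    warning: bool = False

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector (within 1e-12)")

    def transformed(self, t: RigidTransform) -> "HelixAxis":
        return HelixAxis(
            t.apply(self.point),
            t.rotation @ self.direction,
            self.rise_per_residue,
            self.twist_per_residue,
            self.fit_rmsd,
            self.warning,
        )


@dataclass(frozen=True)
class ScrewParameters:
    """Rotation angle about an axis plus translation along it.

    Reapplying (angle, translation) about ``axis`` to the source pose
    reproduces the target within ``residual_rmsd``.
    """

    axis: HelixAxis
    angle: float  # degrees, (-180, 180]
    translation_along_axis: float  # Å
    residual_rmsd: float  # Å

    def to_csv_row(self) -> dict:
        return {
            "angle_deg": self.angle,
            "slide_A": self.translation_along_axis,
            "residual_A": self.residual_rmsd,
            "axis_px": self.axis.point[0],
            "axis_py": self.axis.point[1],
            "axis_pz": self.axis.point[2],
            "axis_dx": self.axis.direction[0],
            "axis_dy": self.axis.direction[1],
            "axis_dz": self.axis.direction[2],
        }


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Weighted least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimizing the weighted RMSD and that
    RMSD.  Reflections are excluded by construction (SVD sign correction).
    Raises :class:`DegenerateGeometryError` for <3 points or collinear input,
    where the rotation is not unique.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"coordinate sets must match in shape: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(
            f"need at least 3 points for a unique superposition, got {n}"
        )
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    cm = (w[:, None] * P).sum(0) / wsum
    cr = (w[:, None] * Q).sum(0) / wsum
    P0 = P - cm
    Q0 = Q - cr
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear point sets leave the rotation about the line undetermined
    if S[1] <= 1e-8 * max(S[0], 1.0):
        raise DegenerateGeometryError(
            "input points are (nearly) collinear; rotation is not unique"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cr - R @ cm
    transform = RigidTransform(R, t)
    diff = transform.apply(P) - Q
    out_rmsd = float(np.sqrt((w * (diff**2).sum(1)).sum() / wsum))
    return transform, out_rmsd


def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation between two equally sized coordinate sets.

    ``superpose=True`` applies a Kabsch fit first; otherwise the deviation is
    taken in the current frame (the receptor-frame signal used for trajectory
    metrics).
    """
    A = np.asarray(a, dtype=float)
    B = np.asarray(b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"mismatched coordinate counts: {A.shape} vs {B.shape}")
    if A.size == 0:
        raise ValueError("empty coordinate sets")
    if superpose:
        _, value = kabsch_superpose(A, B)
        return value
    return float(np.sqrt(((A - B) ** 2).sum(1).mean()))


# ---------------------------------------------------------------------------
# Helix axis
# ---------------------------------------------------------------------------

_AXIS_WINDOW = 4  # Cα per sliding centroid, ~one helical turn


def fit_helix_axis(ca_coords: np.ndarray, sanity_rmsd: float = 1.0) -> HelixAxis:
    """Fit the helix axis through ordered Cα coordinates (N→C).

    The axis is the total-least-squares line through centroids of sliding
    windows of four consecutive Cα atoms; rise is the mean axial spacing of
    consecutive residues and twist the mean angular advance of Cα projections
    about the axis.  A fit RMSD above ``sanity_rmsd`` sets the ``warning``
    flag (and emits a warning) but does not raise.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("ca_coords must be (N, 3)")
    n = ca.shape[0]
    if n < _AXIS_WINDOW + 1:
        raise ValueError(f"need at least {_AXIS_WINDOW + 1} Cα positions, got {n}")
    centroids = np.array(
        [ca[i : i + _AXIS_WINDOW].mean(0) for i in range(n - _AXIS_WINDOW + 1)]
    )
    center = centroids.mean(0)
    _, svals, vt = np.linalg.svd(centroids - center)
    direction = vt[0]
    if direction @ (centroids[-1] - centroids[0]) < 0:
        direction = -direction
    # RMS perpendicular distance of centroids from the fitted line
    perp = (centroids - center) - np.outer((centroids - center) @ direction, direction)
    fit_rmsd = float(np.sqrt((perp**2).sum(1).mean()))

    axial = ca @ direction
    rise = float(np.diff(axial).mean())

    rel = ca - center
    proj = rel - np.outer(rel @ direction, direction)
    angles = []
    for p, q in zip(proj[:-1], proj[1:]):
        angles.append(np.arctan2(direction @ np.cross(p, q), p @ q))
    twist = float(np.degrees(np.mean(angles)))

    warn = fit_rmsd > sanity_rmsd
    if warn:
        warnings.warn(
            f"helix axis fit RMSD {fit_rmsd:.2f} Å exceeds sanity bound "
            f"{sanity_rmsd:.2f} Å",
            stacklevel=2,
        )
    return HelixAxis(center, direction, rise, twist, fit_rmsd, warn)


# ---------------------------------------------------------------------------
# Screw motions
# ---------------------------------------------------------------------------

def _wrap_angle(deg: float) -> float:
    wrapped = (deg + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def screw_about_axis(
    pose_a: StructureModel | np.ndarray,
    pose_b: StructureModel | np.ndarray,
    axis: HelixAxis,
    atom_selection: str | None = "backbone",
) -> ScrewParameters:
    """Best fit of pose_a → pose_b within the restricted screw family.

    The family is {rotate θ about ``axis``, then translate d along it}.  Both
    parameters have closed forms: d is the mean axial displacement and θ the
    atan2 of summed cross/dot products of the axis-perpendicular components,
    sign by right-hand rule about the N→C direction.  The residual RMSD of
    the fit is reported; it is never smaller than the free Kabsch RMSD.
    """
    A = _resolve_coords(pose_a, atom_selection)
    B = _resolve_coords(pose_b, atom_selection)
    if A.shape != B.shape:
        raise ValueError("selections differ between the two poses")
    if A.shape[0] == 0:
        raise ValueError("empty atom selection")
    u = axis.direction
    ra = A - axis.point
    rb = B - axis.point
    d = float(((rb - ra) @ u).mean())
    pa = ra - np.outer(ra @ u, u)
    pb = rb - np.outer(rb @ u, u)
    if np.max(np.linalg.norm(pa, axis=1)) < 1e-9:
        raise DegenerateGeometryError(
            "all atoms lie on the axis; rotation angle is undefined"
        )
    num = float((np.cross(pa, pb) @ u).sum())
    den = float((pa * pb).sum())
    theta = np.degrees(np.arctan2(num, den))
    sp = ScrewParameters(axis, _wrap_angle(theta), d, 0.0)
    moved = recompose(sp).apply(A)
    residual = float(np.sqrt(((moved - B) ** 2).sum(1).mean()))
    return ScrewParameters(axis, _wrap_angle(theta), d, residual)


def _resolve_coords(pose, atom_selection) -> np.ndarray:
    if isinstance(pose, StructureModel):
        sub = select(pose, atom_selection) if atom_selection else pose
        return sub.coords if sub.atoms else np.empty((0, 3))
    return np.asarray(pose, dtype=float)


def recompose(screw: ScrewParameters) -> RigidTransform:
    """The rigid transform realizing a set of screw parameters."""
    u = screw.axis.direction
    c = screw.axis.point
    R = Rotation.from_rotvec(np.radians(screw.angle) * u).as_matrix()
    t = c - R @ c + screw.translation_along_axis * u
    return RigidTransform(R, t)


_PURE_TRANSLATION_ANGLE = 0.1  # degrees


def chasles_decompose(t: RigidTransform) -> ScrewParameters:
    """Unique screw axis/angle/slide of an arbitrary proper rigid transform.

    For |angle| below 0.1° the motion is reported in pure-translation form:
    angle 0, axis along the translation vector.
    """
    rot = Rotation.from_matrix(t.rotation)
    rotvec = rot.as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < _PURE_TRANSLATION_ANGLE:
        norm = np.linalg.norm(t.translation)
        u = t.translation / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        return ScrewParameters(
            HelixAxis(np.zeros(3), u), 0.0, float(norm), 0.0
        )
    u = rotvec / np.radians(angle)
    slide = float(t.translation @ u)
    t_perp = t.translation - slide * u
    # axis point solves (I - R) c = t_perp in the plane orthogonal to u
    c, *_ = np.linalg.lstsq(np.eye(3) - t.rotation, t_perp, rcond=None)
    c = c - (c @ u) * u
    return ScrewParameters(HelixAxis(c, u), _wrap_angle(angle), slide, 0.0)


def tilt_angle(axis: HelixAxis, reference_normal: np.ndarray) -> float:
    """Angle between the helix axis and the plane orthogonal to the normal.

    In degrees, range [−90, 90], positive when the axis points toward the
    normal (by MD convention the membrane normal, default ẑ elsewhere).
    """
    n = np.asarray(reference_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("reference normal must be non-zero")
    n = n / norm
    return float(np.degrees(np.arcsin(np.clip(axis.direction @ n, -1.0, 1.0))))
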