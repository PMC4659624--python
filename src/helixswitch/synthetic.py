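"""Seeded generators for every input the pipeline needs.

Real inputs for this kind of analysis are docking poses and MD trajectories of
GαCT peptides in the cytoplasmic crevice of an active GPCR.  This module
replaces them with fully synthetic, seeded stand-ins built around an ideal
α-helix (φ = −57°, ψ = −47°, textbook peptide internal coordinates):

* :func:`build_ideal_helix` — backbone (+CB) helix from internal coordinates;
* :func:`make_interface_scene` — a deliberately minimal receptor scaffold
  (an arginine probe at position 3.50, a main-chain carbonyl probe at 3.54)
  with the peptide placed in either contact register, plus bridging and bulk
  waters and the expected contact fingerprint;
* :func:`make_switch_trajectory` — a trajectory with a planted switch: the
  peptide starts in the GDP-intermediate register and screws into the
  nucleotide-free register along a logistic ramp (default 60° / 1.5 Å),
  with i.i.d. Gaussian coordinate noise, plus the per-frame ground truth;
* :func:`make_pose_set` / :func:`make_register_pose_set` — pose ensembles
  with planted cluster structure for clustering and end-to-end tests.

Every generator is a pure function of its spec and seed: identical calls are
bit-identical, and stochastic outputs always come with their ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import HelixAxis, RigidTransform, ScrewParameters, fit_helix_axis, recompose
from .model_io import Atom, GenericNumberMap, StructureModel, Trajectory, assign_generic_numbers, select
from .pose_analysis import PoseSet

__all__ = [
    "HelixSpec",
    "SwitchTrajectorySpec",
    "InterfaceSceneSpec",
    "InterfaceScene",
    "SwitchTrajectoryResult",
    "build_ideal_helix",
    "make_interface_scene",
    "make_switch_trajectory",
    "make_pose_set",
    "make_register_pose_set",
    "scene_anchor_table",
    "PLANTED_SCREW_ANGLE",
    "PLANTED_SCREW_SLIDE",
]

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Canonical peptide internal coordinates (Å / degrees); overridable per spec.
INTERNAL_COORDS = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "CA-CB": 1.530,
    "N-CA-C": 110.0,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.5,
    "N-CA-CB": 110.5,
    "C-N-CA-CB": -122.6,
}

#: Magnitudes of the planted helix-switch screw motion.
PLANTED_SCREW_ANGLE = 60.0  # degrees
PLANTED_SCREW_SLIDE = 1.5  # Å


@dataclass(frozen=True)
class HelixSpec:
    """An ideal α-helical peptide."""

    sequence: str = "AAAAAAAAAAA"  # 11-mer
    phi: float = -57.7
    psi: float = -47.5
    omega: float = 180.0
    chain_id: str = "P"
    first_res_seq: int = 1
    internal_coords: dict = field(default_factory=dict, hash=False)

    def __post_init__(self):
        if len(self.sequence) < 5:
            raise ValueError("sequence must be at least 5 residues")
        unknown = set(self.sequence) - set(THREE_LETTER)
        if unknown:
            raise ValueError(f"unknown residue letters {sorted(unknown)}")
        for name, val in (("phi", self.phi), ("psi", self.psi), ("omega", self.omega)):
            if not -180.0 <= val <= 180.0:
                raise ValueError(f"{name} must be in [-180, 180]")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom d from three predecessors: |c−d| = r, angle(b,c,d) = theta,
    dihedral(a,b,c,d) = phi (degrees)."""
    th = np.radians(theta)
    ph = np.radians(phi)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [-r * np.cos(th), r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_ideal_helix(spec: HelixSpec = HelixSpec()) -> StructureModel:
    """Backbone N/CA/C/O (+CB for non-Gly) helix from internal coordinates.

    Atoms in N→C order, deterministic.  The default φ/ψ (−57.7°/−47.5°, with
    N–CA–C 110°) give the canonical α-helix: rise 1.50 Å per residue,
    ≈ 3.6 residues per turn (twist ≈ 99.6°/residue).
    """
    ic = {**INTERNAL_COORDS, **spec.internal_coords}
    n_res = len(spec.sequence)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (ic["N-CA"], 0.0, 0.0)
    a = np.radians(180.0 - ic["N-CA-C"])
    C[0] = CA[0] + ic["CA-C"] * np.array([np.cos(a), np.sin(a), 0.0])
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], ic["C-N"], ic["CA-C-N"], spec.psi)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], ic["N-CA"], ic["C-N-CA"], spec.omega)
        C[i] = _nerf(C[i - 1], N[i], CA[i], ic["CA-C"], ic["N-CA-C"], spec.phi)

    atoms: list[Atom] = []
    serial = 1

    def add(name: str, element: str, res_i: int, xyz: np.ndarray):
        nonlocal serial
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                res_name=THREE_LETTER[spec.sequence[res_i]],
                res_seq=spec.first_res_seq + res_i,
                chain_id=spec.chain_id,
                xyz=np.asarray(xyz, dtype=float),
            )
        )
        serial += 1

    for i in range(n_res):
        add("N", "N", i, N[i])
        add("CA", "C", i, CA[i])
        add("C", "C", i, C[i])
        O = _nerf(N[i], CA[i], C[i], ic["C-O"], ic["CA-C-O"], spec.psi + 180.0)
        add("O", "O", i, O)
        if spec.sequence[i] != "G":
            CB = _nerf(C[i], N[i], CA[i], ic["CA-CB"], ic["N-CA-CB"], ic["C-N-CA-CB"])
            add("CB", "C", i, CB)
    return StructureModel(1, atoms)


# ---------------------------------------------------------------------------
# The two-register interface scene
# ---------------------------------------------------------------------------

#: GsαCT-like 11-mer, author numbering 382–392 (C-terminus E392, cap
#: tyrosine Y391, N-terminal contacts Q384/R385).
SCENE_SEQUENCE = "IIQRMHLRQYE"
SCENE_FIRST_RES = 382
SCENE_C_TERM = 392

_RES = {  # residue numbers of the actors
    "GLN": 384,
    "ARG_PEP": 385,
    "TYR": 391,
    "GLU": 392,
}
_RECEPTOR_ARG = 131  # 3.50
_RECEPTOR_ILE = 135  # 3.54

_CATION_PI_DIST = 4.0  # Å, planted ring-centroid to guanidinium distance
_HBOND_DIST = 2.9  # Å, planted donor–acceptor distances


def scene_anchor_table() -> pd.DataFrame:
    """Numbering anchors for the synthetic receptor: R131 pinned to 3.50."""
    return pd.DataFrame(
        [
            {
                "chain": "R",
                "res_seq": _RECEPTOR_ARG,
                "bw_label": "3.50",
                "segment_start": 127,
                "segment_end": 139,
            }
        ]
    )


@dataclass
class _SceneCore:
    peptide_empty: StructureModel  # chain P, nucleotide-free-like register
    peptide_intermediate: StructureModel  # GDP-intermediate register
    receptor: StructureModel  # chain R
    axis: HelixAxis
    screw: ScrewParameters  # maps intermediate -> empty
    numbering: GenericNumberMap
    # (peptide res_seq, probe, class) triples per register
    expected_empty: set[tuple[int, str, str]]
    expected_intermediate: set[tuple[int, str, str]]
    # contact atoms used for water bridging, per register
    bridge_pair_empty: tuple[np.ndarray, np.ndarray]
    bridge_pair_intermediate: tuple[np.ndarray, np.ndarray]


def _radial_frame(axis: HelixAxis, point: np.ndarray):
    """(radial, tangential) unit vectors of the axis frame at ``point``."""
    u = axis.direction
    rel = point - axis.point
    rd = rel - (rel @ u) * u
    rd /= np.linalg.norm(rd)
    return rd, np.cross(rd, u)


def _scene_core() -> _SceneCore:
    helix = build_ideal_helix(
        HelixSpec(sequence=SCENE_SEQUENCE, first_res_seq=SCENE_FIRST_RES, chain_id="P")
    )
    axis = fit_helix_axis(select(helix, "name CA").coords)
    u = axis.direction
    screw = ScrewParameters(axis, PLANTED_SCREW_ANGLE, PLANTED_SCREW_SLIDE, 0.0)
    S = recompose(screw)  # intermediate -> empty
    atom_of = {(a.res_seq, a.name): a for a in helix.atoms}

    def pos(res: int, name: str) -> np.ndarray:
        return atom_of[(res, name)].xyz

    extra: dict[int, list[tuple[str, str, np.ndarray]]] = {}

    def add_extra(res: int, name: str, element: str, xyz: np.ndarray):
        extra.setdefault(res, []).append((name, element, np.asarray(xyz, float)))

    # --- Y391 ring, face-on to the outside of the helix -------------------
    y = _RES["TYR"]
    rd_y, tg_y = _radial_frame(axis, pos(y, "CA"))
    ring_centroid = pos(y, "CB") + 2.5 * rd_y
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    for k, name in enumerate(ring_names):
        ang = np.radians(60.0 * k)
        add_extra(y, name, "C", ring_centroid + 1.39 * (np.cos(ang) * u + np.sin(ang) * tg_y))

    # --- receptor Arg131 (3.50 probe): guanidinium on the ring normal -----
    arg_cz = ring_centroid + _CATION_PI_DIST * rd_y
    arg_nh1 = arg_cz + 1.33 * rd_y
    arg_ne = arg_cz + 1.33 * (-0.5 * rd_y + 0.866 * tg_y)
    arg_nh2 = arg_cz + 1.33 * (-0.5 * rd_y - 0.866 * tg_y)
    arg_base = arg_cz + 2.5 * rd_y + 1.5 * u  # backbone kept clear of the interface
    receptor_atoms = [
        ("ARG", _RECEPTOR_ARG, "N", "N", arg_base + 1.46 * tg_y),
        ("ARG", _RECEPTOR_ARG, "CA", "C", arg_base),
        ("ARG", _RECEPTOR_ARG, "C", "C", arg_base - 1.53 * tg_y),
        ("ARG", _RECEPTOR_ARG, "O", "O", arg_base - 1.53 * tg_y + 1.23 * rd_y),
        ("ARG", _RECEPTOR_ARG, "NE", "N", arg_ne),
        ("ARG", _RECEPTOR_ARG, "CZ", "C", arg_cz),
        ("ARG", _RECEPTOR_ARG, "NH1", "N", arg_nh1),
        ("ARG", _RECEPTOR_ARG, "NH2", "N", arg_nh2),
    ]

    # --- Q384 amide and the receptor 3.54 carbonyl probe -------------------
    q = _RES["GLN"]
    rd_q, tg_q = _radial_frame(axis, pos(q, "CA"))
    q_cd = pos(q, "CB") + 1.30 * rd_q
    q_ne2 = q_cd + 1.33 * rd_q
    q_oe1 = q_cd + 1.23 * (-0.5 * rd_q + 0.866 * tg_q)
    add_extra(q, "CD", "C", q_cd)
    add_extra(q, "OE1", "O", q_oe1)
    add_extra(q, "NE2", "N", q_ne2)

    ile_o = q_ne2 + _HBOND_DIST * rd_q
    ile_c = ile_o + 1.23 * rd_q
    ile_n = ile_c + 1.33 * u
    ile_ca = ile_c + 1.52 * (0.3 * rd_q - 0.954 * u)
    receptor_atoms += [
        ("ILE", _RECEPTOR_ILE, "N", "N", ile_n),
        ("ILE", _RECEPTOR_ILE, "CA", "C", ile_ca),
        ("ILE", _RECEPTOR_ILE, "C", "C", ile_c),
        ("ILE", _RECEPTOR_ILE, "O", "O", ile_o),
    ]

    # --- E392 carboxylate: placed so that in the INTERMEDIATE register it
    # hydrogen-bonds to the Arg131 guanidinium.  Atoms are stored in the
    # empty-register pose, i.e. at the planted screw image of the target
    # intermediate-register position. --------------------------------------
    e_oe1_b = arg_nh1 + _HBOND_DIST * rd_y
    e_cd_b = e_oe1_b + 1.25 * u
    e_oe2_b = e_oe1_b + 2.20 * tg_y
    e = _RES["GLU"]
    add_extra(e, "CD", "C", S.apply(e_cd_b))
    add_extra(e, "OE1", "O", S.apply(e_oe1_b))
    add_extra(e, "OE2", "O", S.apply(e_oe2_b))

    # --- R385 guanidinium: donor to the 3.54 carbonyl in the intermediate --
    r_nh1_b = ile_o + _HBOND_DIST * rd_q
    r_cz_b = r_nh1_b + 1.33 * rd_q
    r = _RES["ARG_PEP"]
    add_extra(r, "CZ", "C", S.apply(r_cz_b))
    add_extra(r, "NH1", "N", S.apply(r_nh1_b))

    # assemble peptide (empty register) with residue-contiguous atom order
    atoms: list[Atom] = []
    serial = 1
    for a in helix.atoms:
        atoms.append(replace(a, serial=serial))
        serial += 1
        if a.name == "CB" and a.res_seq in extra:
            for name, element, xyz in extra[a.res_seq]:
                atoms.append(
                    Atom(serial, name, element, a.res_name, a.res_seq, "P", xyz)
                )
                serial += 1
    peptide_empty = StructureModel(1, atoms)

    receptor = StructureModel(
        1,
        [
            Atom(900 + i, name, element, res_name, res_seq, "R", xyz)
            for i, (res_name, res_seq, name, element, xyz) in enumerate(receptor_atoms)
        ],
    )

    peptide_intermediate = peptide_empty.with_coords(
        S.inverse().apply(peptide_empty.coords)
    )
    numbering = assign_generic_numbers(None, scene_anchor_table())

    expected_empty = {
        (y, "3.50", "cation_pi"),
        (y, "3.50", "nonpolar"),  # ring carbons against the guanidinium CZ
        (q, "3.54", "hbond"),
    }
    expected_intermediate = {
        (e, "3.50", "hbond"),
        (e, "3.50", "nonpolar"),  # carboxylate CD against CZ
        (r, "3.54", "hbond"),
        (r, "3.54", "nonpolar"),  # guanidinium CZ against the Ile backbone C
    }
    return _SceneCore(
        peptide_empty=peptide_empty,
        peptide_intermediate=peptide_intermediate,
        receptor=receptor,
        axis=axis,
        screw=screw,
        numbering=numbering,
        expected_empty=expected_empty,
        expected_intermediate=expected_intermediate,
        bridge_pair_empty=(q_ne2, ile_o),
        bridge_pair_intermediate=(r_nh1_b, ile_o),
    )


@dataclass(frozen=True)
class InterfaceSceneSpec:
    register: str = "empty"  # "empty" | "gdp_intermediate"
    n_bridging_waters: int = 3
    n_bulk_waters: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.register not in ("empty", "gdp_intermediate"):
            raise ValueError(f"unknown register {self.register!r}")
        if self.n_bridging_waters < 0 or self.n_bulk_waters < 0:
            raise ValueError("water counts must be non-negative")


@dataclass
class InterfaceScene:
    """A generated receptor–peptide–water scene with its ground truth."""

    scene: StructureModel  # receptor + peptide + waters
    receptor: StructureModel
    peptide: StructureModel
    numbering: GenericNumberMap
    expected_contacts: set[tuple[int, str, str]]  # (pep res, probe, class)
    expected_state: str
    expected_shift: int
    n_bridging_waters: int
    screw: ScrewParameters  # planted intermediate -> empty screw
    axis: HelixAxis


def make_interface_scene(spec: InterfaceSceneSpec = InterfaceSceneSpec()) -> InterfaceScene:
    """Minimal receptor scaffold + peptide in the requested register + waters.

    Bridging waters are placed within 3.5 Å of heavy atoms of both partners
    near the register's hydrogen-bond pair; bulk waters far from everything.
    The expected fingerprint (and state/shift) is returned as ground truth.
    """
    core = _scene_core()
    rng = np.random.default_rng(spec.seed)
    if spec.register == "empty":
        peptide = core.peptide_empty
        expected = core.expected_empty
        state, shift = "empty", 0
        pair = core.bridge_pair_empty
    else:
        peptide = core.peptide_intermediate
        expected = core.expected_intermediate
        state, shift = "gdp_intermediate", 1
        pair = core.bridge_pair_intermediate

    partners = np.vstack([core.receptor.coords, peptide.coords])
    midpoint = (pair[0] + pair[1]) / 2.0
    pep_coords = peptide.coords
    rec_coords = core.receptor.coords

    waters: list[Atom] = []
    serial = 2000
    placed: list[np.ndarray] = []
    for i in range(spec.n_bridging_waters):
        for _ in range(200):
            cand = midpoint + rng.normal(0.0, 0.5, 3)
            da = np.min(np.linalg.norm(rec_coords - cand, axis=1))
            db = np.min(np.linalg.norm(pep_coords - cand, axis=1))
            if da <= 3.4 and db <= 3.4 and all(
                np.linalg.norm(cand - p) > 0.5 for p in placed
            ):
                break
        else:
            raise RuntimeError("could not place a bridging water")
        placed.append(cand)
        waters.append(
            Atom(serial, "O", "O", "HOH", 1001 + i, "W", cand, het=True)
        )
        serial += 1

    center = partners.mean(0)
    max_r = np.max(np.linalg.norm(partners - center, axis=1))
    for i in range(spec.n_bulk_waters):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = max_r + 10.0 + rng.uniform(0.0, 10.0)
        cand = center + direction * dist
        waters.append(
            Atom(serial, "O", "O", "HOH", 1501 + i, "W", cand, het=True)
        )
        serial += 1

    scene = StructureModel(
        1, list(core.receptor.atoms) + list(peptide.atoms) + waters
    )
    return InterfaceScene(
        scene=scene,
        receptor=core.receptor,
        peptide=peptide,
        numbering=core.numbering,
        expected_contacts=expected,
        expected_state=state,
        expected_shift=shift,
        n_bridging_waters=spec.n_bridging_waters,
        screw=core.screw,
        axis=core.axis,
    )


# ---------------------------------------------------------------------------
# Switch trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchTrajectorySpec:
    """A planted helix-switch: logistic ramp from the GDP-intermediate to the
    nucleotide-free register, with Gaussian coordinate noise on the peptide."""

    theta_target: float = PLANTED_SCREW_ANGLE  # degrees
    slide_target: float = PLANTED_SCREW_SLIDE  # Å
    onset_time: float = 50.0  # ns
    ramp_width: float = 1.0  # ns; small = switch-like
    dt: float = 1.0  # ns per frame
    n_frames: int = 200
    noise_sigma: float = 0.3  # Å per coordinate
    seed: int = 0
    switch: bool = True  # False: null trajectory (stays in start register)
    global_motion: bool = False  # add a random rigid motion per frame

    def __post_init__(self):
        if self.n_frames < 2 or self.dt <= 0:
            raise ValueError("need n_frames >= 2 and dt > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.switch and not (
            0.0 <= self.onset_time <= self.dt * (self.n_frames - 1)
        ):
            raise ValueError("onset_time must lie within the trajectory")


@dataclass
class SwitchTrajectoryResult:
    trajectory: Trajectory  # receptor (chain R) + peptide (chain P)
    truth: pd.DataFrame  # frame, time_ns, theta_deg, slide_A
    reference: StructureModel  # noise-free start frame (intermediate register)
    target: StructureModel  # noise-free end state (empty register)
    receptor: StructureModel
    numbering: GenericNumberMap
    axis: HelixAxis


def make_switch_trajectory(
    spec: SwitchTrajectorySpec = SwitchTrajectorySpec(),
) -> SwitchTrajectoryResult:
    """Generate the planted-switch trajectory plus its ground-truth table."""
    core = _scene_core()
    rng = np.random.default_rng(spec.seed)
    times = spec.dt * np.arange(spec.n_frames)
    if spec.switch:
        from scipy.special import expit

        ramp = expit((times - spec.onset_time) / spec.ramp_width)
    else:
        ramp = np.zeros(spec.n_frames)
    thetas = spec.theta_target * ramp
    slides = spec.slide_target * ramp

    start_pep = core.peptide_intermediate
    start_coords = start_pep.coords
    n_rec = len(core.receptor.atoms)
    base = StructureModel(
        1, list(core.receptor.atoms) + list(start_pep.atoms)
    )
    frames = []
    for i in range(spec.n_frames):
        sp = ScrewParameters(core.axis, float(thetas[i]), float(slides[i]), 0.0)
        pep = recompose(sp).apply(start_coords)
        if spec.noise_sigma > 0:
            pep = pep + rng.normal(0.0, spec.noise_sigma, pep.shape)
        coords = np.vstack([core.receptor.coords, pep])
        if spec.global_motion:
            from scipy.spatial.transform import Rotation

            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-20.0, 20.0, 3)
            coords = coords @ R.T + t
        frame = base.with_coords(coords)
        frame.model_id = i + 1
        frames.append(frame)

    truth = pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "time_ns": times,
            "theta_deg": thetas,
            "slide_A": slides,
        }
    )
    target = StructureModel(
        1, list(core.receptor.atoms) + list(core.peptide_empty.atoms)
    )
    return SwitchTrajectoryResult(
        trajectory=Trajectory(frames, times),
        truth=truth,
        reference=base,
        target=target,
        receptor=core.receptor,
        numbering=core.numbering,
        axis=core.axis,
    )


# ---------------------------------------------------------------------------
# Pose sets with planted clusters
# ---------------------------------------------------------------------------

def make_pose_set(
    k_centers: int = 3,
    sizes: tuple[int, ...] = (11, 6, 3),
    jitter_sigma: float = 0.05,
    center_spacing: float = 5.0,
    seed: int = 0,
    helix: HelixSpec = HelixSpec(),
) -> tuple[PoseSet, np.ndarray]:
    """Pose ensemble with planted cluster structure.

    Centers are distinct screw placements of the helix (40° steps about the
    axis combined with ``center_spacing`` Å of axial slide, so adjacent
    centers are at least ``center_spacing`` apart in RMSD); members add
    i.i.d. Gaussian coordinate jitter.  Returns the set and planted labels.
    """
    if len(sizes) != k_centers:
        raise ValueError("sizes must have k_centers entries")
    if center_spacing <= 0:
        raise ValueError("center_spacing must be positive")
    rng = np.random.default_rng(seed)
    model = build_ideal_helix(helix)
    axis = fit_helix_axis(select(model, "name CA").coords)
    coords = model.coords
    poses: list[StructureModel] = []
    labels: list[int] = []
    for c in range(k_centers):
        sp = ScrewParameters(axis, 40.0 * c, center_spacing * c, 0.0)
        center = recompose(sp).apply(coords)
        for _ in range(sizes[c]):
            jitter = (
                rng.normal(0.0, jitter_sigma, coords.shape)
                if jitter_sigma > 0
                else 0.0
            )
            m = model.with_coords(center + jitter)
            m.model_id = len(poses) + 1
            poses.append(m)
            labels.append(c)
    return PoseSet(poses), np.array(labels)


def make_register_pose_set(
    n_empty: int = 11,
    n_intermediate: int = 6,
    jitter_sigma: float = 0.05,
    seed: int = 0,
) -> tuple[PoseSet, np.ndarray, InterfaceScene]:
    """Two-register pose ensemble for the end-to-end pose pipeline.

    Poses are jittered copies of the peptide in the nucleotide-free ("empty",
    label 0) and GDP-intermediate (label 1) placements, which differ by the
    planted 60° / 1.5 Å screw.  The accompanying scene provides the receptor
    and numbering; cluster occupancies default to the 11-vs-6 split of the
    two relevant docking clusters.
    """
    scene = make_interface_scene(InterfaceSceneSpec(register="empty", seed=seed))
    core_b = make_interface_scene(
        InterfaceSceneSpec(register="gdp_intermediate", seed=seed)
    )
    rng = np.random.default_rng(seed)
    poses: list[StructureModel] = []
    labels: list[int] = []
    for label, pep, n in (
        (0, scene.peptide, n_empty),
        (1, core_b.peptide, n_intermediate),
    ):
        base = pep.coords
        for _ in range(n):
            jitter = (
                rng.normal(0.0, jitter_sigma, base.shape) if jitter_sigma > 0 else 0.0
            )
            m = pep.with_coords(base + jitter)
            m.model_id = len(poses) + 1
            poses.append(m)
            labels.append(label)
    return PoseSet(poses), np.array(labels), scene
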