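"""Receptor–peptide interface characterization.

Quantifies the interactions that drive the α5 helix-switch: hydrogen bonds,
the conserved cation-π contact between the GαCT C-terminal cap tyrosine and
R\\ :sup:`3.50`, buried (and apolar buried) interface area, and bridging
interface waters whose expulsion accompanies the switch.

Hydrogen bonds follow the common crystallographic heavy-atom geometry
(donor–acceptor ≤ 3.5 Å; D–H…A ≥ 120° when explicit hydrogens exist, else an
antecedent–D…A ≥ 90° proxy).  Surface areas use Shrake–Rupley quadrature with
a deterministic Fibonacci sphere point set (probe 1.4 Å, 960 points by
default); buried interface area is the half loss of solvent-accessible area
on complex formation, (SASA(a) + SASA(b) − SASA(ab)) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .model_io import Atom, StructureModel, WATER_RESNAMES, select

__all__ = [
    "HBond",
    "CationPi",
    "InterfaceReport",
    "HBondCriteria",
    "CationPiCriteria",
    "VDW_RADII",
    "sasa",
    "buried_interface_area",
    "detect_hbonds",
    "detect_cation_pi",
    "count_interface_waters",
    "interface_report",
]

# Bondi-style van der Waals radii (Å) per element
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class HBond:
    donor: Atom
    acceptor: Atom
    distance: float  # heavy-atom donor..acceptor, Å
    angle: Optional[float] = None  # D-H...A degrees, when an explicit H was used

    def __str__(self) -> str:
        d, a = self.donor, self.acceptor
        return (
            f"{d.chain_id}/{d.res_name}{d.res_seq}/{d.name} -> "
            f"{a.chain_id}/{a.res_name}{a.res_seq}/{a.name} ({self.distance:.2f} A)"
        )


@dataclass(frozen=True)
class CationPi:
    cation_residue: tuple[str, int, str]  # chain, res_seq, res_name
    ring_residue: tuple[str, int, str]
    distance: float  # ring centroid to cation, Å
    angle: float  # ring normal vs centroid->cation, degrees


@dataclass
class InterfaceReport:
    """Summary of one receptor–peptide interface."""

    buried_area: float
    apolar_buried_area: float
    hbonds: list[HBond]
    cation_pi: list[CationPi]
    n_interface_waters: int
    water_ids: list[tuple[str, int]] = dc_field(default_factory=list)

    def __post_init__(self):
        if not (-1e-6 <= self.apolar_buried_area <= self.buried_area + 1e-6):
            raise ValueError("apolar buried area must lie within [0, buried_area]")

    def to_dict(self) -> dict:
        return {
            "buried_area_A2": self.buried_area,
            "apolar_buried_area_A2": self.apolar_buried_area,
            "n_hbonds": len(self.hbonds),
            "hbonds": [str(h) for h in self.hbonds],
            "n_cation_pi": len(self.cation_pi),
            "cation_pi": [
                {
                    "cation": list(c.cation_residue),
                    "ring": list(c.ring_residue),
                    "distance_A": c.distance,
                    "angle_deg": c.angle,
                }
                for c in self.cation_pi
            ],
            "n_interface_waters": self.n_interface_waters,
            "water_ids": [list(w) for w in self.water_ids],
        }


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def _radii_for(model: StructureModel, radii: dict[str, float]) -> np.ndarray:
    out = np.empty(len(model.atoms))
    for i, a in enumerate(model.atoms):
        try:
            out[i] = radii[a.element.upper()]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {a.element!r} "
                f"(atom {a.key}); extend the radius table"
            ) from None
    return out


def sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley.

    Deterministic for fixed ``n_points`` (Fibonacci sphere point set).
    """
    import biotite.structure as struc

    if n_points < 100:
        raise ValueError("n_points must be at least 100 for a meaningful quadrature")
    radii = radii or VDW_RADII
    r = _radii_for(model, radii)
    n = len(model.atoms)
    arr = struc.AtomArray(n)
    arr.coord = model.coords.astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in model.atoms])
    arr.res_id = np.array([a.res_seq for a in model.atoms])
    arr.res_name = np.array([a.res_name for a in model.atoms])
    arr.atom_name = np.array([a.name for a in model.atoms])
    arr.element = np.array([a.element for a in model.atoms])
    arr.hetero = np.array([a.het for a in model.atoms])
    areas = struc.sasa(
        arr,
        probe_radius=probe,
        point_number=n_points,
        point_distr="Fibonacci",
        vdw_radii=r,
        ignore_ions=False,
    )
    return np.nan_to_num(np.asarray(areas, dtype=float))


def _merged(a: StructureModel, b: StructureModel) -> StructureModel:
    keys_a = {at.key for at in a.atoms}
    overlap = keys_a & {at.key for at in b.atoms}
    if overlap:
        raise ValueError(f"partners share atoms: {sorted(overlap)[:3]} ...")
    return StructureModel(a.model_id, list(a.atoms) + list(b.atoms))


def buried_interface_area(
    a: StructureModel,
    b: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] | None = None,
    apolar_only: bool = False,
) -> float:
    """Buried interface area (Å²): (SASA(a) + SASA(b) − SASA(a∪b)) / 2.

    ``apolar_only`` restricts the per-atom sums to carbon and sulfur atoms —
    the hydrophobic-patch contribution to the interface.
    """
    ab = _merged(a, b)
    sa = sasa(a, probe, n_points, radii)
    sb = sasa(b, probe, n_points, radii)
    sab = sasa(ab, probe, n_points, radii)
    if apolar_only:
        mask_a = np.array([at.element.upper() in ("C", "S") for at in a.atoms])
        mask_b = np.array([at.element.upper() in ("C", "S") for at in b.atoms])
        mask_ab = np.concatenate([mask_a, mask_b])
        sa, sb, sab = sa[mask_a], sb[mask_b], sab[mask_ab]
    return float((sa.sum() + sb.sum() - sab.sum()) / 2.0)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

# donor atom -> antecedent heavy atom, per residue type; "*" applies to all
# standard amino acids (backbone amide)
SIDECHAIN_DONORS = {
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "LYS": {"NZ": "CE"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CE1"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "TRP": {"NE1": "CD1"},
}

SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.5  # donor..acceptor heavy-atom distance, Å
    h_angle_min: float = 120.0  # D-H...A, degrees (explicit hydrogens)
    proxy_angle_min: float = 90.0  # antecedent-D...A, degrees (no hydrogens)


def _donor_antecedent(atom: Atom) -> str | None:
    """Antecedent heavy-atom name when ``atom`` can donate, else None."""
    if atom.res_name in WATER_RESNAMES and atom.element == "O":
        return None  # water O donates but has no useful antecedent
    if atom.name == "N" and atom.res_name not in WATER_RESNAMES:
        return "CA"
    table = SIDECHAIN_DONORS.get(atom.res_name, {})
    return table.get(atom.name)


def _is_donor(atom: Atom) -> bool:
    if atom.res_name in WATER_RESNAMES:
        return atom.element == "O"
    return atom.name == "N" or atom.name in SIDECHAIN_DONORS.get(atom.res_name, {})


def _is_acceptor(atom: Atom) -> bool:
    if atom.res_name in WATER_RESNAMES:
        return atom.element == "O"
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in SIDECHAIN_ACCEPTORS.get(atom.res_name, set())


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _residue_atoms(model: StructureModel) -> dict[tuple[str, int], dict[str, Atom]]:
    out: dict[tuple[str, int], dict[str, Atom]] = {}
    for a in model.atoms:
        out.setdefault((a.chain_id, a.res_seq), {})[a.name] = a
    return out


def _hydrogens_near(model: StructureModel, donor: Atom) -> list[Atom]:
    # explicit H bonded to the donor by proximity (covalent N/O-H < 1.25 Å)
    return [
        a
        for a in model.atoms
        if a.element == "H"
        and a.chain_id == donor.chain_id
        and a.res_seq == donor.res_seq
        and np.linalg.norm(a.xyz - donor.xyz) < 1.25
    ]


def _directed_hbonds(
    donor_model: StructureModel,
    acceptor_model: StructureModel,
    criteria: HBondCriteria,
) -> list[HBond]:
    donors = [a for a in donor_model.atoms if _is_donor(a)]
    acceptors = [a for a in acceptor_model.atoms if _is_acceptor(a)]
    if not donors or not acceptors:
        return []
    res_atoms = _residue_atoms(donor_model)
    tree = cKDTree(np.array([a.xyz for a in acceptors]))
    found = []
    for d in donors:
        for j in tree.query_ball_point(d.xyz, criteria.d_max):
            acc = acceptors[j]
            dist = float(np.linalg.norm(d.xyz - acc.xyz))
            hydrogens = _hydrogens_near(donor_model, d)
            if hydrogens:
                # D-H...A is the angle at the hydrogen
                best = max(_angle(d.xyz, h.xyz, acc.xyz) for h in hydrogens)
                if best < criteria.h_angle_min:
                    continue
                found.append(HBond(d, acc, dist, best))
            else:
                ante_name = _donor_antecedent(d)
                ante = res_atoms.get((d.chain_id, d.res_seq), {}).get(ante_name)
                if ante is not None and (
                    _angle(ante.xyz, d.xyz, acc.xyz) < criteria.proxy_angle_min
                ):
                    continue
                found.append(HBond(d, acc, dist, None))
    return found


def detect_hbonds(
    a: StructureModel,
    b: StructureModel,
    criteria: HBondCriteria | None = None,
) -> list[HBond]:
    """Hydrogen bonds between (not within) two structures, both directions.

    Missing hydrogens are allowed by design: crystallographic "potential
    hydrogen bonds" imply heavy-atom geometry only.
    """
    criteria = criteria or HBondCriteria()
    bonds = _directed_hbonds(a, b, criteria) + _directed_hbonds(b, a, criteria)
    return sorted(bonds, key=lambda h: h.distance)


# ---------------------------------------------------------------------------
# Cation-pi
# ---------------------------------------------------------------------------

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

CATION_ATOMS = {"ARG": "CZ", "LYS": "NZ"}


@dataclass(frozen=True)
class CationPiCriteria:
    d_max: float = 6.0  # ring centroid to cation, Å
    angle_max: float = 45.0  # ring normal vs centroid->cation, degrees


def _rings(model: StructureModel) -> list[tuple[tuple[str, int, str], np.ndarray, np.ndarray]]:
    """(residue id, centroid, unit normal) for each complete aromatic ring."""
    rings = []
    for (chain, res_seq), atoms in _residue_atoms(model).items():
        res_name = next(iter(atoms.values())).res_name
        names = RING_ATOMS.get(res_name)
        if names is None:
            continue
        if not all(n in atoms for n in names):
            warnings.warn(
                f"{res_name}{res_seq} (chain {chain}) misses ring atoms; skipped",
                stacklevel=2,
            )
            continue
        coords = np.array([atoms[n].xyz for n in names])
        centroid = coords.mean(0)
        _, _, vt = np.linalg.svd(coords - centroid)
        rings.append(((chain, res_seq, res_name), centroid, vt[2]))
    return rings


def _cations(model: StructureModel) -> list[tuple[tuple[str, int, str], np.ndarray]]:
    out = []
    for (chain, res_seq), atoms in _residue_atoms(model).items():
        res_name = next(iter(atoms.values())).res_name
        name = CATION_ATOMS.get(res_name)
        if name and name in atoms:
            out.append(((chain, res_seq, res_name), atoms[name].xyz))
    return out


def detect_cation_pi(
    a: StructureModel,
    b: StructureModel,
    criteria: CationPiCriteria | None = None,
) -> list[CationPi]:
    """Cation-π contacts between the two structures (both pairings).

    Cations: Arg guanidinium (CZ) and Lys NZ; rings: Phe/Tyr six-ring, Trp
    indole six-ring, His five-ring.  A contact requires centroid–cation
    distance ≤ 6 Å and ≤ 45° between the ring normal and the centroid→cation
    direction (face-on approach).
    """
    criteria = criteria or CationPiCriteria()
    found = []
    for ring_model, cation_model in ((a, b), (b, a)):
        for ring_id, centroid, normal in _rings(ring_model):
            for cat_id, pos in _cations(cation_model):
                vec = pos - centroid
                dist = float(np.linalg.norm(vec))
                if dist > criteria.d_max or dist < 1e-9:
                    continue
                cosang = abs(normal @ vec) / dist
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if ang <= criteria.angle_max:
                    found.append(CationPi(cat_id, ring_id, dist, ang))
    return sorted(found, key=lambda c: c.distance)


# ---------------------------------------------------------------------------
# Interface waters
# ---------------------------------------------------------------------------

def count_interface_waters(
    scene: StructureModel,
    sel_a: str,
    sel_b: str,
    cutoff: float = 3.5,
) -> tuple[int, list[tuple[str, int]]]:
    """Bridging waters: O within ``cutoff`` of heavy atoms of BOTH partners.

    Returns the count and the (chain, res_seq) ids of the bridging waters.
    A scene without waters yields (0, []) with a notice.
    """
    waters = [
        a for a in scene.atoms if a.res_name in WATER_RESNAMES and a.element == "O"
    ]
    if not waters:
        warnings.warn("scene contains no waters", stacklevel=2)
        return 0, []
    part_a = select(scene, f"{sel_a} and heavy and not water")
    part_b = select(scene, f"{sel_b} and heavy and not water")
    if not part_a.atoms or not part_b.atoms:
        raise ValueError("partner selection resolved to no atoms")
    tree_a = cKDTree(part_a.coords)
    tree_b = cKDTree(part_b.coords)
    ids = []
    for w in waters:
        if tree_a.query(w.xyz)[0] <= cutoff and tree_b.query(w.xyz)[0] <= cutoff:
            ids.append((w.chain_id, w.res_seq))
    return len(ids), ids


def interface_report(
    a: StructureModel,
    b: StructureModel,
    scene: StructureModel | None = None,
    sel_a: str | None = None,
    sel_b: str | None = None,
    water_cutoff: float = 3.5,
    hbond_criteria: HBondCriteria | None = None,
    cation_pi_criteria: CationPiCriteria | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> InterfaceReport:
    """Full interface summary for a receptor–peptide pair.

    Water counting requires the enclosing ``scene`` (with waters) plus the
    selections identifying the two partners within it.
    """
    buried = buried_interface_area(a, b, probe, n_points)
    apolar = buried_interface_area(a, b, probe, n_points, apolar_only=True)
    n_waters, water_ids = 0, []
    if scene is not None and sel_a and sel_b:
        n_waters, water_ids = count_interface_waters(scene, sel_a, sel_b, water_cutoff)
    return InterfaceReport(
        buried_area=max(buried, 0.0),
        apolar_buried_area=float(np.clip(apolar, 0.0, max(buried, 0.0))),
        hbonds=detect_hbonds(a, b, hbond_criteria),
        cation_pi=detect_cation_pi(a, b, cation_pi_criteria),
        n_interface_waters=n_waters,
        water_ids=water_ids,
    )
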