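"""Docking-pose clustering and contact-register state assignment.

Docking a GαCT peptide into the cytoplasmic crevice of an active receptor
yields pose ensembles that fall into discrete binding modes.  Poses are
clustered by pairwise RMSD with single linkage at a fixed cut height
(equivalently: connected components of the graph with edges where
distance ≤ cutoff, the documented behaviour of the classic trajectory
clustering tools), and each pose is assigned to a functional state by the
register of its contacts with conserved receptor positions.

The two states of interest differ by a one-residue register shift along the
peptide: in the nucleotide-free-like ("empty") register the conserved
R\\ :sup:`3.50` arginine engages the residue one before the C-terminus and the
3.54 main-chain carbonyl engages the residue eight before it; in the
GDP-intermediate register both contacts shift one residue toward the
C-terminus.  Offsets are counted from the peptide C-terminus so that Gs and
Gt peptides are handled uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import rmsd
from .interface_analysis import (
    CationPiCriteria,
    HBondCriteria,
    detect_cation_pi,
    detect_hbonds,
)
from .model_io import GenericNumberMap, StructureModel, select

__all__ = [
    "PoseSet",
    "ClusterResult",
    "Contact",
    "ContactFingerprint",
    "StateDefinition",
    "ContactCriteria",
    "DEFAULT_STATES",
    "pairwise_rmsd_matrix",
    "single_linkage_cluster",
    "contact_fingerprint",
    "classify_pose",
]


@dataclass
class PoseSet:
    """Poses of identical atom composition, optionally tagged."""

    poses: list[StructureModel]
    labels: list[str] | None = None

    def __post_init__(self):
        if not self.poses:
            raise ValueError("PoseSet requires at least one pose")
        first = self.poses[0]
        for i, p in enumerate(self.poses[1:], start=1):
            if not first.same_composition(p):
                raise ValueError(f"pose {i} atom composition differs from pose 0")
        if self.labels is not None and len(self.labels) != len(self.poses):
            raise ValueError("labels length must match pose count")

    def __len__(self) -> int:
        return len(self.poses)


@dataclass
class ClusterResult:
    """Cluster assignment with ranks ordered by descending occupancy."""

    assignment: np.ndarray  # per-pose cluster index (0 = largest cluster)
    sizes: np.ndarray  # per-cluster counts, descending
    representatives: np.ndarray  # per-cluster pose index (min summed distance)

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.representatives = np.asarray(self.representatives, dtype=int)
        if self.sizes.sum() != len(self.assignment):
            raise ValueError("cluster sizes must sum to the pose count")
        for ci, rep in enumerate(self.representatives):
            if self.assignment[rep] != ci:
                raise ValueError(f"representative {rep} not in cluster {ci}")

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def pairwise_rmsd_matrix(
    poses: PoseSet,
    selection: str = "backbone",
    superpose: bool = False,
) -> np.ndarray:
    """Symmetric pose-by-pose RMSD matrix (Å) on the selected atoms.

    By default no re-superposition is applied: docking poses share the
    receptor frame, so position within the crevice is part of the distance.
    """
    if len(poses) < 2:
        raise ValueError("need at least two poses")
    subsets = [select(p, selection) for p in poses.poses]
    if not subsets[0].atoms:
        raise ValueError(f"selection {selection!r} matched no atoms")
    coords = np.array([s.coords for s in subsets])
    n = len(poses)
    if not superpose:
        diff = coords[:, None, :, :] - coords[None, :, :, :]
        mat = np.sqrt((diff**2).sum(-1).mean(-1))
    else:
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = rmsd(coords[i], coords[j], superpose=True)
    np.fill_diagonal(mat, 0.0)
    return mat


def single_linkage_cluster(dist: np.ndarray, cutoff: float) -> ClusterResult:
    """Single-linkage clusters at a fixed cut height.

    Clusters are the connected components of the graph with an edge wherever
    ``dist ≤ cutoff``.  Ranks are by descending size, ties broken by the
    lowest member index; the representative of a cluster is the member with
    the smallest summed distance to its cluster mates (ties: lowest index).
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(D < 0):
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-8):
        raise ValueError("distance matrix diagonal must be zero")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = D.shape[0]
    adj = csr_matrix(D <= cutoff)
    _, comp = connected_components(adj, directed=False)

    order = sorted(
        set(comp),
        key=lambda c: (-int((comp == c).sum()), int(np.argmax(comp == c))),
    )
    relabel = {old: new for new, old in enumerate(order)}
    assignment = np.array([relabel[c] for c in comp])
    sizes = np.array([(assignment == ci).sum() for ci in range(len(order))])
    reps = []
    for ci in range(len(order)):
        members = np.flatnonzero(assignment == ci)
        sums = D[np.ix_(members, members)].sum(1)
        reps.append(int(members[int(np.argmin(sums))]))
    return ClusterResult(assignment, sizes, np.array(reps))


# ---------------------------------------------------------------------------
# Contact fingerprints and state registers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contact:
    """One peptide-residue / receptor-position interaction."""

    peptide_res_seq: int
    receptor_label: str  # Ballesteros-Weinstein label, or raw res_seq string
    interaction: str  # hbond | cation_pi | nonpolar
    distance: float
    bw_mapped: bool = True


@dataclass
class ContactFingerprint:
    """Interaction register of one peptide pose with the receptor."""

    contacts: frozenset[Contact]
    peptide_c_term: int  # res_seq of the peptide C-terminal residue

    def offsets_by_probe(self) -> dict[str, set[int]]:
        """Observed peptide offsets (relative to the C-terminus) per probe."""
        out: dict[str, set[int]] = {}
        for c in self.contacts:
            out.setdefault(c.receptor_label, set()).add(
                c.peptide_res_seq - self.peptide_c_term
            )
        return out


@dataclass(frozen=True)
class ContactCriteria:
    hbond: HBondCriteria = HBondCriteria()
    cation_pi: CationPiCriteria = CationPiCriteria()
    nonpolar_d_max: float = 4.5  # C/S to C/S heavy-atom distance, Å


@dataclass(frozen=True)
class StateDefinition:
    """A functional state as its expected contact register.

    ``register`` maps a receptor probe position (BW label) to the expected
    peptide residue offset from the C-terminus (0 = C-terminal residue).
    """

    name: str
    register: dict[str, int] = field(hash=False)

    def __post_init__(self):
        if len(set(self.register)) != len(self.register):
            raise ValueError("probe positions must be distinct")


#: The two registers of the α5 helix-switch: the nucleotide-free-like pose
#: (C-cap tyrosine on 3.50, Gln at −8 on the 3.54 carbonyl) and the
#: GDP-intermediate pose with both contacts shifted one residue C-terminally.
DEFAULT_STATES = [
    StateDefinition("empty", {"3.50": -1, "3.54": -8}),
    StateDefinition("gdp_intermediate", {"3.50": 0, "3.54": -7}),
]


def states_from_yaml(path) -> list[StateDefinition]:
    """Load state definitions from YAML: a list of {name, register} entries,
    register mapping probe labels to offsets from the peptide C-terminus."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [
        StateDefinition(entry["name"], {str(k): int(v) for k, v in entry["register"].items()})
        for entry in data
    ]


def contact_fingerprint(
    receptor: StructureModel,
    peptide: StructureModel,
    numbering: GenericNumberMap | None = None,
    criteria: ContactCriteria | None = None,
) -> ContactFingerprint:
    """Detect all peptide–receptor interactions and report them as a register.

    Receptor residues are reported by Ballesteros–Weinstein label where the
    numbering map covers them; unmapped contacting residues are reported by
    raw residue number with a warning flag on the record.
    """
    criteria = criteria or ContactCriteria()
    contacts: set[Contact] = set()

    def receptor_label(chain: str, res_seq: int) -> tuple[str, bool]:
        if numbering is not None:
            label = numbering.get(chain, res_seq)
            if label is not None:
                return label, True
        return str(res_seq), False

    receptor_keys = {a.key for a in receptor.atoms}

    for hb in detect_hbonds(receptor, peptide, criteria.hbond):
        if hb.donor.key in receptor_keys:
            rec, pep = hb.donor, hb.acceptor
        else:
            rec, pep = hb.acceptor, hb.donor
        label, mapped = receptor_label(rec.chain_id, rec.res_seq)
        contacts.add(Contact(pep.res_seq, label, "hbond", hb.distance, mapped))

    for cp in detect_cation_pi(receptor, peptide, criteria.cation_pi):
        rec_res = (
            cp.cation_residue
            if (cp.cation_residue[0], cp.cation_residue[1]) in
            {(a.chain_id, a.res_seq) for a in receptor.atoms}
            else cp.ring_residue
        )
        pep_res = cp.ring_residue if rec_res is cp.cation_residue else cp.cation_residue
        label, mapped = receptor_label(rec_res[0], rec_res[1])
        contacts.add(Contact(pep_res[1], label, "cation_pi", cp.distance, mapped))

    # apolar (hydrophobic-patch) contacts: C/S atoms across the interface
    from scipy.spatial import cKDTree

    rec_apolar = [a for a in receptor.atoms if a.element.upper() in ("C", "S")]
    pep_apolar = [a for a in peptide.atoms if a.element.upper() in ("C", "S")]
    if rec_apolar and pep_apolar:
        tree = cKDTree(np.array([a.xyz for a in rec_apolar]))
        for pa in pep_apolar:
            hits = tree.query_ball_point(pa.xyz, criteria.nonpolar_d_max)
            if hits:
                dists = [float(np.linalg.norm(pa.xyz - rec_apolar[j].xyz)) for j in hits]
                j = hits[int(np.argmin(dists))]
                ra = rec_apolar[j]
                label, mapped = receptor_label(ra.chain_id, ra.res_seq)
                contacts.add(
                    Contact(pa.res_seq, label, "nonpolar", min(dists), mapped)
                )

    unmapped = {c.receptor_label for c in contacts if not c.bw_mapped}
    if unmapped:
        warnings.warn(
            f"contacting receptor residues outside the numbered segments: "
            f"{sorted(unmapped)}",
            stacklevel=2,
        )
    pep_res = [a.res_seq for a in peptide.atoms]
    return ContactFingerprint(frozenset(contacts), max(pep_res))


def classify_pose(
    fp: ContactFingerprint,
    states: list[StateDefinition] | None = None,
) -> tuple[str, int | None]:
    """Assign a fingerprint to a state and report the register shift.

    Returns ``(state name, shift)`` where the shift is the uniform residue
    offset of the observed register relative to the "empty" register (0 for
    empty-like, +1 toward the C-terminus for the GDP intermediate).  Returns
    ``("other", None)`` for an empty fingerprint, for contradictory offsets
    at a single probe, or when no state's register matches.
    """
    if states is None:
        states = DEFAULT_STATES
    if not states:
        raise ValueError("states must be non-empty")
    observed = fp.offsets_by_probe()
    probe_set = {p for s in states for p in s.register}
    observed = {p: offs for p, offs in observed.items() if p in probe_set}
    if not observed:
        return "other", None
    if any(len(offs) > 1 for offs in observed.values()):
        warnings.warn(
            f"contradictory register at probes "
            f"{ {p: sorted(o) for p, o in observed.items() if len(o) > 1} }",
            stacklevel=2,
        )
        return "other", None
    flat = {p: next(iter(offs)) for p, offs in observed.items()}

    empty = next((s for s in states if s.name == "empty"), states[0])
    for state in states:
        if set(flat) == set(state.register) and all(
            flat[p] == state.register[p] for p in state.register
        ):
            shifts = {
                flat[p] - empty.register[p] for p in flat if p in empty.register
            }
            shift = shifts.pop() if len(shifts) == 1 else None
            return state.name, shift
    return "other", None
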