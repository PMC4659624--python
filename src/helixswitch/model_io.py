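"""Structure and trajectory I/O, atom selection, and generic residue numbering.

The universal in-memory unit is :class:`StructureModel`, an ordered list of
:class:`Atom` records read from (multi-model) PDB files.  Multi-model PDB
doubles as the trajectory format; binary MD formats are deliberately not
parsed.  Ballesteros–Weinstein generic numbering ("t.pp", e.g. the conserved
TM3 arginine R\\ :sup:`3.50`) is propagated arithmetically from user-supplied
anchor residues, which is how the labels are used in GPCR structural work:
within one TM segment, sequence-number differences equal position differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "StructureModel",
    "Trajectory",
    "GenericNumberMap",
    "PDBParseError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "select",
    "assign_generic_numbers",
    "load_anchors",
    "WATER_RESNAMES",
    "AMINO_ACIDS",
    "BACKBONE_NAMES",
]

WATER_RESNAMES = {"HOH", "WAT", "SOL", "H2O", "TIP3"}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_NAMES = {"N", "CA", "C", "O"}


class PDBParseError(ValueError):
    """Raised for malformed fixed-width PDB records (names the line number)."""


class SelectionError(ValueError):
    """Raised for syntax errors in a selection expression."""


@dataclass(frozen=True)
class Atom:
    """One PDB atom record.  Coordinates in Å, B-factor in Å²."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    icode: str = ""
    het: bool = False

    def __post_init__(self):
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))
        if self.xyz.shape != (3,):
            raise ValueError(f"xyz must be a 3-vector, got shape {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.key}")
        if not self.element:
            raise ValueError(f"empty element for atom serial {self.serial}")

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, res_seq, name) — unique within one model."""
        return (self.chain_id, self.res_seq, self.name)


@dataclass
class StructureModel:
    """One model: an ordered list of atoms plus free-form metadata."""

    model_id: int
    atoms: list[Atom]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom {a.key} in model {self.model_id}")
            seen.add(a.key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of the model with replaced coordinates (same atom identity)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(self.atoms)} atoms"
            )
        atoms = [replace(a, xyz=c.copy()) for a, c in zip(self.atoms, coords)]
        return StructureModel(self.model_id, atoms, dict(self.meta))

    def atom_index(self, chain_id: str, res_seq: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.key == (chain_id, res_seq, name):
                return i
        raise KeyError(f"no atom ({chain_id}, {res_seq}, {name})")

    def same_composition(self, other: "StructureModel") -> bool:
        return len(self) == len(other) and all(
            a.key == b.key for a, b in zip(self.atoms, other.atoms)
        )


@dataclass
class Trajectory:
    """Ordered frames of identical atom composition with times in ns."""

    frames: list[StructureModel]
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.times)} time points"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        first = self.frames[0]
        for i, fr in enumerate(self.frames[1:], start=1):
            if not first.same_composition(fr):
                raise ValueError(
                    f"frame {i} atom composition differs from frame 0"
                )

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from None


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from None


def _guess_element(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_structure(
    path: str | Path, model_index: int | None = None
) -> StructureModel | list[StructureModel]:
    """Read a (multi-model) PDB file.

    Returns a single :class:`StructureModel` for single-model files (or when
    ``model_index`` is given, 1-based), otherwise the list of models.  Waters
    are retained; insertion codes are preserved on the atoms.  Alternate
    locations are reduced to the highest-occupancy conformer (ties broken by
    altloc letter order) and the choice is logged.
    """
    path = Path(path)
    models: list[StructureModel] = []
    # raw atom rows per model; altloc resolution happens per residue afterwards
    current: list[tuple[Atom, str]] = []
    current_id = 1
    explicit_models = False

    def flush():
        nonlocal current
        if current:
            models.append(_finalize_model(current, current_id))
            current = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                flush()
                explicit_models = True
                current_id_str = line[6:].strip() or str(len(models) + 1)
                current_id = _parse_int(current_id_str, "model number", lineno)
            elif rec == "ENDMDL":
                if not current:
                    raise PDBParseError(f"line {lineno}: empty MODEL block")
                flush()
            elif rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"line {lineno}: truncated {rec.strip()} record"
                    )
                name = line[12:16].strip()
                altloc = line[16].strip()
                elem = line[76:78].strip() if len(line) >= 78 else ""
                atom = Atom(
                    serial=_parse_int(line[6:11], "serial", lineno),
                    name=name,
                    element=elem or _guess_element(name),
                    res_name=line[17:20].strip(),
                    res_seq=_parse_int(line[22:26], "residue number", lineno),
                    chain_id=line[21].strip() or " ",
                    xyz=np.array(
                        [
                            _parse_float(line[30:38], "x coordinate", lineno),
                            _parse_float(line[38:46], "y coordinate", lineno),
                            _parse_float(line[46:54], "z coordinate", lineno),
                        ]
                    ),
                    occupancy=_parse_float(line[54:60], "occupancy", lineno)
                    if line[54:60].strip()
                    else 1.0,
                    b_factor=_parse_float(line[60:66], "B-factor", lineno)
                    if line[60:66].strip()
                    else 0.0,
                    icode=line[26].strip(),
                    het=rec == "HETATM",
                )
                current.append((atom, altloc))
    flush()

    if not models:
        raise PDBParseError(f"{path}: no atoms found")
    if model_index is not None:
        for m in models:
            if m.model_id == model_index:
                return m
        raise KeyError(f"model {model_index} not in {path}")
    if len(models) == 1 and not explicit_models:
        return models[0]
    return models


def _finalize_model(rows: list[tuple[Atom, str]], model_id: int) -> StructureModel:
    """Resolve altlocs: keep the highest-occupancy conformer per atom site."""
    chosen: dict[tuple, tuple[int, Atom, str]] = {}
    order: list[tuple] = []
    for i, (atom, altloc) in enumerate(rows):
        k = atom.key
        if k not in chosen:
            chosen[k] = (i, atom, altloc)
            order.append(k)
        else:
            _, prev, prev_alt = chosen[k]
            if (atom.occupancy, _alt_rank(altloc)) > (
                prev.occupancy,
                _alt_rank(prev_alt),
            ):
                better, alt = atom, altloc
            else:
                better, alt = prev, prev_alt
            if better is atom:
                chosen[k] = (chosen[k][0], atom, altloc)
            logger.info(
                "altloc at %s: kept %r (occ %.2f)",
                k,
                alt or prev_alt,
                better.occupancy,
            )
    atoms = [chosen[k][1] for k in order]
    return StructureModel(model_id, atoms)


def _alt_rank(altloc: str) -> int:
    # empty altloc ranks above lettered ones; then reverse letter order so that
    # max() prefers 'A' over 'B' on occupancy ties
    if not altloc:
        return 1000
    return -ord(altloc)


_COORD_LIMIT = 9999.999


def write_structure(
    models: StructureModel | Sequence[StructureModel], path: str | Path
) -> None:
    """Write one or more models as fixed-width PDB (MODEL/ENDMDL when several).

    Output is bit-stable given identical input.  Coordinates outside the PDB
    fixed-width range raise instead of being silently truncated.
    """
    if isinstance(models, StructureModel):
        model_list = [models]
        multi = False
    else:
        model_list = list(models)
        multi = True
    if not model_list:
        raise ValueError("no models to write")
    path = Path(path)
    lines: list[str] = []
    for m in model_list:
        if not m.atoms:
            raise ValueError("refusing to write a model with no atoms")
        if multi:
            lines.append(f"MODEL     {m.model_id:4d}")
        for a in m.atoms:
            if np.any(np.abs(a.xyz) > _COORD_LIMIT):
                raise ValueError(
                    f"coordinate out of PDB fixed-width range for atom {a.key}: {a.xyz}"
                )
            lines.append(_format_atom_line(a))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _format_atom_line(a: Atom) -> str:
    rec = "HETATM" if a.het else "ATOM  "
    # PDB atom-name column convention: 1-char elements start in column 14
    if len(a.name) < 4 and len(a.element) == 1:
        name = f" {a.name:<3s}"
    else:
        name = f"{a.name:<4s}"
    return (
        f"{rec}{a.serial:5d} {name} {a.res_name:>3s} {a.chain_id:1s}"
        f"{a.res_seq:4d}{a.icode or ' ':1s}   "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
    )


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _clause_predicate(clause: str):
    tokens = clause.split()
    if not tokens:
        raise SelectionError("empty selection clause")
    negate = False
    if tokens[0] == "not":
        negate = True
        tokens = tokens[1:]
        if not tokens:
            raise SelectionError("dangling 'not'")
    head, args = tokens[0], tokens[1:]

    if head == "chain":
        if not args:
            raise SelectionError("'chain' needs at least one chain id")
        ids = set(args)
        pred = lambda a: a.chain_id in ids
    elif head == "resid":
        if not args:
            raise SelectionError("'resid' needs a number or range")
        ranges: list[tuple[int, int]] = []
        for part in " ".join(args).replace(",", " ").split():
            if "-" in part[1:]:  # allow leading minus of negative resid
                lo, _, hi = part.rpartition("-")
                try:
                    ranges.append((int(lo), int(hi)))
                except ValueError:
                    raise SelectionError(f"bad resid range {part!r}") from None
            else:
                try:
                    ranges.append((int(part), int(part)))
                except ValueError:
                    raise SelectionError(f"bad resid {part!r}") from None
        pred = lambda a: any(lo <= a.res_seq <= hi for lo, hi in ranges)
    elif head == "name":
        if not args:
            raise SelectionError("'name' needs at least one atom name")
        names = set(args)
        pred = lambda a: a.name in names
    elif head == "backbone":
        if args:
            raise SelectionError("'backbone' takes no arguments")
        pred = lambda a: a.name in BACKBONE_NAMES and a.res_name in AMINO_ACIDS
    elif head == "heavy":
        if args:
            raise SelectionError("'heavy' takes no arguments")
        pred = lambda a: a.element != "H"
    elif head == "water":
        if args:
            raise SelectionError("'water' takes no arguments")
        pred = lambda a: a.res_name in WATER_RESNAMES
    elif head == "protein":
        if args:
            raise SelectionError("'protein' takes no arguments")
        pred = lambda a: a.res_name in AMINO_ACIDS
    else:
        raise SelectionError(f"unknown selection keyword {head!r}")

    if negate:
        return lambda a: not pred(a)
    return pred


def select(model: StructureModel, expr: str) -> StructureModel:
    """Subset a model by a selection expression; pure, order-preserving.

    Grammar: clauses joined by ``and``; clauses are ``chain A [B ...]``,
    ``resid 382-392[,400]``, ``name CA N``, and the keywords ``backbone``,
    ``heavy``, ``water``, ``protein``, each optionally prefixed by ``not``.
    An empty result is allowed but flagged in ``meta['empty_selection']``
    (and a warning is emitted).
    """
    preds = [_clause_predicate(c) for c in expr.split(" and ")]
    kept = [a for a in model.atoms if all(p(a) for p in preds)]
    meta = dict(model.meta, selection=expr)
    if not kept:
        warnings.warn(f"selection {expr!r} matched no atoms", stacklevel=2)
        meta["empty_selection"] = True
    return StructureModel(model.model_id, kept, meta)


# ---------------------------------------------------------------------------
# Generic (Ballesteros–Weinstein) numbering
# ---------------------------------------------------------------------------

@dataclass
class GenericNumberMap:
    """Anchor-propagated Ballesteros–Weinstein labels.

    Each anchor pins one residue of a TM segment to a label ``t.pp``; every
    residue of that segment is then numbered by offset (``anchor_resid + k``
    maps to ``position pp + k``).  Lookups outside numbered segments raise.
    """

    mapping: dict[tuple[str, int], str]

    def lookup(self, chain_id: str, res_seq: int) -> str:
        try:
            return self.mapping[(chain_id, res_seq)]
        except KeyError:
            raise KeyError(
                f"residue ({chain_id}, {res_seq}) is outside all numbered segments"
            ) from None

    def get(self, chain_id: str, res_seq: int, default=None):
        return self.mapping.get((chain_id, res_seq), default)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


def _parse_bw(label: str) -> tuple[int, int]:
    try:
        tm, pos = label.split(".")
        return int(tm), int(pos)
    except ValueError:
        raise ValueError(f"malformed Ballesteros–Weinstein label {label!r}") from None


def load_anchors(path: str | Path) -> pd.DataFrame:
    """Read an anchor table CSV: chain,res_seq,bw_label,segment_start,segment_end."""
    df = pd.read_csv(path, dtype={"chain": str, "bw_label": str})
    required = {"chain", "res_seq", "bw_label", "segment_start", "segment_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"anchor table {path} missing columns {sorted(missing)}")
    return df


def assign_generic_numbers(
    model: StructureModel | None, anchors: pd.DataFrame | Iterable[dict]
) -> GenericNumberMap:
    """Propagate anchors to a full per-residue generic-number map.

    ``model`` may be None: the map is purely arithmetic over the declared
    segments.  Two anchors within one segment that disagree on offset raise.
    """
    if not isinstance(anchors, pd.DataFrame):
        anchors = pd.DataFrame(list(anchors))
    mapping: dict[tuple[str, int], str] = {}
    origin: dict[tuple[str, int], tuple] = {}
    for row in anchors.itertuples(index=False):
        chain = str(row.chain)
        res_seq = int(row.res_seq)
        tm, pos = _parse_bw(str(row.bw_label))
        start, end = int(row.segment_start), int(row.segment_end)
        if not (start <= res_seq <= end):
            raise ValueError(
                f"anchor residue {res_seq} outside its segment {start}-{end}"
            )
        for r in range(start, end + 1):
            label = f"{tm}.{pos + (r - res_seq)}"
            key = (chain, r)
            if key in mapping and mapping[key] != label:
                raise ValueError(
                    f"anchors disagree at residue {key}: "
                    f"{mapping[key]} (from {origin[key]}) vs {label} "
                    f"(from anchor {res_seq}->{tm}.{pos})"
                )
            mapping[key] = label
            origin[key] = (res_seq, f"{tm}.{pos}")
    return GenericNumberMap(mapping)
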