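"""Atomic models, a small selection language, and atom pairing.

Models are addressed by *author* chain IDs and *author* residue numbers
throughout, because published measurement protocols cite author numbering
(e.g. 16S rRNA C1478, 23S rRNA 2090-2174).  Parsing and fixture writing go
through gemmi; this module only fixes the in-memory representation and the
semantics of selection and pairing.

Selection syntax (bit-exact, documented):

    chain:A res:1045-1099,2090-2174 atom:P,CA

Fields within one term are AND-ed; multiple terms joined by ``;`` are OR-ed;
a term prefixed with ``!`` is an exclusion applied after all inclusions.
Residue ranges are inclusive on both ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
_RNA = {"A", "C", "G", "U", "I", "N"}
_DNA = {"DA", "DC", "DG", "DT", "DI", "DN"}

_HYDROGEN = {"H", "D"}


class StructureError(Exception):
    """Base class for structure I/O and addressing failures."""


class EmptyModelError(StructureError):
    """A parsed file or constructed model contains no atoms."""


class FormatError(StructureError):
    """File format could not be determined or parsed."""


class SelectionError(StructureError):
    """A selection expression is malformed or selects nothing where atoms are required."""


class PairingError(StructureError):
    """No atoms could be paired between two models for a given selection."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with author addressing and Cartesian coordinates in Å."""

    chain_id: str
    residue_number: int
    insertion: str          # '' when absent
    residue_name: str
    atom_name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    alt_loc: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Pairing key: (chain, residue number, insertion code, atom name)."""
        return (self.chain_id, self.residue_number, self.insertion, self.atom_name)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


def residue_polymer_type(residue_name: str) -> str:
    """Classify a residue name as 'protein', 'RNA', 'DNA' or 'other'."""
    name = residue_name.strip().upper()
    if name in _AMINO:
        return "protein"
    if name in _RNA:
        return "RNA"
    if name in _DNA:
        return "DNA"
    return "other"


@dataclass
class StructureModel:
    """An ordered collection of atoms plus a per-chain polymer-type index."""

    identifier: str
    atoms: list[AtomRecord]
    chain_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyModelError(f"model {self.identifier!r} has no atoms")
        if not self.chain_types:
            self.chain_types = _infer_chain_types(self.atoms)
        missing = {a.chain_id for a in self.atoms} - set(self.chain_types)
        if missing:
            raise StructureError(f"chains missing from chain index: {sorted(missing)}")

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of coordinates in model order."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def with_coords(self, coords: np.ndarray, identifier: str | None = None) -> "StructureModel":
        """Copy of the model with every atom's coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, coord=tuple(c)) for a, c in zip(self.atoms, coords)]
        return StructureModel(identifier or self.identifier, atoms, dict(self.chain_types))

    def transformed(self, transform, identifier: str | None = None) -> "StructureModel":
        """Copy with a RigidTransform applied to all coordinates."""
        return self.with_coords(transform.apply(self.coords), identifier)

    def __len__(self) -> int:
        return len(self.atoms)


def _infer_chain_types(atoms: Sequence[AtomRecord]) -> dict[str, str]:
    votes: dict[str, dict[str, int]] = {}
    for a in atoms:
        votes.setdefault(a.chain_id, {})
        t = residue_polymer_type(a.residue_name)
        votes[a.chain_id][t] = votes[a.chain_id].get(t, 0) + 1
    return {c: max(v, key=v.get) for c, v in votes.items()}


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionTerm:
    """One conjunctive term: chain set AND residue ranges AND atom names.

    ``None`` for a field means "no constraint".  ``negate`` marks the term as
    an exclusion.
    """

    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = None
    negate: bool = False

    def matches(self, atom: AtomRecord) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None:
            n = atom.residue_number
            if not any(lo <= n <= hi for lo, hi in self.residue_ranges):
                return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        return True


@dataclass(frozen=True)
class SelectionExpr:
    """Union of inclusion terms, minus the union of exclusion terms."""

    terms: tuple[SelectionTerm, ...]

    @classmethod
    def parse(cls, text: str) -> "SelectionExpr":
        """Parse the documented syntax, e.g. ``chain:A res:1-10 atom:CA; !chain:B``."""
        terms = []
        for raw in text.split(";"):
            raw = raw.strip()
            if not raw:
                continue
            negate = raw.startswith("!")
            if negate:
                raw = raw[1:].strip()
            chains = ranges = names = None
            for tok in raw.split():
                if ":" not in tok:
                    raise SelectionError(f"malformed token {tok!r} in selection {text!r}")
                kind, _, val = tok.partition(":")
                if kind == "chain":
                    chains = frozenset(v for v in val.split(",") if v)
                elif kind == "res":
                    parsed = []
                    for r in val.split(","):
                        if "-" in r[1:]:  # allow negative residue numbers
                            cut = r.index("-", 1)
                            lo, hi = int(r[:cut]), int(r[cut + 1:])
                        else:
                            lo = hi = int(r)
                        if lo > hi:
                            raise SelectionError(f"inverted range {r!r} in {text!r}")
                        parsed.append((lo, hi))
                    ranges = tuple(parsed)
                elif kind == "atom":
                    names = frozenset(v for v in val.split(",") if v)
                else:
                    raise SelectionError(f"unknown field {kind!r} in selection {text!r}")
            terms.append(SelectionTerm(chains, ranges, names, negate))
        if not terms:
            raise SelectionError(f"empty selection {text!r}")
        return cls(tuple(terms))

    @classmethod
    def all(cls) -> "SelectionExpr":
        return cls((SelectionTerm(),))

    def __or__(self, other: "SelectionExpr") -> "SelectionExpr":
        return SelectionExpr(self.terms + other.terms)

    def excluding(self, other: "SelectionExpr") -> "SelectionExpr":
        """Attach *other*'s inclusion terms as exclusions."""
        extra = tuple(replace(t, negate=True) for t in other.terms if not t.negate)
        return SelectionExpr(self.terms + extra)

    @property
    def inclusions(self) -> tuple[SelectionTerm, ...]:
        return tuple(t for t in self.terms if not t.negate)

    @property
    def exclusions(self) -> tuple[SelectionTerm, ...]:
        return tuple(t for t in self.terms if t.negate)

    def matches(self, atom: AtomRecord) -> bool:
        inc = self.inclusions
        if inc and not any(t.matches(atom) for t in inc):
            return False
        if not inc:
            # pure-exclusion expression selects everything not excluded
            pass
        return not any(t.matches(atom) for t in self.exclusions)

    def text(self) -> str:
        parts = []
        for t in self.terms:
            toks = []
            if t.chains is not None:
                toks.append("chain:" + ",".join(sorted(t.chains)))
            if t.residue_ranges is not None:
                toks.append("res:" + ",".join(
                    f"{lo}-{hi}" if lo != hi else str(lo) for lo, hi in t.residue_ranges))
            if t.atom_names is not None:
                toks.append("atom:" + ",".join(sorted(t.atom_names)))
            prefix = "!" if t.negate else ""
            parts.append(prefix + " ".join(toks))
        return "; ".join(parts)


def select(model: StructureModel, expr: SelectionExpr) -> list[AtomRecord]:
    """Atoms of *model* matching *expr*, in model order.

    A term that names a chain absent from the model contributes nothing; a
    warning is logged rather than raising, because anchor configurations are
    shared across sister structures that may lack individual chains.
    """
    present = set(model.chain_types)
    for t in expr.terms:
        if t.chains is not None and not (t.chains & present):
            logger.warning(
                "selection term references chain(s) %s absent from model %r",
                sorted(t.chains), model.identifier)
    return [a for a in model.atoms if expr.matches(a)]


def pair_atoms(
    a: StructureModel,
    b: StructureModel,
    expr: SelectionExpr,
    atom_names: Iterable[str] | None = None,
    include_hydrogens: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str, str]], int]:
    """Match equivalent atoms of two models on (chain, residue, insertion, atom name).

    Returns ``(coords_a, coords_b, keys, n_dropped)`` with rows sorted by key
    so the pairing is deterministic and independent of file atom order.
    Unmatched atoms on either side are dropped and counted.  Hydrogens are
    excluded by default.
    """
    names = frozenset(atom_names) if atom_names is not None else None

    def index(m: StructureModel) -> dict:
        out = {}
        for atom in select(m, expr):
            if not include_hydrogens and atom.is_hydrogen:
                continue
            if names is not None and atom.atom_name not in names:
                continue
            out.setdefault(atom.key, atom)  # first conformer wins (alt-locs pre-resolved)
        return out

    ia, ib = index(a), index(b)
    keys = sorted(set(ia) & set(ib))
    dropped = len(set(ia) ^ set(ib))
    if not keys:
        raise PairingError(
            f"no atom pairs between {a.identifier!r} and {b.identifier!r} "
            f"for selection {expr.text()!r}")
    ca = np.array([ia[k].coord for k in keys], dtype=float)
    cb = np.array([ib[k].coord for k in keys], dtype=float)
    return ca, cb, keys, dropped


# ---------------------------------------------------------------------------
# I/O via gemmi
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read an mmCIF or PDB file into a StructureModel.

    All ATOM/HETATM records are retained with author chain IDs and author
    residue numbers.  For atoms with alternate locations only the
    highest-occupancy conformer is kept (ties broken by file order).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in {".cif", ".mmcif"}:
            fmt = "mmcif"
        elif suffix in {".pdb", ".ent"}:
            fmt = "pdb"
        else:
            raise FormatError(f"cannot infer format from extension {suffix!r}")
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise FormatError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc

    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise EmptyModelError(f"{path} contains no model")
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion=(res.seqid.icode or " ").strip(),
                    residue_name=res.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=float(atom.occ),
                    alt_loc=(atom.altloc or "").strip(),
                ))
    if not atoms:
        raise EmptyModelError(f"{path} contains no atoms")
    return StructureModel(path.stem, _resolve_altlocs(atoms))


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per (chain, residue, insertion, atom name)."""
    best: dict[tuple, tuple[int, AtomRecord]] = {}
    for i, a in enumerate(atoms):
        k = a.key
        if k not in best:
            best[k] = (i, a)
        else:
            _, cur = best[k]
            if a.occupancy > cur.occupancy:
                best[k] = (best[k][0], a)  # keep first position, better conformer
    kept = sorted(best.values(), key=lambda t: t[0])
    return [a if a.alt_loc == "" else replace(a, alt_loc="") for _, a in kept]


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a standard 80-column PDB file (fixtures, cross-tool use)."""
    st = gemmi.Structure()
    st.name = model.identifier[:78]
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple, gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        rk = a.residue_key
        if rk not in residues:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion or " ")
            res.het_flag = "A"
            chains[a.chain_id].add_residue(res)
            residues[rk] = chains[a.chain_id][-1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.coord)
        atom.occ = a.occupancy
        residues[rk].add_atom(atom)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
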