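"""Protein structure model: I/O, backbone extraction and gap definition.

Coordinates are in Å throughout. Residues are identified publicly by author
numbering plus insertion code; internal indices are 0-based and contiguous.
PDB (and mmCIF) parsing is delegated to gemmi; only backbone-level information
is retained in the in-memory model, side-chain atoms are carried through I/O
untouched inside the per-residue atom dictionaries.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C")
BACKBONE_ATOMS_O = ("N", "CA", "C", "O")

#: minimum / maximum fragment length served by the database
MIN_FRAGMENT_LEN = 3
MAX_FRAGMENT_LEN = 35

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
_ONE_TO_THREE = {v: k for k, v in reversed(list(_THREE_TO_ONE.items()))}


class StructureError(ValueError):
    """Raised for malformed structures or invalid gap definitions."""


ResidueId = tuple[int, str]


def _normalize_resid(resid) -> ResidueId:
    """Accept 10, (10, ''), or (10, 'A') and return (number, icode)."""
    if isinstance(resid, tuple):
        num, icode = resid
        return int(num), str(icode or "")
    return int(resid), ""


@dataclass
class Residue:
    number: int
    icode: str = ""
    amino_acid: str = "X"
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def resid(self) -> ResidueId:
        return (self.number, self.icode)

    def has_backbone(self, include_o: bool = False) -> bool:
        names = BACKBONE_ATOMS_O if include_o else BACKBONE_ATOMS
        return all(n in self.atoms for n in names)

    def backbone_names(self) -> tuple[str, ...]:
        return BACKBONE_ATOMS_O if "O" in self.atoms else BACKBONE_ATOMS


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def index_of(self, resid) -> int:
        resid = _normalize_resid(resid)
        for i, r in enumerate(self.residues):
            if r.resid == resid:
                return i
        raise StructureError(
            f"residue {resid[0]}{resid[1]} not found in chain {self.chain_id}"
        )

    def get(self, resid) -> Residue:
        return self.residues[self.index_of(resid)]


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    name: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise StructureError(f"chain {chain_id!r} not found")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


class CoordinateSet:
    """An ordered list of labeled 3-D points (atom name, residue index, xyz/Å)."""

    __slots__ = ("atom_names", "residue_indices", "coords")

    def __init__(self, atom_names: Sequence[str], residue_indices: Sequence[int],
                 coords: np.ndarray):
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(coords) == 0:
            raise StructureError("CoordinateSet must contain at least one point")
        if not np.all(np.isfinite(coords)):
            raise StructureError("CoordinateSet coordinates must be finite")
        if len(atom_names) != len(coords) or len(residue_indices) != len(coords):
            raise StructureError("labels and coordinates must have equal length")
        self.atom_names = list(atom_names)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.coords = coords

    def __len__(self) -> int:
        return len(self.coords)

    def with_coords(self, coords: np.ndarray) -> "CoordinateSet":
        return CoordinateSet(self.atom_names, self.residue_indices, coords)

    def select_atoms(self, names: Iterable[str]) -> "CoordinateSet":
        names = set(names)
        mask = np.array([n in names for n in self.atom_names], dtype=bool)
        return CoordinateSet(
            [n for n, m in zip(self.atom_names, mask) if m],
            self.residue_indices[mask], self.coords[mask])

    def select_residues(self, indices: Iterable[int]) -> "CoordinateSet":
        indices = set(int(i) for i in indices)
        mask = np.array([i in indices for i in self.residue_indices], dtype=bool)
        return CoordinateSet(
            [n for n, m in zip(self.atom_names, mask) if m],
            self.residue_indices[mask], self.coords[mask])

    def group_by_residue(self) -> dict[int, dict[str, np.ndarray]]:
        out: dict[int, dict[str, np.ndarray]] = {}
        for name, idx, xyz in zip(self.atom_names, self.residue_indices, self.coords):
            out.setdefault(int(idx), {})[name] = xyz
        return out

    @staticmethod
    def concatenate(sets: Sequence["CoordinateSet"]) -> "CoordinateSet":
        return CoordinateSet(
            [n for s in sets for n in s.atom_names],
            np.concatenate([s.residue_indices for s in sets]),
            np.vstack([s.coords for s in sets]))


# ---------------------------------------------------------------------------
# I/O

def read_structure(path, model_index: int = 0) -> Structure:
    """Read a PDB (or mmCIF) file into a Structure.

    The requested model (first by default) is used; alternate locations are
    resolved to the highest-occupancy conformer; HETATM groups, waters and
    hydrogens are dropped.
    """
    path = str(path)
    try:
        st = gemmi.read_structure(path)
    except Exception as exc:  # noqa: BLE001 - gemmi raises bare RuntimeError
        raise StructureError(f"cannot parse structure file {path!r}: {exc}") from exc
    st.setup_entities()
    if model_index >= len(st):
        raise StructureError(
            f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]
    out = Structure(name=Path(path).stem)
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            if gres.het_flag == "H" and gres.name not in _THREE_TO_ONE:
                continue
            res = Residue(
                number=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                amino_acid=_THREE_TO_ONE.get(gres.name, "X"),
            )
            best: dict[str, tuple[float, np.ndarray]] = {}
            for atom in gres:
                if atom.is_hydrogen():
                    continue
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev[0]:
                    best[atom.name] = (atom.occ, pos)
            res.atoms = {name: xyz for name, (_, xyz) in best.items()}
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.number, r.icode))
            out.chains.append(chain)
    if not out.chains:
        raise StructureError(f"no polymer residues found in {path!r}")
    return out


def write_structure(structure: Structure, path) -> None:
    """Write a Structure as PDB ATOM records with sequential serials."""
    st = gemmi.Structure()
    st.name = structure.name or "model"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = _ONE_TO_THREE.get(res.amino_acid, "UNK")
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[:1])
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Backbone extraction and gaps

def extract_backbone(structure: Structure, chain_id: str, first, last) -> CoordinateSet:
    """Backbone atoms (N, CA, C and O when present) for a contiguous residue range."""
    chain = structure.chain(chain_id)
    i0, i1 = chain.index_of(first), chain.index_of(last)
    if i1 < i0:
        raise StructureError("last residue precedes first residue")
    names: list[str] = []
    indices: list[int] = []
    coords: list[np.ndarray] = []
    for i in range(i0, i1 + 1):
        res = chain.residues[i]
        missing = [n for n in BACKBONE_ATOMS if n not in res.atoms]
        if missing:
            raise StructureError(
                f"residue {res.number}{res.icode} in chain {chain_id} is missing "
                f"backbone atom(s) {', '.join(missing)}")
        for n in res.backbone_names():
            names.append(n)
            indices.append(i)
            coords.append(res.atoms[n])
    return CoordinateSet(names, indices, np.vstack(coords))


@dataclass
class GapSpec:
    """A modeling task: context structure, flanking stem residues, query sequence.

    The queried segment of length L sits strictly between the two stem
    residues; database fragments of length L + 2 are grafted so that their
    terminal residues coincide with the stems.
    """

    structure: Structure
    chain_id: str
    nstem_residue: ResidueId
    cstem_residue: ResidueId
    query_sequence: str

    @property
    def length(self) -> int:
        return len(self.query_sequence)

    # Alias used throughout the docs: L
    L = length

    @property
    def fragment_length(self) -> int:
        return self.length + 2

    def _chain(self) -> Chain:
        return self.structure.chain(self.chain_id)

    def stem_residue(self, side: str) -> Residue:
        resid = self.nstem_residue if side == "n" else self.cstem_residue
        return self._chain().get(resid)

    def stem_atoms(self, side: str, include_o: bool = True) -> dict[str, np.ndarray]:
        res = self.stem_residue(side)
        names = BACKBONE_ATOMS_O if include_o and "O" in res.atoms else BACKBONE_ATOMS
        return {n: res.atoms[n] for n in names}

    def stems_have_o(self) -> bool:
        return all("O" in self.stem_residue(s).atoms for s in ("n", "c"))

    def _span_indices(self) -> tuple[int, int]:
        chain = self._chain()
        return chain.index_of(self.nstem_residue), chain.index_of(self.cstem_residue)

    def context_coords(self, include_stems: bool = True) -> CoordinateSet | None:
        """All chain atoms excluding the modeled span (and optionally the stems).

        Returns None when nothing remains (minimal toy chains).
        """
        chain = self._chain()
        i_n, i_c = self._span_indices()
        excluded = set(range(i_n + 1, i_c))
        if not include_stems:
            excluded |= {i_n, i_c}
        names, indices, coords = [], [], []
        for i, res in enumerate(chain.residues):
            if i in excluded:
                continue
            for n, xyz in res.atoms.items():
                names.append(n)
                indices.append(i)
                coords.append(xyz)
        if not coords:
            return None
        return CoordinateSet(names, indices, np.vstack(coords))

    def native_segment(self, atoms: Sequence[str] = BACKBONE_ATOMS) -> CoordinateSet | None:
        """Backbone of the original residues between the stems, if present."""
        chain = self._chain()
        i_n, i_c = self._span_indices()
        if i_c - i_n - 1 != self.length:
            return None
        names, indices, coords = [], [], []
        for i in range(i_n + 1, i_c):
            res = chain.residues[i]
            if not all(a in res.atoms for a in atoms):
                return None
            for a in atoms:
                names.append(a)
                indices.append(i - i_n - 1)
                coords.append(res.atoms[a])
        return CoordinateSet(names, indices, np.vstack(coords))


def define_gap(structure: Structure, chain_id: str, nstem, cstem,
               sequence: str) -> GapSpec:
    """Define a modeling gap between two stem residues of a chain."""
    L = len(sequence)
    if not (MIN_FRAGMENT_LEN <= L <= MAX_FRAGMENT_LEN):
        raise StructureError(
            f"query length {L} outside supported range "
            f"[{MIN_FRAGMENT_LEN}, {MAX_FRAGMENT_LEN}]")
    chain = structure.chain(chain_id)
    nstem = _normalize_resid(nstem)
    cstem = _normalize_resid(cstem)
    i_n, i_c = chain.index_of(nstem), chain.index_of(cstem)
    if i_c <= i_n:
        raise StructureError("C-stem must follow N-stem in the chain")
    for resid, idx in ((nstem, i_n), (cstem, i_c)):
        res = chain.residues[idx]
        if not res.has_backbone():
            raise StructureError(
                f"stem residue {resid[0]}{resid[1]} lacks complete N/CA/C")
    return GapSpec(structure, chain_id, nstem, cstem, sequence)
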