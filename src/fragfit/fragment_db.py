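"""Fragment extraction and the indexed single-file fragment database.

All overlapping windows of 3–35 residues are harvested from each chain of
each input structure; windows crossing chain breaks (CA–CA > 4.5 Å or a jump
in author numbering) or containing incomplete backbones are skipped silently
and counted in the build report. The store is a single sqlite file with a
B-tree index over (length, stem distance d) answering the strict range query
|d_rec − d| < Δd in one pass. Coordinates are packed float64 blobs — the
database is a run-time artifact, not an exchange format.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from fragfit.geometry import GeometricFingerprint, compute_fingerprint
from fragfit.structure_model import (
    MAX_FRAGMENT_LEN,
    MIN_FRAGMENT_LEN,
    Chain,
    CoordinateSet,
    Structure,
    StructureError,
    read_structure,
)

CHAIN_BREAK_CA_CA = 4.5  # Å; beyond any trans/cis peptide geometry

_ATOMS3 = ("N", "CA", "C")
_ATOMS4 = ("N", "CA", "C", "O")


@dataclass
class FragmentRecord:
    """One database fragment: sequence, provenance, backbone and fingerprint.

    ``coords`` has shape (length, atoms_per_residue, 3) with atom order
    N, CA, C(, O). The first and last residues are the fragment's own stems;
    the interior (length − 2 residues) is what fills a gap after grafting.
    """

    source_id: str
    chain_id: str
    first_residue_number: int
    length: int
    sequence: str
    coords: np.ndarray
    has_o: bool
    fingerprint: GeometricFingerprint = None  # type: ignore[assignment]
    fragment_id: int | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        apr = 4 if self.has_o else 3
        if self.coords.shape != (self.length, apr, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"length={self.length}, has_o={self.has_o}")
        if len(self.sequence) != self.length:
            raise ValueError("sequence length does not match fragment length")
        if self.fingerprint is None:
            self.fingerprint = self.compute_fingerprint()

    @property
    def atom_names(self) -> tuple[str, ...]:
        return _ATOMS4 if self.has_o else _ATOMS3

    @property
    def interior_sequence(self) -> str:
        return self.sequence[1:-1]

    def residue_atoms(self, index: int) -> dict[str, np.ndarray]:
        return {n: self.coords[index, i] for i, n in enumerate(self.atom_names)}

    def compute_fingerprint(self) -> GeometricFingerprint:
        return compute_fingerprint(self.residue_atoms(0),
                                   self.residue_atoms(self.length - 1))

    def backbone_coordinate_set(self) -> CoordinateSet:
        names = [n for _ in range(self.length) for n in self.atom_names]
        indices = np.repeat(np.arange(self.length), len(self.atom_names))
        return CoordinateSet(names, indices, self.coords.reshape(-1, 3))

    def interior_coordinate_set(self) -> CoordinateSet:
        inner = self.coords[1:-1]
        names = [n for _ in range(self.length - 2) for n in self.atom_names]
        indices = np.repeat(np.arange(self.length - 2), len(self.atom_names))
        return CoordinateSet(names, indices, inner.reshape(-1, 3))


# ---------------------------------------------------------------------------
# Extraction

def _complete_runs(chain: Chain) -> list[list[int]]:
    """Indices of maximal runs of complete, consecutively numbered residues."""
    runs: list[list[int]] = []
    current: list[int] = []
    prev = None
    for i, res in enumerate(chain.residues):
        ok = res.has_backbone()
        if not ok:
            if current:
                runs.append(current)
            current, prev = [], None
            continue
        if prev is not None:
            prev_res = chain.residues[prev]
            numbering_ok = (res.number == prev_res.number + 1 and not res.icode
                            and not prev_res.icode)
            ca_ca = np.linalg.norm(res.atoms["CA"] - prev_res.atoms["CA"])
            if not numbering_ok or ca_ca > CHAIN_BREAK_CA_CA:
                runs.append(current)
                current = []
        current.append(i)
        prev = i
    if current:
        runs.append(current)
    return runs


def extract_fragments(structure: Structure, min_len: int = MIN_FRAGMENT_LEN,
                      max_len: int = MAX_FRAGMENT_LEN,
                      source_id: str | None = None) -> list[FragmentRecord]:
    """All overlapping fragments of min_len–max_len residues, per chain.

    A chain of n complete consecutive residues yields Σ_L max(0, n − L + 1)
    records; windows spanning breaks or incomplete residues are skipped.
    """
    source = source_id if source_id is not None else (structure.name or "struct")
    records: list[FragmentRecord] = []
    for chain in structure.chains:
        for run in _complete_runs(chain):
            residues = [chain.residues[i] for i in run]
            n = len(residues)
            has_o_flags = ["O" in r.atoms for r in residues]
            for L in range(min_len, max_len + 1):
                for start in range(0, n - L + 1):
                    window = residues[start:start + L]
                    has_o = all(has_o_flags[start:start + L])
                    atoms = _ATOMS4 if has_o else _ATOMS3
                    coords = np.array([[r.atoms[a] for a in atoms] for r in window])
                    records.append(FragmentRecord(
                        source_id=source,
                        chain_id=chain.chain_id,
                        first_residue_number=window[0].number,
                        length=L,
                        sequence="".join(r.amino_acid for r in window),
                        coords=coords,
                        has_o=has_o,
                    ))
    return records


# ---------------------------------------------------------------------------
# Store

_SCHEMA = """
CREATE TABLE IF NOT EXISTS fragments (
    fragment_id INTEGER PRIMARY KEY,
    source_id TEXT NOT NULL,
    chain_id TEXT NOT NULL,
    first_residue_number INTEGER NOT NULL,
    length INTEGER NOT NULL,
    sequence TEXT NOT NULL,
    has_o INTEGER NOT NULL,
    d REAL NOT NULL,
    theta_n REAL NOT NULL,
    theta_c REAL NOT NULL,
    phi REAL NOT NULL,
    coords BLOB NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_len_d ON fragments (length, d);
"""


class FragmentDB:
    """Single-file sqlite-backed fragment store indexed by (length, d)."""

    def __init__(self, path):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)

    def close(self) -> None:
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    @staticmethod
    def _to_row(rec: FragmentRecord) -> tuple:
        fp = rec.fingerprint
        return (rec.source_id, rec.chain_id, rec.first_residue_number,
                rec.length, rec.sequence, int(rec.has_o),
                fp.d, fp.theta_n, fp.theta_c, fp.phi,
                rec.coords.astype("<f8").tobytes())

    @staticmethod
    def _from_row(row) -> FragmentRecord:
        (fid, source, chain, first, length, seq, has_o,
         d, tn, tc, phi, blob) = row
        apr = 4 if has_o else 3
        coords = np.frombuffer(blob, dtype="<f8").reshape(length, apr, 3).copy()
        return FragmentRecord(
            source_id=source, chain_id=chain, first_residue_number=first,
            length=length, sequence=seq, coords=coords, has_o=bool(has_o),
            fingerprint=GeometricFingerprint(d, tn, tc, phi), fragment_id=fid)

    def add_records(self, records: Iterable[FragmentRecord]) -> int:
        rows = [self._to_row(r) for r in records]
        with self._conn:
            self._conn.executemany(
                "INSERT INTO fragments (source_id, chain_id, first_residue_number,"
                " length, sequence, has_o, d, theta_n, theta_c, phi, coords)"
                " VALUES (?,?,?,?,?,?,?,?,?,?,?)", rows)
        return len(rows)

    def get(self, fragment_id: int) -> FragmentRecord:
        row = self._conn.execute(
            "SELECT * FROM fragments WHERE fragment_id=?", (fragment_id,)).fetchone()
        if row is None:
            raise KeyError(f"fragment {fragment_id} not in database")
        return self._from_row(row)

    def __len__(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM fragments").fetchone()[0]

    def counts_per_length(self) -> dict[int, int]:
        rows = self._conn.execute(
            "SELECT length, COUNT(*) FROM fragments GROUP BY length").fetchall()
        return {int(L): int(c) for L, c in rows}

    def iter_records(self) -> Iterable[FragmentRecord]:
        for row in self._conn.execute(
                "SELECT * FROM fragments ORDER BY fragment_id"):
            yield self._from_row(row)

    def query_by_length_distance(self, length: int, d: float,
                                 delta_d: float) -> list[FragmentRecord]:
        """Records with record.length == length and |d_rec − d| < delta_d (strict)."""
        if not (MIN_FRAGMENT_LEN <= length <= MAX_FRAGMENT_LEN):
            raise ValueError(f"length {length} outside [{MIN_FRAGMENT_LEN}, "
                             f"{MAX_FRAGMENT_LEN}]")
        if delta_d <= 0:
            raise ValueError("delta_d must be positive")
        rows = self._conn.execute(
            "SELECT * FROM fragments WHERE length=? AND d>? AND d<? "
            "ORDER BY fragment_id",
            (length, d - delta_d, d + delta_d)).fetchall()
        # SQL comparisons are on the stored float; re-check strictness exactly
        return [r for r in map(self._from_row, rows)
                if abs(r.fingerprint.d - d) < delta_d]


def query_by_length_distance(db: FragmentDB, length: int, d: float,
                             delta_d: float) -> list[FragmentRecord]:
    return db.query_by_length_distance(length, d, delta_d)


@dataclass
class BuildReport:
    n_records: int = 0
    records_per_length: dict = field(default_factory=dict)
    n_files: int = 0
    n_warnings: int = 0
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "records_per_length": dict(sorted(self.records_per_length.items())),
            "n_files": self.n_files,
            "n_warnings": self.n_warnings,
            "warnings": list(self.warnings),
        }


def build_db(structure_paths: Sequence, db_path, min_len: int = MIN_FRAGMENT_LEN,
             max_len: int = MAX_FRAGMENT_LEN) -> tuple[FragmentDB, BuildReport]:
    """Extract fragments from all readable input structures into one store.

    Unreadable files are logged into the report and skipped. Duplicate inputs
    produce duplicate records by design; de-duplication is a search-stage
    concern.
    """
    db = FragmentDB(db_path)
    report = BuildReport()
    for path in structure_paths:
        try:
            structure = read_structure(path)
        except StructureError as exc:
            report.n_warnings += 1
            report.warnings.append(str(exc))
            continue
        records = extract_fragments(structure, min_len, max_len)
        db.add_records(records)
        report.n_files += 1
        for rec in records:
            report.records_per_length[rec.length] = (
                report.records_per_length.get(rec.length, 0) + 1)
    report.n_records = len(db)
    return db, report


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def filter_identity(records: Sequence[FragmentRecord], query_sequence: str,
                    max_identity: float = 0.90) -> list[FragmentRecord]:
    """Drop records whose identity to the query is strictly above the cutoff.

    A record's interior sequence (the residues that would fill the gap) is
    compared position-wise against the query; a record at exactly the cutoff
    (e.g. 9/10 positions for the default 0.90) is retained.
    """
    kept = []
    for rec in records:
        if sequence_identity(rec.interior_sequence, query_sequence) <= max_identity:
            kept.append(rec)
    return kept
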