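"""Synthetic test inputs: ideal segments, toy proteins, mini databases, maps.

Everything here is generated programmatically and deterministically from a
seed, so the full pipeline is testable without any downloads. Backbones are
built from ideal internal coordinates (bond lengths/angles of the trans
peptide) by natural extension of reference frames (NeRF), with canonical
torsions per secondary-structure class:

* helix:  φ = −57°, ψ = −47°  (1.5 Å rise, ~100°/residue CA trace)
* strand: φ = −120°, ψ = +120° with an alternating ±10° pleat on ψ
* loop:   φ, ψ drawn from the broad coil region, with self-avoidance retries

Decoy fragments perturb the native interior while keeping the terminal
(stem) residues fixed, so they pass the geometric stage-1 screen by
construction and the density re-ranking becomes the deciding stage. Fixture
"experimental" maps are simulated maps plus optional i.i.d. Gaussian voxel
noise at a configured SNR; real maps have structured noise, which these
fixtures do not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fragfit.density import DensityMap, default_box, simulate_map
from fragfit.fragment_db import FragmentDB, FragmentRecord, extract_fragments
from fragfit.structure_model import (
    Chain,
    CoordinateSet,
    GapSpec,
    Residue,
    Structure,
    define_gap,
)

# trans-peptide ideal internal coordinates (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.5
OMEGA = 180.0

TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
}
STRAND_PLEAT = 10.0
LOOP_PHI_RANGE = (-160.0, -50.0)
LOOP_PSI_RANGE = (-70.0, 170.0)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FixtureError(ValueError):
    """Raised when a fixture layout cannot be realized."""


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position of atom D given A-B-C and internal coordinates of D."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(phi: Sequence[float], psi: Sequence[float]) -> np.ndarray:
    """Backbone (n, 4, 3) with atom order N, CA, C, O from torsion lists.

    ``phi[0]`` is unused (no preceding carbonyl); ``psi[-1]`` still orients
    the final carbonyl oxygen.
    """
    n = len(phi)
    coords = np.zeros((n, 4, 3))
    coords[0, 0] = np.array([0.0, 0.0, 0.0])
    coords[0, 1] = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    coords[0, 2] = coords[0, 1] + B_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0])
    for i in range(n - 1):
        Ni, CAi, Ci = coords[i, 0], coords[i, 1], coords[i, 2]
        Nn = _place_atom(Ni, CAi, Ci, B_C_N, A_CA_C_N, psi[i])
        CAn = _place_atom(CAi, Ci, Nn, B_N_CA, A_C_N_CA, OMEGA)
        Cn = _place_atom(Ci, Nn, CAn, B_CA_C, A_N_CA_C, phi[i + 1])
        coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2] = Nn, CAn, Cn
        coords[i, 3] = _place_atom(Ni, CAi, Ci, B_C_O, A_CA_C_O, psi[i] + 180.0)
    last = n - 1
    coords[last, 3] = _place_atom(coords[last, 0], coords[last, 1],
                                  coords[last, 2], B_C_O, A_CA_C_O,
                                  psi[last] + 180.0)
    return coords


def _self_clash(coords: np.ndarray, cutoff: float = 2.0) -> bool:
    """True if any atoms of residues at least 2 apart are closer than cutoff."""
    n = len(coords)
    flat = coords.reshape(-1, 3)
    res_idx = np.repeat(np.arange(n), coords.shape[1])
    from scipy.spatial import cKDTree
    tree = cKDTree(flat)
    for i, j in tree.query_pairs(r=cutoff):
        if abs(res_idx[i] - res_idx[j]) >= 2:
            return True
    return False


def _draw_torsions(kinds: Sequence[str], rng: np.random.Generator
                   ) -> tuple[list[float], list[float]]:
    phi, psi = [], []
    for i, kind in enumerate(kinds):
        if kind == "loop":
            phi.append(float(rng.uniform(*LOOP_PHI_RANGE)))
            psi.append(float(rng.uniform(*LOOP_PSI_RANGE)))
        elif kind == "strand":
            p, s = TORSIONS["strand"]
            psi.append(s + (STRAND_PLEAT if i % 2 else -STRAND_PLEAT))
            phi.append(p)
        elif kind == "helix":
            p, s = TORSIONS["helix"]
            phi.append(p)
            psi.append(s)
        else:
            raise FixtureError(f"unknown secondary-structure kind {kind!r}")
    return phi, psi


def _backbone_from_kinds(kinds: Sequence[str], rng: np.random.Generator,
                         max_tries: int = 200) -> np.ndarray:
    has_loop = "loop" in kinds
    for _ in range(max_tries):
        phi, psi = _draw_torsions(kinds, rng)
        coords = _build_backbone(phi, psi)
        if not _self_clash(coords):
            return coords
        if not has_loop:
            raise FixtureError(
                "layout with fixed torsions is self-clashing; impossible layout")
    raise FixtureError(f"could not realize a clash-free layout in {max_tries} tries")


def make_ideal_segment(kind: str, length: int, seed: int = 0) -> CoordinateSet:
    """An ideal-geometry backbone segment (N, CA, C, O per residue)."""
    if length < 3:
        raise FixtureError("segment length must be at least 3")
    rng = np.random.default_rng(seed)
    coords = _backbone_from_kinds([kind] * length, rng)
    names = [a for _ in range(length) for a in ("N", "CA", "C", "O")]
    indices = np.repeat(np.arange(length), 4)
    return CoordinateSet(names, indices, coords.reshape(-1, 3))


def perturb_fragment(frag: CoordinateSet, sd: float, seed: int = 0) -> CoordinateSet:
    """Add isotropic Gaussian displacement to interior atoms.

    Atoms of the first and last residue (the stems) are kept bitwise fixed.
    Bond lengths of the perturbed interior are NOT restored: decoys are
    geometric, not stereochemical, objects.
    """
    if sd < 0:
        raise FixtureError("perturbation sd must be non-negative")
    coords = frag.coords.copy()
    if sd > 0:
        rng = np.random.default_rng(seed)
        lo, hi = frag.residue_indices.min(), frag.residue_indices.max()
        interior = (frag.residue_indices != lo) & (frag.residue_indices != hi)
        coords[interior] += rng.normal(0.0, sd, size=(interior.sum(), 3))
    return frag.with_coords(coords)


@dataclass
class FixtureSpec:
    """Layout and randomness of one toy-fixture set (seed-deterministic)."""
    seed: int = 0
    layouts: list = field(default_factory=lambda: [
        [("helix", 14), ("loop", 6), ("strand", 8), ("loop", 6), ("helix", 10)],
        [("strand", 8), ("loop", 5), ("strand", 8), ("loop", 5), ("helix", 14)],
        [("helix", 10), ("loop", 8), ("helix", 12), ("loop", 6), ("strand", 8)],
    ])
    perturb_sd: float = 1.0
    n_decoys: int = 20


def build_toy_protein_set(spec: FixtureSpec) -> list[Structure]:
    """Toy single-chain proteins concatenating the specified H/E/L runs."""
    rng = np.random.default_rng(spec.seed)
    structures = []
    for s_idx, layout in enumerate(spec.layouts):
        kinds = [kind for kind, run_len in layout for _ in range(run_len)]
        coords = _backbone_from_kinds(kinds, rng)
        seq = "".join(rng.choice(list(AMINO_ACIDS)) for _ in kinds)
        chain = Chain(chain_id="A")
        for i, aa in enumerate(seq):
            chain.residues.append(Residue(
                number=i + 1, amino_acid=aa,
                atoms={n: coords[i, j].copy()
                       for j, n in enumerate(("N", "CA", "C", "O"))}))
        structures.append(Structure(chains=[chain], name=f"toy{s_idx}"))
    return structures


def make_toy_gap(kind: str, length: int, seed: int = 0,
                 flank: int = 8) -> tuple[Structure, GapSpec]:
    """A toy protein with an embedded run of ``kind`` and a gap over it.

    The structure is helix–(kind run of length+2)–helix; the gap's stems are
    the first and last residue of the middle run, so the queried segment is
    exactly the run interior and its native class is ``kind``.
    """
    layout = [("helix", flank), (kind, length + 2), ("helix", flank)]
    spec = FixtureSpec(seed=seed, layouts=[layout])
    structure = build_toy_protein_set(spec)[0]
    chain = structure.chains[0]
    nstem = flank + 1
    cstem = flank + length + 2
    seq = "".join(chain.residues[i].amino_acid
                  for i in range(nstem, cstem - 1))
    gap = define_gap(structure, "A", nstem, cstem, seq)
    return structure, gap


# ---------------------------------------------------------------------------
# Mini databases

def native_fragment_record(gap: GapSpec, source_id: str = "native") -> FragmentRecord:
    """The gap's own stems-plus-segment window as a database record."""
    chain = gap.structure.chain(gap.chain_id)
    i_n = chain.index_of(gap.nstem_residue)
    i_c = chain.index_of(gap.cstem_residue)
    window = chain.residues[i_n:i_c + 1]
    has_o = all("O" in r.atoms for r in window)
    atoms = ("N", "CA", "C", "O") if has_o else ("N", "CA", "C")
    coords = np.array([[r.atoms[a] for a in atoms] for r in window])
    return FragmentRecord(
        source_id=source_id, chain_id=gap.chain_id,
        first_residue_number=window[0].number, length=len(window),
        sequence="".join(r.amino_acid for r in window),
        coords=coords, has_o=has_o)


def _mutate_sequence(seq: str, rng: np.random.Generator) -> str:
    """Mutate at least half of the positions (identity guaranteed ≤ 0.5)."""
    n_mut = (len(seq) + 1) // 2
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        choices = [a for a in AMINO_ACIDS if a != out[p]]
        out[p] = str(rng.choice(choices))
    return "".join(out)


def make_decoy_records(gap: GapSpec, n_decoys: int, seed: int = 0,
                       sd_range: tuple[float, float] = (0.25, 2.5)
                       ) -> list[FragmentRecord]:
    """Stage-1-passing decoys: perturbed native interior, mutated sequence.

    Terminal (stem) residues stay fixed, so each decoy's fingerprint
    distance d equals the gap's exactly and the geometric pre-screen cannot
    reject it — discrimination is left to the later stages.
    """
    native = native_fragment_record(gap)
    rng = np.random.default_rng(seed)
    decoys = []
    for i in range(n_decoys):
        sd = float(rng.uniform(*sd_range))
        coords = native.coords.copy()
        coords[1:-1] += rng.normal(0.0, sd, size=coords[1:-1].shape)
        interior = _mutate_sequence(native.interior_sequence, rng)
        seq = native.sequence[0] + interior + native.sequence[-1]
        decoys.append(FragmentRecord(
            source_id=f"decoy{i}", chain_id=gap.chain_id,
            first_residue_number=native.first_residue_number,
            length=native.length, sequence=seq, coords=coords,
            has_o=native.has_o))
    return decoys


def build_mini_db(structures: Sequence[Structure], gap: GapSpec,
                  include_native: bool = True, n_decoys: int = 20,
                  seed: int = 0, db_path=":memory:",
                  sd_range: tuple[float, float] = (0.25, 2.5),
                  min_len: int = 3, max_len: int | None = None) -> FragmentDB:
    """Desk-scale fragment database: toy-set fragments + native + decoys."""
    db = FragmentDB(db_path)
    max_len = max_len if max_len is not None else max(
        gap.fragment_length, min_len)
    for st in structures:
        db.add_records(extract_fragments(st, min_len, max_len))
    if include_native:
        db.add_records([native_fragment_record(gap)])
    if n_decoys > 0:
        db.add_records(make_decoy_records(gap, n_decoys, seed=seed,
                                          sd_range=sd_range))
    return db


def build_benchmark_db(structures: Sequence[Structure], gaps: Sequence[GapSpec],
                       include_native: bool = True, n_decoys: int = 20,
                       seed: int = 0, db_path=":memory:",
                       sd_range: tuple[float, float] = (0.25, 2.5)) -> FragmentDB:
    """One database seeding stage-1-passing decoys for every benchmark gap."""
    db = FragmentDB(db_path)
    lengths = {g.fragment_length for g in gaps}
    for st in structures:
        db.add_records(extract_fragments(st, min(lengths), max(lengths)))
    for k, gap in enumerate(gaps):
        if include_native:
            db.add_records([native_fragment_record(gap, source_id=f"native{k}")])
        db.add_records(make_decoy_records(gap, n_decoys, seed=seed + 7919 * k,
                                          sd_range=sd_range))
    return db


# ---------------------------------------------------------------------------
# Fixture maps

def all_atom_coords(structure: Structure) -> CoordinateSet:
    names, indices, coords = [], [], []
    i = 0
    for chain in structure.chains:
        for res in chain.residues:
            for n, xyz in res.atoms.items():
                names.append(n)
                indices.append(i)
                coords.append(xyz)
            i += 1
    return CoordinateSet(names, indices, np.vstack(coords))


def fixture_voxel_size(resolution: float) -> float:
    """Sampling used for fixture maps: resolution/4, clamped to [1, 3] Å."""
    return float(np.clip(resolution / 4.0, 1.0, 3.0))


def make_experimental_map(structure: Structure, resolution: float,
                          voxel_size: float | None = None,
                          snr: float | None = None, seed: int = 0,
                          margin: float | None = None) -> DensityMap:
    """Simulated stand-in for an experimental map, with optional voxel noise.

    ``snr`` is the ratio of the noiseless map's standard deviation to the
    added Gaussian noise's; ``snr=None`` adds no noise.
    """
    voxel = voxel_size if voxel_size is not None else fixture_voxel_size(resolution)
    coords = all_atom_coords(structure)
    if margin is None:
        margin = resolution + 2 * voxel
    origin, shape = default_box(coords, voxel, margin)
    dmap = simulate_map(coords, voxel, resolution, (origin, shape))
    if snr is not None:
        rng = np.random.default_rng(seed)
        noise_sd = float(dmap.values.std()) / snr
        dmap.values = dmap.values + rng.normal(0.0, noise_sd, size=dmap.shape)
    return dmap
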