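"""Model quality metrics and benchmark harnesses.

Backbone RMSD is computed in the frame fixed by the stem superposition — no
further fitting happens inside the metric. The TM-score uses the simplified
identical-length form (all residues aligned, stem-anchored frame):

    TM = (1/L) Σ_i 1 / (1 + d_i²/d0²)

with the standard length-dependent scale d0(L) = 1.24·(L−15)^⅓ − 1.8,
floored at 0.5 Å, computed over CA atoms.

The benchmark harness slides a window over a (toy) structure, deletes the
native segment from the context, runs the full pipeline against a density
map, and records the geometric-search top-1, density-reranked top-1 and
best-of-top-5 RMSD per window, plus ΔRMSD = RMSD(search) − RMSD(density
rerank), the gain from using the map as a restraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fragfit.density import DensityMap
from fragfit.fragfit_score import FitResult, run_fragfit
from fragfit.fragment_db import FragmentDB
from fragfit.fragsearch import SearchParams
from fragfit.geometry import dihedral_deg
from fragfit.structure_model import (
    Chain,
    CoordinateSet,
    GapSpec,
    Structure,
    define_gap,
)
from fragfit.synthetic_fixtures import all_atom_coords, fixture_voxel_size
from fragfit.density import default_box, simulate_map


def backbone_rmsd(x, y) -> float:
    """Root-mean-square deviation between matched coordinate sets (Å).

    Both sets must already be in a common frame (stem-superposed); this
    function performs no fitting.
    """
    xa = x.coords if isinstance(x, CoordinateSet) else np.asarray(x, float)
    ya = y.coords if isinstance(y, CoordinateSet) else np.asarray(y, float)
    if xa.shape != ya.shape:
        raise ValueError(f"coordinate shape mismatch: {xa.shape} vs {ya.shape}")
    if len(xa) == 0:
        raise ValueError("empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((xa - ya) ** 2, axis=1))))


def d0_scale(L: int) -> float:
    """Standard TM-score distance scale, floored at 0.5 Å."""
    if L > 15:
        return max(1.24 * (L - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


@dataclass(frozen=True)
class TMScoreParams:
    L: int
    d0: float | None = None

    @property
    def scale(self) -> float:
        d0 = self.d0 if self.d0 is not None else d0_scale(self.L)
        if d0 <= 0:
            raise ValueError("d0 must be positive")
        return d0


def tm_score(x, y, params: TMScoreParams | None = None) -> float:
    """Simplified TM-score over matched CA coordinates in a fixed frame."""
    xa = x.coords if isinstance(x, CoordinateSet) else np.asarray(x, float)
    ya = y.coords if isinstance(y, CoordinateSet) else np.asarray(y, float)
    if xa.shape != ya.shape:
        raise ValueError(f"coordinate shape mismatch: {xa.shape} vs {ya.shape}")
    L = len(xa)
    if L == 0:
        raise ValueError("empty coordinate sets")
    if params is None:
        params = TMScoreParams(L=L)
    d0 = params.scale
    di2 = np.sum((xa - ya) ** 2, axis=1)
    return float(np.mean(1.0 / (1.0 + di2 / d0**2)))


# ---------------------------------------------------------------------------
# Secondary-structure labeling (torsion-based; loops absorb everything else)

_HELIX_PHI, _HELIX_PSI = (-100.0, -30.0), (-80.0, -5.0)
_STRAND_PHI, _STRAND_PSI = (-180.0, -80.0), (80.0, 180.0)


def _phi_psi(chain: Chain) -> list[tuple[float | None, float | None]]:
    out = []
    res = chain.residues
    for i, r in enumerate(res):
        phi = psi = None
        try:
            if i > 0 and all(a in res[i - 1].atoms for a in ("C",)):
                phi = dihedral_deg(res[i - 1].atoms["C"], r.atoms["N"],
                                   r.atoms["CA"], r.atoms["C"])
            if i < len(res) - 1 and "N" in res[i + 1].atoms:
                psi = dihedral_deg(r.atoms["N"], r.atoms["CA"], r.atoms["C"],
                                   res[i + 1].atoms["N"])
        except KeyError:
            pass
        out.append((phi, psi))
    return out


def assign_secondary_structure(structure: Structure, chain_id: str) -> str:
    """Per-residue H/E/L string from φ/ψ torsions (run-length filtered)."""
    chain = structure.chain(chain_id)
    torsions = _phi_psi(chain)
    raw = []
    for phi, psi in torsions:
        if phi is not None and psi is not None and \
                _HELIX_PHI[0] <= phi <= _HELIX_PHI[1] and \
                _HELIX_PSI[0] <= psi <= _HELIX_PSI[1]:
            raw.append("H")
        elif phi is not None and psi is not None and \
                _STRAND_PHI[0] <= phi <= _STRAND_PHI[1] and \
                _STRAND_PSI[0] <= psi <= _STRAND_PSI[1]:
            raw.append("E")
        else:
            raw.append("L")
    # minimum run lengths: helix 4, strand 3; shorter runs become loop
    out = list(raw)
    i = 0
    n = len(raw)
    while i < n:
        j = i
        while j < n and raw[j] == raw[i]:
            j += 1
        run_len = j - i
        min_run = {"H": 4, "E": 3}.get(raw[i], 1)
        if run_len < min_run:
            for k in range(i, j):
                out[k] = "L"
        i = j
    return "".join(out)


def segment_class(ss: str, start: int, end: int) -> str:
    """Majority secondary-structure class of residues [start, end) (0-based)."""
    seg = ss[start:end]
    counts = {c: seg.count(c) for c in "HEL"}
    best = max(counts, key=lambda c: (counts[c], c))
    return {"H": "helix", "E": "strand", "L": "loop"}[best]


# ---------------------------------------------------------------------------
# Benchmark harnesses

def _candidate_rmsd(cand, native: CoordinateSet) -> float:
    placed = cand.placed_coords.select_atoms(("N", "CA", "C"))
    return backbone_rmsd(placed, native)


def evaluate_fit(result: FitResult, gap: GapSpec) -> dict | None:
    """Per-gap quality summary of a pipeline result against the native segment."""
    native = gap.native_segment()
    if native is None or not result.candidates:
        return None
    by_search = sorted(result.candidates, key=lambda c: c.fragsearch_rank)
    by_fit = sorted(result.candidates, key=lambda c: c.fragfit_rank)
    rmsd_search = _candidate_rmsd(by_search[0], native)
    rmsd_fit = _candidate_rmsd(by_fit[0], native)
    rmsd_best5 = min(_candidate_rmsd(c, native) for c in by_fit[:5])
    native_ca = gap.native_segment(atoms=("CA",))
    top1_ca = by_fit[0].placed_coords.select_atoms(("CA",))
    tm = tm_score(top1_ca, native_ca)
    return {
        "length": gap.length,
        "rmsd_fragsearch_top1": rmsd_search,
        "rmsd_fragfit_top1": rmsd_fit,
        "rmsd_fragfit_best_of_5": rmsd_best5,
        "tm_score_top1": tm,
        "delta_rmsd": rmsd_search - rmsd_fit,
        "n_candidates": len(result.candidates),
    }


def enumerate_window_gaps(structure: Structure, lengths, stride: int = 1,
                          chain_id: str = "A") -> list[tuple[int, GapSpec]]:
    """All stem-flanked sliding-window gaps of the given segment lengths.

    Returns (start, gap) pairs where start is the 0-based chain index of the
    first segment residue. Windows with incomplete backbone are skipped.
    """
    chain = structure.chain(chain_id)
    n = len(chain)
    gaps = []
    for L in lengths:
        for start in range(1, n - L, stride):
            residues = chain.residues[start - 1:start + L + 1]
            if len(residues) < L + 2 or not all(r.has_backbone() for r in residues):
                continue
            seq = "".join(r.amino_acid for r in residues[1:-1])
            try:
                gap = define_gap(structure, chain_id, residues[0].resid,
                                 residues[-1].resid, seq)
            except Exception:  # noqa: BLE001
                continue
            gaps.append((start, gap))
    return gaps


def benchmark_sliding_window(structure: Structure, exp_map: DensityMap,
                             resolution: float, db: FragmentDB,
                             window_range: tuple[int, int] = (5, 35),
                             params: SearchParams = SearchParams(),
                             chain_id: str = "A", stride: int = 1,
                             benchmark_mode: bool = True,
                             lengths=None) -> pd.DataFrame:
    """Slide windows of every length in ``window_range`` over the chain.

    For each window a gap is defined over it (stems = flanking residues),
    the native segment is removed from the context, the full pipeline runs
    in benchmark mode (identity filter active), and the quality metrics are
    recorded. Windows with incomplete backbone or an empty shortlist are
    skipped. ``stride`` subsamples window start positions; ``lengths``
    overrides the contiguous ``window_range`` with an explicit length list.
    """
    ss = assign_secondary_structure(structure, chain_id)
    if lengths is None:
        lengths = range(window_range[0], window_range[1] + 1)
    rows = []
    for start, gap in enumerate_window_gaps(structure, lengths, stride, chain_id):
        L = gap.length
        try:
            result = run_fragfit(gap, db, exp_map, resolution, params,
                                 benchmark_mode=benchmark_mode)
        except Exception:  # noqa: BLE001 - benchmark skips failing windows
            continue
        metrics = evaluate_fit(result, gap)
        if metrics is None:
            continue
        metrics["gap_id"] = f"{structure.name}:{chain_id}:{start + 1}-{start + L}"
        metrics["ss_class"] = segment_class(ss, start, start + L)
        rows.append(metrics)
    columns = ["gap_id", "length", "ss_class", "rmsd_fragsearch_top1",
               "rmsd_fragfit_top1", "rmsd_fragfit_best_of_5", "tm_score_top1",
               "delta_rmsd", "n_candidates"]
    return pd.DataFrame(rows, columns=columns)


def resolution_sweep(structure: Structure, resolutions, db: FragmentDB,
                     params: SearchParams = SearchParams(),
                     window_range: tuple[int, int] = (5, 9),
                     chain_id: str = "A", stride: int = 1,
                     lengths=None) -> pd.DataFrame:
    """Mean ΔRMSD per (resolution, segment length) over simulated maps.

    For each resolution a map of the full structure is simulated and the
    sliding-window benchmark is run against it.
    """
    tables = []
    for resolution in resolutions:
        voxel = fixture_voxel_size(resolution)
        coords = all_atom_coords(structure)
        origin, shape = default_box(coords, voxel, resolution + 2 * voxel)
        exp_map = simulate_map(coords, voxel, resolution, (origin, shape))
        bench = benchmark_sliding_window(structure, exp_map, resolution, db,
                                         window_range=window_range,
                                         params=params, chain_id=chain_id,
                                         stride=stride, lengths=lengths)
        if bench.empty:
            continue
        agg = (bench.groupby("length")["delta_rmsd"].mean()
               .reset_index())
        agg.insert(0, "resolution", resolution)
        tables.append(agg)
    if not tables:
        return pd.DataFrame(columns=["resolution", "length", "delta_rmsd"])
    return pd.concat(tables, ignore_index=True)
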