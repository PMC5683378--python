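"""Four-stage hierarchical fragment search producing a top-100 shortlist.

Stage 1 selects fragments of the right length whose stem-stem distance d is
within Δd < 0.75 Å of the gap's. Stage 2 superposes each candidate's
terminal residues onto the gap stems and keeps the best 1000 by stem RMSD.
Stage 3 grafts candidates into the gap, removes those clashing with the
structural context, and deletes redundant conformers (identical sequence, or
placed-backbone RMSD < 0.5 Å — the copy with the lower stem RMSD survives).
Stage 4 re-ranks the survivors by a combination of sequence similarity to
the query and fingerprint match, truncated to the top 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from fragfit.fragment_db import FragmentDB, FragmentRecord, filter_identity
from fragfit.geometry import (
    RigidTransform,
    compute_fingerprint,
    detect_clashes,
    fingerprint_deviation,
    graft_fragment,
    superpose_fragment,
)
from fragfit.structure_model import CoordinateSet, GapSpec


@dataclass(frozen=True)
class SearchParams:
    delta_d: float = 0.75          # Å, stage-1 stem-distance window (strict <)
    redundancy_rmsd: float = 0.5   # Å, stage-3 fold-identity threshold (strict <)
    clash_cutoff: float = 2.0      # Å, heavy-atom clash distance
    pool_size: int = 1000          # stage-2 truncation
    shortlist_size: int = 100      # stage-4 truncation
    identity_cutoff: float = 0.90  # benchmark mode: drop identity > cutoff
    w_seq: float = 0.5             # stage-4 weight on sequence similarity
    w_geo: float = 0.5             # stage-4 weight on fingerprint deviation

    def __post_init__(self):
        if min(self.delta_d, self.redundancy_rmsd, self.clash_cutoff,
               self.pool_size, self.shortlist_size) <= 0:
            raise ValueError("all search parameters must be positive")
        if self.shortlist_size > self.pool_size:
            raise ValueError("shortlist_size must not exceed pool_size")


@dataclass
class ScoredCandidate:
    fragment_id: int
    record: FragmentRecord
    transform: RigidTransform
    placed_coords: CoordinateSet      # interior residues, gap frame
    stem_rmsd: float
    seq_similarity: float | None = None
    fp_deviation: float | None = None
    combined_score: float | None = None
    ccc: float | None = None          # unset until the density re-ranking stage
    fragsearch_rank: int | None = None
    fragfit_rank: int | None = None
    flags: list = field(default_factory=list)


@dataclass
class SearchResult:
    gap: GapSpec
    candidates: list[ScoredCandidate]
    stage_counts: dict[int, int]


# ---------------------------------------------------------------------------
# Sequence similarity

@lru_cache(maxsize=1)
def _blosum62():
    mat = substitution_matrices.load("BLOSUM62")
    smin = float(np.min(np.asarray(mat)))
    return mat, smin


def sequence_similarity(a: str, b: str) -> float:
    """Normalized substitution-matrix similarity in [0, 1]; 1 iff identical.

    Per position, the BLOSUM62 score is min-max normalized against the
    matrix's global minimum and the mean of the two residues' self-scores,
    then averaged over positions. The measure is symmetric.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    mat, smin = _blosum62()
    total = 0.0
    for x, y in zip(a, b):
        x = x if x in mat.alphabet else "X"
        y = y if y in mat.alphabet else "X"
        self_ref = 0.5 * (mat[x, x] + mat[y, y])
        denom = self_ref - smin
        score = (mat[x, y] - smin) / denom if denom > 0 else 0.0
        total += float(np.clip(score, 0.0, 1.0))
    return total / len(a)


# ---------------------------------------------------------------------------
# Search pipeline

def _interior_nca(candidate: ScoredCandidate) -> np.ndarray:
    return candidate.placed_coords.select_atoms(("N", "CA", "C")).coords


def run_fragsearch(gap: GapSpec, db: FragmentDB,
                   params: SearchParams = SearchParams(),
                   benchmark_mode: bool = False) -> SearchResult:
    """Run the four-stage hierarchical search for a gap against a database.

    In benchmark mode, records with sequence identity strictly above
    ``params.identity_cutoff`` to the query are removed after stage 1 —
    mimicking evaluation against an "unknown" structure.
    """
    gap_fp = compute_fingerprint(gap.stem_atoms("n", include_o=False),
                                 gap.stem_atoms("c", include_o=False))
    stage_counts: dict[int, int] = {}

    # stage 1: same length, similar stem distance (strict Δd window)
    records = db.query_by_length_distance(gap.fragment_length, gap_fp.d,
                                          params.delta_d)
    if benchmark_mode:
        records = filter_identity(records, gap.query_sequence,
                                  params.identity_cutoff)
    stage_counts[1] = len(records)
    if not records:
        return SearchResult(gap, [], {1: 0, 2: 0, 3: 0, 4: 0})

    # stage 2: rank by stem RMSD after terminal-residue superposition
    candidates: list[ScoredCandidate] = []
    for rec in records:
        transform, stem_rmsd = superpose_fragment(rec, gap)
        placed = graft_fragment(rec, gap, transform=transform)
        candidates.append(ScoredCandidate(
            fragment_id=rec.fragment_id if rec.fragment_id is not None else -1,
            record=rec, transform=transform, placed_coords=placed,
            stem_rmsd=stem_rmsd))
    candidates.sort(key=lambda c: (c.stem_rmsd, c.fragment_id))
    candidates = candidates[:params.pool_size]
    stage_counts[2] = len(candidates)

    # stage 3: clash exclusion, then redundancy deletion
    context = gap.context_coords(include_stems=False)
    survivors: list[ScoredCandidate] = []
    for cand in candidates:
        if detect_clashes(cand.placed_coords, context, params.clash_cutoff) > 0:
            continue
        survivors.append(cand)
    kept: list[ScoredCandidate] = []
    kept_nca: list[np.ndarray] = []
    kept_seqs: set[str] = set()
    for cand in survivors:  # already ordered by stem_rmsd: first copy is best
        seq = cand.record.sequence
        if seq in kept_seqs:
            continue
        nca = _interior_nca(cand)
        redundant = any(
            float(np.sqrt(np.mean(np.sum((nca - other) ** 2, axis=1))))
            < params.redundancy_rmsd
            for other in kept_nca)
        if redundant:
            continue
        kept.append(cand)
        kept_nca.append(nca)
        kept_seqs.add(seq)
    stage_counts[3] = len(kept)

    # stage 4: re-rank by sequence similarity and fingerprint match
    for cand in kept:
        cand.seq_similarity = sequence_similarity(
            cand.record.interior_sequence, gap.query_sequence)
        cand.fp_deviation = fingerprint_deviation(cand.record.fingerprint, gap_fp)
        geo_term = cand.fp_deviation / (1.0 + cand.fp_deviation)
        cand.combined_score = (params.w_seq * cand.seq_similarity
                               - params.w_geo * geo_term)
    kept.sort(key=lambda c: (-c.combined_score, c.stem_rmsd, c.fragment_id))
    shortlist = kept[:params.shortlist_size]
    for rank, cand in enumerate(shortlist, start=1):
        cand.fragsearch_rank = rank
    stage_counts[4] = len(shortlist)
    return SearchResult(gap, shortlist, stage_counts)


def stage_report(result: SearchResult) -> dict[int, int]:
    """Per-stage candidate counts (monotone non-increasing over stages)."""
    return dict(sorted(result.stage_counts.items()))
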