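"""Density-based re-ranking of the FragSearch shortlist and model export.

Each shortlisted candidate's placed interior coordinates are converted into
a simulated density map on the grid of the (context-subtracted) experimental
sub-box and compared against it by Pearson cross-correlation; the shortlist
is re-ordered by descending CCC. Re-ranking never changes the candidate set,
only the order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fragfit.density import (
    DensityError,
    DensityMap,
    minimal_box,
    pearson_ccc,
    simulate_map,
    subtract_context,
)
from fragfit.fragsearch import ScoredCandidate, SearchParams, SearchResult, run_fragsearch
from fragfit.fragment_db import FragmentDB
from fragfit.structure_model import (
    GapSpec,
    Residue,
    Structure,
    write_structure,
)


@dataclass
class FitResult:
    gap: GapSpec
    candidates: list[ScoredCandidate]  # ordered by descending CCC
    stage_counts: dict[int, int]
    resolution: float | None = None
    box_shape: tuple | None = None
    diagnostics: dict = field(default_factory=dict)


def score_candidates(shortlist: list[ScoredCandidate], residual_box: DensityMap,
                     resolution: float) -> list[ScoredCandidate]:
    """Assign a CCC to every candidate against the residual density box.

    Candidates whose placed atoms all fall outside the box (or whose
    simulated density is degenerate) receive ccc = −1 and are flagged.
    """
    for cand in shortlist:
        try:
            sim = simulate_map(cand.placed_coords, residual_box.voxel_size,
                               resolution, residual_box, clip=True)
            cand.ccc = pearson_ccc(sim, residual_box)
        except DensityError:
            cand.ccc = -1.0
            cand.flags.append("outside_box")
    return shortlist


def rank_by_ccc(candidates: list[ScoredCandidate]) -> list[ScoredCandidate]:
    ordered = sorted(candidates,
                     key=lambda c: (-c.ccc, c.stem_rmsd, c.fragment_id))
    for rank, cand in enumerate(ordered, start=1):
        cand.fragfit_rank = rank
    return ordered


def run_fragfit(gap: GapSpec, db: FragmentDB, exp_map: DensityMap,
                resolution: float, params: SearchParams = SearchParams(),
                benchmark_mode: bool = False,
                subtract: bool = True) -> FitResult:
    """Full pipeline: hierarchical search, map preprocessing, CCC re-ranking.

    ``subtract=False`` scores against the normalized (but unsubtracted)
    minimal box, for ablation. The input map is never modified; all
    preprocessing happens on the extracted sub-box copy.
    """
    search = run_fragsearch(gap, db, params, benchmark_mode=benchmark_mode)
    if not search.candidates:
        return FitResult(gap, [], search.stage_counts, resolution=resolution,
                         diagnostics={"empty_shortlist": True})
    box = minimal_box(gap, exp_map, pad=resolution)
    context = gap.context_coords(include_stems=True)
    if subtract:
        residual = subtract_context(box, context, resolution)
    else:
        from fragfit.density import normalize_map
        residual = normalize_map(box)
    scored = score_candidates(search.candidates, residual, resolution)
    ordered = rank_by_ccc(scored)
    return FitResult(gap, ordered, search.stage_counts, resolution=resolution,
                     box_shape=residual.shape)


# ---------------------------------------------------------------------------
# Export

def _grafted_structure(result: FitResult, cand: ScoredCandidate) -> Structure:
    gap = result.gap
    st = gap.structure.copy()
    chain = st.chain(gap.chain_id)
    i_n = chain.index_of(gap.nstem_residue)
    i_c = chain.index_of(gap.cstem_residue)
    by_res = cand.placed_coords.group_by_residue()
    nstem_number = chain.residues[i_n].number
    new_residues = []
    for k in sorted(by_res):
        new_residues.append(Residue(
            number=nstem_number + 1 + k,
            amino_acid=gap.query_sequence[k],
            atoms={name: np.asarray(xyz) for name, xyz in by_res[k].items()},
        ))
    chain.residues = chain.residues[:i_n + 1] + new_residues + chain.residues[i_c:]
    return st


def export_models(result: FitResult, k: int = 5, out_dir=".") -> list[Path]:
    """Write the top-k grafted models as PDB files plus a TSV of all scores.

    Filenames encode the density-fit rank and the fragment id. Asking for
    more models than available writes all of them.
    """
    if not result.candidates:
        raise ValueError("cannot export from an empty result")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    n_models = min(k, len(result.candidates))
    for cand in result.candidates[:n_models]:
        path = out_dir / f"model_rank{cand.fragfit_rank:03d}_frag{cand.fragment_id}.pdb"
        write_structure(_grafted_structure(result, cand), path)
        written.append(path)
    tsv_path = out_dir / "scores.tsv"
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["fragfit_rank", "fragsearch_rank", "fragment_id",
                         "ccc", "stem_rmsd", "seq_sim", "fp_dev"])
        for cand in result.candidates:
            writer.writerow([
                cand.fragfit_rank, cand.fragsearch_rank, cand.fragment_id,
                f"{cand.ccc:.6f}" if cand.ccc is not None else "",
                f"{cand.stem_rmsd:.6f}",
                f"{cand.seq_similarity:.6f}",
                f"{cand.fp_deviation:.6f}",
            ])
    written.append(tsv_path)
    return written
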