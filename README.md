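# fragfit

Fragment-based modeling of missing protein segments into cryo-EM density
maps.

Cryo-EM structures routinely contain gaps: flexible loops, linkers and
hinge regions whose density is too weak or too ambiguous for automatic
chain tracing. `fragfit` closes such gaps with backbone fragments harvested
from known structures, using the density map itself as the deciding
restraint. It is aimed at structural biologists finishing cryo-EM models
and at method developers who want a compact, fully testable implementation
of the classical two-step search-then-score strategy.

## Method

Given a structure with a gap of *L* residues between two **stem residues**,
the query sequence of the gap, a density map and its nominal resolution:

1. **Fragment database.** All overlapping backbone fragments of 3–35
   residues are extracted from a set of input structures and stored in a
   single indexed file together with their sequence and a **geometric
   fingerprint** of the two terminal (stem) residues: the CA–CA distance
   *d* and three angles (θₙ, θ꜀, φ) fixing their relative orientation. A
   gap of *L* residues is served by fragments of *L* + 2 residues, whose
   terminal residues are superposed onto the stems.

2. **Hierarchical geometric search** (the candidate generator):
   - stage 1: fragments with the right length and |Δd| < 0.75 Å;
   - stage 2: rank by stem RMSD after least-squares superposition of the
     terminal residues onto the stems (Kabsch), keep the top 1000;
   - stage 3: discard candidates clashing with the modeled context
     (heavy-atom distance < 2 Å) and redundant conformers (identical
     sequence, or placed-backbone RMSD < 0.5 Å);
   - stage 4: re-rank by sequence similarity (normalized BLOSUM62) and
     fingerprint match, keep the top 100.

3. **Density re-scoring** (the selector). A minimal sub-box guaranteed to
   contain any placement of the segment (the prolate spheroid of chain
   reach 3.8·(L+1) Å with foci at the stem CAs) is cut from the map,
   normalized to mean 0 / SD 1, and the simulated density of the already
   modeled atoms inside it is subtracted. Each shortlisted candidate is
   converted into a simulated map on the same grid (unit-weight atom
   deposition, Butterworth low-pass H(f) = (1 + (f/f_c)^{2n})^{-1/2} at the
   map's resolution) and scored by the Pearson cross-correlation
   coefficient (CCC) against the residual. The shortlist is re-ordered by
   descending CCC; re-scoring never changes the candidate set.

Model quality is measured by backbone RMSD in the stem-anchored frame,
RMSD = √(1/N · Σᵢ |Xᵢ − Yᵢ|²), and by the simplified identical-length
TM-score, TM = 1/L · Σᵢ 1/(1 + dᵢ²/d₀²) with d₀(L) = 1.24·(L−15)^⅓ − 1.8
(floored at 0.5 Å), over CA atoms. ΔRMSD = RMSD(geometric top hit) −
RMSD(density-rescored top hit) quantifies the gain from the map.

## Worked example

Everything below runs from synthetic fixtures — no downloads. A 9-residue
loop gap is modeled against an 8 Å simulated map, with the native fragment
excluded by the >90 % sequence-identity rule so the answer must come from
inexact (decoy) candidates:

```python
from fragfit import run_fragfit
from fragfit.synthetic_fixtures import (FixtureSpec, build_toy_protein_set,
                                        build_mini_db, make_experimental_map,
                                        make_toy_gap)
from fragfit.validation import evaluate_fit

toys = build_toy_protein_set(FixtureSpec(seed=5))
structure, gap = make_toy_gap("loop", 9, seed=3)
db = build_mini_db(toys, gap, include_native=True, n_decoys=20, seed=13)
exp_map = make_experimental_map(structure, resolution=8.0)
result = run_fragfit(gap, db, exp_map, resolution=8.0, benchmark_mode=True)

print(f"candidates scored: {len(result.candidates)}")
for cand in result.candidates[:3]:
    print(f"rank {cand.fragfit_rank}: id={cand.fragment_id} "
          f"ccc={cand.ccc:.3f} stem_rmsd={cand.stem_rmsd:.3f} "
          f"seq_sim={cand.seq_similarity:.2f}")
metrics = evaluate_fit(result, gap)
print(f"top-1 backbone RMSD to native: {metrics['rmsd_fragfit_top1']:.2f} A")
print(f"geometric-search top-1 RMSD:   {metrics['rmsd_fragsearch_top1']:.2f} A")
print(f"delta RMSD (gain from map):    {metrics['delta_rmsd']:.2f} A")
```

Output:

```
candidates scored: 9
rank 1: id=1009 ccc=0.947 stem_rmsd=0.000 seq_sim=0.61
rank 2: id=996 ccc=0.947 stem_rmsd=0.000 seq_sim=0.60
rank 3: id=1005 ccc=0.945 stem_rmsd=0.000 seq_sim=0.55
top-1 backbone RMSD to native: 0.45 A
geometric-search top-1 RMSD:   3.14 A
delta RMSD (gain from map):    2.69 A
```

The geometric search alone — which here must rank by sequence similarity,
since all decoys share the gap's stem geometry — picks a 3.1 Å-wrong
conformer; density re-scoring recovers a 0.45 Å model, a ΔRMSD gain of
2.7 Å. The same workflow is available from the shell via the `fragfit` CLI
(`fragfit build-db`, `fragfit search`, `fragfit fit`, `fragfit benchmark`,
`fragfit sweep`, `fragfit fixtures`; see `fragfit --help`).

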