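# Methods

This note documents the model behind `fragfit`, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
demonstrate.

## Gap model and stem convention

A gap is the stretch of *L* residues strictly between two stem residues of
one chain (3 ≤ L ≤ 35). One stem residue per side is used; its backbone
atoms N, CA, C — plus O when present on both sides — anchor all placement.
Database fragments carry their own terminal residues as stems: a fragment
of length *L* + 2 serves a gap of length *L*, its terminals are superposed
onto the gap stems and its interior fills the gap. All public length
parameters refer to the full fragment length; the CLI help restates the
L ↔ L+2 relation.

## Geometric fingerprint

The fingerprint condenses the relative pose of the two stems into four
rigid-motion-invariant numbers computed from N/CA/C only:

| field | definition | role |
|---|---|---|
| d | CA(n-stem)–CA(c-stem) distance | stage-1 hard screen, |Δd| < 0.75 Å strict |
| θₙ | angle of the n-stem CA→C bond to the stem–stem axis | orientation |
| θ꜀ | angle of the c-stem CA→N bond to the reversed axis | orientation |
| φ | torsion C(n)–CA(n)–CA(c)–N(c), in (−180°, 180°] | relative twist |

d plus the three angles fix the relative pose of the two stem frames up to
the bond directions that the peptide itself constrains, so two stem pairs
with equal fingerprints are superposable — which is the property the
stage-1/stage-4 screens rely on. The fingerprint *deviation* used for
re-ranking normalizes each term so that the hard distance threshold
(0.75 Å) and a 30° angular deviation each contribute one unit; the torsion
difference is taken on the circle. The deviation enters the stage-4 score
through x/(1+x), a cohort-independent squashing to [0, 1), combined with
the normalized BLOSUM62 sequence similarity at equal weights (both weights
are exposed in `SearchParams`).

Sequence similarity is the per-position BLOSUM62 score, min-max normalized
between the matrix's global minimum and the mean of the two residues'
self-scores, averaged over positions: symmetric, in [0, 1], and exactly 1
for identical sequences.

## Search-stage parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| Δd window | 0.75 | Å | strict (<) stem-distance screen |
| pool size | 1000 | — | stage-2 truncation by stem RMSD |
| shortlist | 100 | — | stage-4 truncation by combined score |
| clash cutoff | 2.0 | Å | conservative heavy-atom contact for backbone-only models |
| redundancy RMSD | 0.5 | Å | strict (<) fold-identity deletion; the copy with the lower stem RMSD survives |
| identity cutoff | 0.90 | fraction | benchmark mode only; strictly-greater identities removed |

Ties are broken deterministically by (score, stem RMSD, fragment id), so
results are invariant to database record order. The clash check precedes
redundancy deletion; the clash context excludes the stems themselves (the
fragment terminals overlay them by construction) and the modeled span.

## Density pipeline

Simulated maps deposit unit weight per heavy atom by trilinear splatting
and are low-pass filtered in Fourier space with a Butterworth filter,
H(f) = (1 + (f/f_c)^{2n})^{-1/2}, f_c = 1/resolution, order n = 8 by
default. H(0) = 1, so filtering conserves total mass; the gain at the
cutoff is exactly 2^{-1/2}. Element-dependent weighting and B-factors are
deliberately out of scope: at the resolutions where fragment re-scoring is
useful (≳ 4 Å) the shape of the backbone envelope dominates the CCC.

The minimal sub-box is the axis-aligned bounding box of the prolate
spheroid { p : |p − a| + |p − b| ≤ 3.8·(L+1) } with foci a, b at the stem
CA atoms — 3.8 Å being the CA–CA virtual bond, so the spheroid contains
every stereochemically possible placement of the segment — expanded by a
padding that defaults to the map resolution and clipped to map bounds.
Preprocessing then normalizes the box to mean 0 / SD 1, simulates the
density of the context atoms inside the box on the same grid, normalizes
that too, and subtracts it. Both volumes are normalized before
subtraction; scoring against the unsubtracted box is available as an
ablation flag. Candidate CCCs are computed over the full box without a
mask; a candidate whose atoms all fall outside the box scores −1 and is
flagged. Maps with anisotropic voxels are rejected rather than silently
resampled.

## Quality metrics

Backbone RMSD is computed in the frame fixed by the stem superposition; no
re-fitting happens inside the metric, so junction errors propagate into
the score, as intended for gap modeling. The TM-score uses the simplified
identical-length form over CA atoms with the standard scale
d₀(L) = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å (d₀ is a parameter).
Secondary-structure classes for benchmark labeling come from a φ/ψ
classifier (helix: φ ∈ [−100, −30], ψ ∈ [−80, −5], runs ≥ 4; strand:
φ ∈ [−180, −80], ψ ∈ [80, 180], runs ≥ 3; everything else loop, which
therefore absorbs 3₁₀/π irregularities). An external DSSP can be
substituted upstream where available; the classifier only labels rows, it
never participates in search or scoring.

## Synthetic fixtures: what they emulate, what they do not

Toy proteins are built from ideal internal coordinates (NeRF chain
extension; trans peptide, standard bond lengths/angles) with canonical
torsions — helix −57°/−47°, strand −120°/+120° with a ±10° pleat
alternation, loops drawn from the broad coil region with self-avoidance
retries — giving complete N/CA/C/O backbones that are clash-free by
construction. Decoy fragments perturb the native interior with isotropic
Gaussian noise (SD drawn from 0.25–2.5 Å per decoy) while keeping the
terminal residues bitwise fixed, so every decoy passes the stage-1
geometric screen exactly and discrimination falls to sequence and density;
decoy sequences are mutated at ≥ half their positions so the >90 %
identity rule never removes them. Perturbed interiors are *not*
re-regularized to ideal bond geometry.

Fixture "experimental" maps are simulated maps (voxel size resolution/4,
clamped to 1–3 Å) with optional i.i.d. Gaussian voxel noise at a declared
SNR. Real cryo-EM maps have structured, spatially varying noise,
fragmentation and local resolution variation, none of which the fixtures
emulate — so passing tests demonstrate the correctness and the ranking
behavior of the pipeline, not absolute accuracy on experimental data.
Benchmarks in this repository run at desk scale (tens of gaps, databases
of ~10³ fragments); a production database built from the full PDB is
supported by the same `build_db` code path but is not exercised here, and
the problem sizes used by the test suite and the acceptance script (24
gaps at 8 Å; an 11-window sweep over 4–20 Å) were chosen as the smallest
sets that exercise all three secondary-structure classes and four segment
lengths.

## Numerical choices and degenerate inputs

- Superposition is Kabsch via SVD with the proper-rotation sign
  correction; collinear or <3-point inputs raise. Verified against an
  independent quaternion (Horn) implementation to 1e-9.
- Strict inequalities at every printed threshold (0.75 Å, 0.5 Å, 90 %);
  the sqlite range query is re-checked in Python so index arithmetic can
  never widen a boundary.
- Torsions use the atan2 formulation; the φ = ±180° seam is mapped to
  +180° and angular differences are taken on the circle.
- Normalization refuses constant volumes; CCC refuses zero-variance
  volumes and mismatched grids.
- Grafting with adjacent stems (pure insertion) is legal; the native
  segment is then undefined and benchmark rows are skipped.

## Known limitations

- No loop-closure refinement: grafted junctions inherit the fragment's
  terminal geometry and may carry small distortions; downstream real-space
  refinement is assumed.
- No side chains, hydrogens, symmetry mates or multi-chain clash context
  beyond the atoms the caller supplies.
- CCC discrimination fades when the map cannot resolve the difference
  between candidates: conformers within ~1 Å backbone RMSD are
  indistinguishable at 8 Å, and at 20 Å the gain for short segments drops
  toward zero — the resolution sweep quantifies exactly this.
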