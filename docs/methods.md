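# Methods

## Model

A protein chain's surface is modeled as a labeled point set: the Cα
positions and residue types of its surface residues. Every surface residue
centers one circular patch containing all surface residues whose Cα lies
within a Euclidean distance τ_p of the center's Cα. The patch is
summarized by a (20+1)×(b+1) count matrix: rows are the 20 residue types,
columns are b uniform distance bins over (0, τ_p]; the extra row is the
column marginal **sum C** (the patch's distance histogram), the extra
column the row marginal **sum R** (its residue co-occurrence counts).

The chain-level (global) descriptor averages, per central residue type,
the normalized marginals over that type's patches — an empirical estimate
of Pr{d | R_c} and Pr{R_i | R_c}. Four vector views are defined: DD1
(pooled distance distribution, b entries), DD2 (20 distance blocks, 20·b),
RC (20 co-occurrence blocks, 400), DRC (distance and co-occurrence blocks
interleaved per type, 20·(b+20)). Residue-type blocks are laid out in
one-letter alphabetical order. Chains are compared by the Euclidean
distance between same-scheme vectors.

Assumptions: one chain is one surface (multi-chain assemblies are
processed chain by chain); distances are Euclidean Cα–Cα, not geodesic
along the surface; a uniform binning of distances is an adequate density
estimate at the default b.

## Parameters

| parameter | default | units | role |
|-----------|---------|-------|------|
| τ_p | 10 | Å | patch radius; sets the spatial scale of "local" context |
| b | 5 | — | distance bins per patch; fixes descriptor dimensionality |
| probe radius | 1.4 | Å | solvent probe for surface generation / SASA |
| rel. SASA threshold | 0.05 | — | fallback surface-membership cutoff |
| pooling | per_patch | — | how patch statistics combine into a global block |

The τ_p, b and probe defaults are the method's standard operating point.
The SASA threshold of 0.05 relative accessibility is a conventional
surface/buried cutoff; the SASA fallback uses a fixed 960-point Fibonacci
sphere lattice so results are bit-reproducible.

## Numerical choices

- **Bins.** Bin j covers [(j−1)·τ_p/b, j·τ_p/b), except the last bin,
  which is closed at τ_p, so a member at exactly τ_p is counted.
- **Center exclusion.** The central residue is not a member of its own
  patch: its self-distance of zero would add a constant, information-free
  count to the first bin of every patch.
- **Normalize-then-average.** Each non-empty patch's marginals are
  normalized to probability vectors before averaging (`pooling =
  "per_patch"`), so every patch contributes equally regardless of how
  dense its neighborhood is. The alternative — summing raw counts per
  central type and normalizing once (`"pooled"`) — weights patches by
  member count and is available behind the same interface; all shipped
  results use the default.
- **Empty patches** (no neighbor within τ_p) are kept in the patch list
  but skipped in averaging, since their normalization is undefined; their
  count is recorded on the global descriptor. A residue type never
  observed as a non-empty patch center carries all-zero blocks.
- **Ties in ranking** are broken by (structure id, chain id), making
  rankings deterministic; self-hits stay in the ranking at rank 1 (an
  evaluation flag can drop them).
- **Enrichment** at screening fraction f retrieves the top ⌈f·N⌉ hits.
- **PR AUC** is a trapezoid over recall-sorted (recall, precision) points
  with (0, first precision) prepended; points tied in recall keep rank
  order. Recall uses the min{rank, group size} denominator, so a perfect
  prefix of same-group hits scores recall 1 at every rank. Averaging over
  queries is pointwise by rank and requires equal database sizes.
- **Surface membership from a dot surface**: a vertex is owned by its
  nearest atom (the vertex file's nearest-atom index when present, else a
  KD-tree search), and a residue is on the surface iff it owns at least
  one vertex. This rule is parameter-free; whether surface programs'
  annotations or an all-atom search is used makes no difference on the
  shipped fixtures, where both paths are tested.
- **Structure reading**: first model only; alternate locations resolve to
  the highest-occupancy conformer, ties to the lexicographically first
  altloc; selenomethionine, selenocysteine and pyrrolysine map to M, C, K;
  other non-canonical residues, waters and ligands are dropped; residues
  without a Cα are dropped with a warning. Parsed coordinates are rounded
  back to the PDB format's 3 decimals, which undoes the parser's float32
  storage losslessly and makes write/read round-trips exact.

## Classifiers

Classification rates are produced by standard scikit-learn classifiers
with fixed hyperparameters: Gaussian naive Bayes; `logistic` = multinomial
logistic regression with weak L2 (C = 100, lbfgs, max_iter 2000);
`simple_logistic` = the same with C = 1. The latter approximates the
LogitBoost-based "simple logistic" classifier found in older ML suites,
which has no exact counterpart here; no equivalence is claimed. Splits are
stratified by family so small training draws cannot lose a class.

## The synthetic benchmark

`synthetic_fixtures` generates labeled chains on a jittered spherical
shell (radius 16 Å, jitter 1.2 Å, 60–90 residues), so every residue is a
surface residue by construction and descriptor logic is isolated from
surface-selection logic. The default benchmark has three families sharing
this geometry and differing in three respects:

1. **Composition tilt** — each family's three signature residue types are
   4× upweighted over a uniform background.
2. **Co-occurrence boosts** — each family preferentially places a partner
   of a designated type within patch range of a signature residue
   (strength 4, at a family-characteristic distance band).
3. **Signature clustering** — signature-type residues congregate in a
   tight spherical cap (angular spread 0.2 rad, probability 0.8).

The clustering term exists because per-patch normalization makes the
distance blocks shape-only: on a shell of uniform density, the distance
distribution around any center has the same shape regardless of type, and
the type-conditional distributions (DD2) degenerate to the pooled baseline
(DD1). Type-specific clustering changes the shape around signature
centers specifically, which DD2 sees at full strength and DD1 only diluted
by the squared clustered fraction — reproducing the characteristic
ordering DD1 < DD2 < {RC, DRC} that the descriptor family shows on real
protein families.

What the generator does **not** emulate: backbone connectivity and
realistic Cα spacing, side chains, true Connolly geometry with pockets and
clefts, buried residues (the SASA and vertex-ownership paths are instead
tested on separately constructed burial fixtures), and the label noise of
real family assignments. Passing benchmarks on this data therefore
demonstrates that the implementation is correct and that the descriptors
separate families whose signal lies in surface composition, co-occurrence
and type-specific clustering — not that any particular accuracy carries
over to real structure databases.

Benchmark problem sizes were chosen to keep the full suite fast on a
laptop: 3 families × 50 chains for classification (train 50 / test 100,
10 splits) and retrieval (6 queries per scheme), 51 chains of ≤ 60
residues for brute-force equivalence, 20 chains × 10 transforms for the
invariance sweep.

## Known limitations

- Surfaces are treated chain-by-chain; interfaces buried in an assembly
  are still "surface" for the isolated chain.
- The descriptor discards which residue pairs realize a distance beyond
  the 20-type co-occurrence level; two different neighborhoods can share a
  descriptor (the representation is lossy by design).
- The SASA fallback is a residue-level approximation to a Connolly
  surface; near the 0.05 threshold the two surface definitions can
  disagree on individual residues.
- Euclidean matching weights every coordinate equally; no feature scaling
  or alternative metrics are provided.
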