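# surfpatch

Rotation-invariant descriptors of protein surfaces, for fast retrieval and
functional classification of protein chains without structural alignment.

## The problem and the method

Two proteins with similar function often present similar surfaces even when
their sequences have diverged, but comparing 3D surfaces directly requires
expensive alignment. `surfpatch` sidesteps alignment by summarizing a
chain's surface as a fixed-length statistical descriptor that is invariant
to rotation, translation and mirroring.

The pipeline:

1. **Surface residues.** A chain is reduced to the residues on its
   molecular surface, each kept as its residue type plus Cα coordinate.
   Surface membership comes either from an external Connolly dot surface
   (an MSMS-style `.vert` file: a residue is on the surface iff it owns at
   least one surface vertex by nearest-atom assignment) or, with no
   external program, from a built-in Shrake–Rupley relative-SASA filter
   (probe radius 1.4 Å).
2. **Patches.** Every surface residue centers one circular patch: all
   surface residues whose Cα lies within τ_p = 10 Å of its Cα.
3. **Local descriptor.** Each patch is summarized in a (20+1)×(b+1) matrix
   `D_A` (b = 5 distance bins over (0, τ_p]): 20 rows of residue-type ×
   distance-bin counts, a marginal row **sum C** (the patch's distance
   distribution) and a marginal column **sum R** (its residue
   co-occurrence counts).
4. **Global descriptor.** Per central residue type R_c, the normalized
   marginals are averaged over all patches centered on that type, giving
   estimates of Pr{d | R_c} and Pr{R_i | R_c}. Four flat views are used
   for matching, all independent of chain size:

   | scheme | content | length (b = 5) |
   |--------|---------|----------------|
   | DD1 | pooled distance distribution, center type ignored | 5 |
   | DD2 | 20 blocks of Pr{d \| R_c} | 100 |
   | RC  | 20 blocks of Pr{R_i \| R_c} | 400 |
   | DRC | per type, distance block ∘ co-occurrence block | 500 |

5. **Matching.** Chains are compared by the plain Euclidean distance
   D₁₂ = √Σᵢ[D₁(i) − D₂(i)]² between descriptor vectors; a database is
   ranked by ascending distance. Retrieval is scored with the enrichment
   factor N_obs/N_exp at a screening fraction and with precision/recall
   (recall denominator min{rank, query group size}); classification uses
   standard classifiers (naive Bayes, logistic regression) on the vectors.

Because real benchmark families require downloading hundreds of PDB chains
and running a surface program, the package ships a synthetic generator:
labeled residue point clouds on a jittered spherical shell with
controllable composition, residue co-occurrence structure and
signature-type clustering, written out as valid toy PDB/vert files.

## Worked example

```python
import numpy as np
from surfpatch import (default_family_specs, generate_family_dataset,
                       chain_vector, rank_database)
from surfpatch.matching_retrieval import build_database, precision_recall

chains, labels = generate_family_dataset(default_family_specs(),
                                         chains_per_family=10, seed=1)
db = build_database(chains, "drc", labels)          # 30 chains, DRC scheme
query = chains[0]
qvec = chain_vector(query, "drc")                   # length-500 vector
ranked = rank_database(qvec, db, query_id=query.structure_id)
for h in ranked.hits[:3]:
    print(h.structure_id, h.chain_id, h.rank, round(h.distance, 4))
ev = precision_recall(ranked, labels, labels[(query.structure_id, "A")])
print("PR AUC:", round(ev.auc, 4), " EF@10%:", dict(ev.enrichment)[0.10])
```

prints

```
F0C000 A 1 0.0
F0C009 A 2 2.525
F0C001 A 3 2.7184
PR AUC: 0.751  EF@10%: 3.0
```

The query chain matches itself at distance exactly 0 and rank 1; the next
hits are chains from the same synthetic family. The 3-fold enrichment in
the top 10% of the 30-chain screen is the maximum possible with 3 equal
families, and the precision-recall AUC of 0.751 reflects a ranking whose
top is dominated by same-family chains.

The same workflows are available from the shell:

```bash
surfpatch make-fixtures --out data --chains-per-family 5 --seed 7
surfpatch build-db data/*.pdb --labels data/labels.tsv --scheme rc --out db.json
surfpatch rank data/F0C000.pdb db.json --scheme rc --out ranked.tsv
surfpatch evaluate db.json --out metrics.csv
surfpatch classify db.json --n-train 5 --n-test 5 --out rates.csv
```

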