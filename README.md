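# lexitree

Lexical distance matrices, neighbor-joining and generalized tree-comparison
scores for language phylogenetics.

## The problem

Distance-based phylogenetics reconstructs a binary tree of languages from
Swadesh-style word lists. Evaluating such a reconstruction against an
expert catalogue (an Ethnologue-style classification) runs into a
structural mismatch: expert classifications are full of polytomies —
internal nodes whose sub-grouping is deliberately left unresolved — while
inferred trees are fully binary. The standard Robinson-Foulds (RF) and
quartet (QD) distances count every extra edge of the binary tree as an
error even when it merely *refines* the classification.

`lexitree` implements the two asymmetric scores that remove this bias,
together with everything needed around them:

* **word distances** — Levenshtein distance, its length-normalized form
  LDN(α_i, β_i) = LD/max(|α_i|, |β_i|), the language-level LDN (mean over
  shared meanings) and LDND (LDN divided by the mean cross-meaning distance
  over ordered pairs i ≠ j, correcting for chance orthographic similarity);
* **tree scores** — normalized RF and QD, and the generalizations
  GRF(T_E, T_I) = 1 − |compatible splits of T_I| / |E(T_I)| (compatibility
  via the four-subset rule B₁⊆E₁ ∨ B₁⊆E₂ ∨ B₂⊆E₁ ∨ B₂⊆E₂ against every
  reference split E₁|E₂) and GQD(T_E, T_I) = d / B(T_E), the conflicting
  butterflies over the reference's butterfly quartets. Both are exactly 0
  whenever the inferred tree refines the reference;
* **inference** — classic neighbor-joining (exact on additive matrices,
  deterministic tie-breaking) and a plug-in loader for externally inferred
  trees;
* **evaluation** — random-binary-tree null model, the normalized accuracy
  A = max(0, 1 − 2·GQD/⟨GQD_rand⟩), per-group mean/variance aggregation,
  and completeness/coverage diagnostics (attestation fractions f and g,
  effective list size N_eff = Σf_i, coverage = mean pairwise co-attestation);
* **synthetic families** — a two-level replacement/drift generator with a
  known true tree and a degradable (polytomized) reference, so the whole
  pipeline is testable without redistributable databases.

## Worked example

```python
import lexitree as lt

# an expert classification with one unresolved 3-way group,
# and two candidate reconstructions
reference = lt.parse_newick("((a,b),(c,d,e));")
refining  = lt.parse_newick("((a,b),((c,d),e));")   # resolves the polytomy
conflict  = lt.parse_newick("((a,c),((b,d),e));")   # moves b and c around

for name, tree in [("refining", refining), ("conflict", conflict)]:
    print(name,
          "rf=%.3f" % lt.rf_distance(reference, tree),
          "grf=%.3f" % lt.grf_score(reference, tree),
          "gqd=%.3f" % lt.gqd_score(reference, tree))
```

prints

```
refining rf=0.333 grf=0.000 gqd=0.000
conflict rf=1.000 grf=1.000 gqd=1.000
```

The standard RF penalizes the refining tree (0.333) for the one edge the
classification does not contain; the generalized scores correctly give it a
null error, while the genuinely conflicting tree contradicts every
reference split and every one of the reference's three butterfly quartets.

The same machinery drives the CLI end to end:

```sh
lexitree simulate --out-dir fam --seed 3 --low-noise
lexitree dist --input fam/wordlist.tsv --method ldnd --out fam/dm.phy
lexitree infer --matrix fam/dm.phy --out fam/nj.nwk
lexitree score --reference fam/reference.nwk --inferred fam/nj.nwk \
    --scores grf,gqd,rf,qd
```

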