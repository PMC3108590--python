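# Methods

This note records the models, conventions and numerical choices behind
`lexitree`, and what the synthetic validation does and does not show.

## Lexical distances

Words are compared as sequences of Unicode code points with the plain
Levenshtein distance (unit-cost insertion, deletion, substitution); no
sound-class weighting or alignment scoring is applied. The word-level
distance is length-normalized, `LDN(a, b) = LD(a, b) / max(|a|, |b|)`, so
long and short words weigh equally.

Language-level distances:

* **LDN** between two lexicons is the mean word-level LDN over the
  meanings attested in *both* — missing meanings simply drop out of the
  average, keeping the estimate on the pair's common support.
* **LDND** divides LDN by the cross-meaning normalizer: the mean LDN over
  all ordered pairs (i, j), i ≠ j, of different meanings drawn from the
  same shared-meaning set. The normalizer estimates the chance similarity
  of the two orthographies; LDND ≈ 1 for unrelated languages and may
  exceed 1. Because word-level LDN is symmetric, averaging over ordered or
  unordered cross pairs gives identical values (tested); ordered pairs are
  used. A zero normalizer (all shared words identical across meanings) is
  a degenerate input and raises an error rather than returning infinity.

**Synonyms.** Word lists may carry several transcriptions per meaning. The
default rule `first` uses the first listed word — deterministic, and
identical to the single-word case on single-word lists. The alternative
`min` (minimum LDN over synonym cross pairs) is available by flag; which
convention databases use in practice varies, so both are exposed.

## Tree scores

All scores operate on the unrooted interpretation of the trees: the
objects compared are non-trivial bipartitions (splits) and induced
four-leaf (quartet) topologies. A degree-2 root is transparent.

* **RF** (normalized): `(|E1| + |E2| − 2·shared) / (|E1| + |E2|)` over
  non-trivial splits. Two star trees, having no splits at all, are at
  distance 0 by convention.
* **QD** (normalized): the fraction of the C(n,4) quartets whose induced
  topologies differ, computed from the butterfly census
  `(B1 + B2 − 2s − d) / C(n,4)`.
* **GRF(reference, inferred)**: 1 minus the fraction of the *inferred*
  tree's splits compatible with the reference, compatibility being the
  four-subset rule (for every reference split E1|E2, one of B1⊆E1, B1⊆E2,
  B2⊆E1, B2⊆E2). The denominator counts the inferred tree's internal
  edges: this orientation guarantees that refinement edges are never
  errors, which is the entire point of the generalization. An inferred
  *star* has no edges to judge and raises an error rather than scoring a
  perfect 0 — an uninformative reconstruction must not be rewarded.
* **GQD(reference, inferred)**: conflicting butterflies `d` divided by the
  reference's butterfly count B(reference). Reference star quartets are
  never errors; a fully unresolved reference gives GQD = 0 by convention.

When both trees are binary, GRF coincides with normalized RF and GQD with
the conflicting-quartet fraction d / C(n,4) (asserted on random pairs).

The quartet census is an exhaustive O(n⁴) enumeration, vectorized over
numpy boolean membership tables (one pass per split, first resolving split
wins — valid because the splits of one tree are pairwise compatible). This
is comfortably fast to n ≈ 200; sub-quadratic algorithms are out of scope,
and any optimized census must be validated against the exhaustive one.

## Random null and normalized accuracy

The null model draws fully resolved topologies by uniform random
sequential pair-joining of lineages (coalescent-style), seed-controlled;
on 4 taxa this is exactly uniform over the three topologies (tested). The
null summary reports mean and variance of GRF/GQD over R replicates
(default R = 10, configurable), with replicate seeds derived
deterministically from (seed, index).

Normalized accuracy is `A = max(0, min(1, 1 − 2·GQD/⟨GQD_rand⟩))`. The
factor 2 is a visualization stretch: A = 0 already at half the random
distance. When ⟨GQD_rand⟩ = 0 (star reference) accuracy is undefined and a
distinct `UNRESOLVED` sentinel is returned — deliberately not a number, so
it cannot silently enter averages. These constants are this package's
documented convention; figure scales elsewhere need not match exactly.

Group aggregation uses population variance (ddof = 0) by default,
switchable to sample variance.

## Neighbor-joining

Classic NJ with the Q-criterion `(m−2)d_ij − r_i − r_j`. Ties are broken
by the lexicographically smallest label pair, each cluster keyed by the
smallest leaf label it contains — determinism across platforms. Negative
branch lengths are clamped to zero with the deficit transferred to the
sibling branch (the pair's total length is preserved); scores depend on
topology only, so clamping affects output trees, not metrics. On additive
matrices NJ recovers topology and branch lengths exactly (asserted to
1e-9 on random additive instances up to n = 20). FastME-style balanced
minimum evolution and stochastic local search are not reimplemented;
externally produced Newick trees enter the same scoring pipeline through
`load_external_tree`.

## Synthetic families

The generator produces a random binary true tree with i.i.d. branch
lengths, evolves one word per meaning from a random root lexicon, then
degrades the data and the reference:

* per-meaning replacement rates drawn once per family (default
  log-uniform over [0.01, 1] per unit branch length) — along a branch of
  length t the word is replaced by a fresh random string with probability
  1 − exp(−rate·t), modelling lexical turnover with meaning-dependent
  speed;
* surviving words mutate each character independently with probability
  1 − exp(−μ·t) (default μ = 0.1), modelling gradual form change;
* each (language, meaning) entry is kept with the attestation probability
  (default 0.9), emulating database gaps;
* the reference classification contracts each internal edge of the true
  tree with the collapse probability (default 0.5), so every surviving
  reference split is a true split and the true tree always refines the
  reference.

Defaults model a mid-sized family: 20 languages, 40 meanings, 5-character
words over a 20-symbol alphabet, unit-mean exponential branch lengths.

**Low-noise preset.** `SimulationConfig.low_noise()` is the regime in
which distance-based recovery should be near-exact: replacement rates
log-uniform over [1e-3, 1e-2], μ = 0.1, full attestation, and branch
lengths uniform on [0.15, 0.45] instead of exponential. The uniform law is
essential, not cosmetic: a 40-meaning, 5-character list carries only ~200
characters of signal, so an exponentially short branch records no change
at all (its split becomes unrecoverable in principle) while exponentially
long paths push pairwise LDN into saturation where distances stop being
additive. The narrow uniform law gives every branch ≥ 3 expected character
changes and keeps the deepest leaf-to-leaf divergence in the near-linear
range. Under this preset NJ+LDN recovers the true tree with mean GRF ≈
0.01 over 20 families.

**What passing tests show — and don't.** The generator realizes
meaning-dependent turnover, incomplete attestation and unresolved
references, which are the structural features the scores and diagnostics
are designed around. It does not simulate borrowing (horizontal
transfer), sound change with phonological structure, synonym dynamics, or
correlated attestation gaps; results on synthetic families therefore
validate the machinery, not the historical-linguistics conclusions one
would draw from real databases.

## Problem sizes

The shipped test-suite and acceptance-script runs use: quartet-oracle
cross-checks at n ≤ 12 (100 pairs), refinement checks at n ≤ 30 (50
trees), NJ additivity at n ≤ 20 (200 matrices in the suite, 50 in the
script), and synthetic surveys of 12–20 families of 20 languages × 40
meanings. These sizes make every statistic stable at the asserted
tolerances while the full suite runs in well under a minute.

## Degenerate inputs and conventions (summary)

| situation | behaviour |
|---|---|
| LDN of two empty strings | error |
| no shared meanings between two lexicons | `NoOverlapError`, offending pair named |
| < 2 shared meanings, or zero cross-meaning normalizer | `DegenerateNormalizerError` |
| RF of two star trees | 0 |
| GRF with star reference | 0 (vacuous compatibility) |
| GRF with star inferred tree | `UndefinedScoreError` |
| GQD with star reference | 0 |
| normalized accuracy with zero null mean | `UNRESOLVED` sentinel |
| completeness curve at an N where a pair loses all overlap | row kept, scores NaN |
| negative NJ branch length | clamped to 0, deficit moved to sibling |
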