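# Methods

## The fingerprint

A molecule's fingerprint is a vector of 39 non-negative integers, one per
substructure key of the default registry. Entry *i* is the number of
*distinct atom sets* in the molecule matching key *i*'s pattern:

- Matches that map the same atom set under a pattern automorphism count
  once (a six-carbon-ring pattern matches benzene once, not twelve times —
  one per ordered ring walk).
- Different placements of the same key, and placements of different keys,
  may share atoms freely. Overlap is intentional: biosynthetic building
  blocks overlap in real scaffolds (an acetate unit can sit inside an
  isoprene unit's atoms).

### Key registry

The registry is data, not code: a versioned JSON file
(`src/biosynkey/data/registry.json`) with columns name, group, pathway,
raw SMARTS and a building-block flag, so patterns can be swapped without
code changes. The roster covers:

| block | keys | pathway |
|---|---|---|
| fundamental building blocks (8) | indole-C2N, C6C2N, C6C3, C6C1, C2 acetate, C5 isoprene, C3 pyruvate, C1 methyl | shikimate / acetate / terpenoid / carbohydrate / amino-acid |
| acetate units | malonyl C3 | acetate |
| sugars | pyranose, furanose, glycosidic (acetal) oxygen | carbohydrate |
| amino acids | 10 side-chain-specific keys + generic α-amino-acid backbone | amino-acid |
| decorations (14) | hydroxyl, carbonyl, carboxyl, primary amine, sulfur, phosphate, F/Cl/Br/I, 3-/4-/5-/6-membered carbocycles | none |
| helpers (2) | coenzyme-A thioester (pantetheine arm), purine nucleotide motif | none |

Key order is fixed — pathway blocks in the order shikimate, acetate,
terpenoid, carbohydrate, amino-acid, then decorations, then helpers;
within a block, descending pattern size, ties alphabetical — so fingerprint
indices are stable across runs and QR plots read as pathway blocks. The
individual SMARTS are this package's own concrete definitions of the named
building blocks; swapping in a different edition of any pattern is a
one-line data change.

The C1 methyl key is grouped with the amino-acid pathway (its biosynthetic
donor is S-adenosyl-methionine); the C3 pyruvate key with the carbohydrate
pathway (glycolysis). Amino acids keep their own annotation regardless of
their individual precursor pathways. Chirality is deliberately ignored
throughout — most large structure collections carry incomplete or
inconsistent stereo annotations.

### Bond-order relaxation

Patterns are authored as ordinary SMARTS and rewritten before matching:
every atom primitive becomes an element-only constraint (`C`, `c`,
`[CH3]` → `[#6]`) and every bond — explicit, implicit, or ring-closure —
becomes the any-bond connector `~`. The rewrite is a small tokenizer
(bracket atoms, two-letter elements, bonds, ring closures, branches, dots),
not string substitution, so bracket atoms and ring-closure digits survive.

Atoms authored in `[#n...]` form pass through verbatim. This is the escape
hatch for keys whose meaning *requires* more than an element: the methyl
key `[#6H3]`, hydroxyl `[#8H1]`, carbonyl oxygen `[#8D1H0]`, primary amine
`[#7H2]` and carboxyl are defined by hydrogen-count/degree constraints
rather than bond orders, because under bond-order relaxation an O–H count
is the only thing separating a hydroxyl from an ether or carbonyl oxygen.
A consequence worth stating: relaxation is idempotent on every registry
pattern (`relax(relax(s)) == relax(s)`), which the tests enforce.

### Atom coverage

Coverage is the fraction of heavy atoms appearing in at least one match of
at least one key; hydrogens are excluded from numerator and denominator.
It measures how much of a structure the key set "sees". Adding keys can
only increase it; removing keys can only decrease it.

### Occurrence and co-occurrence statistics

Per-key count distributions are summarised as mean/quartiles/max over a
molecule table. Co-occurrence uses pointwise mutual information on
binarised occurrence (count > 0), base-2 logarithm:
`PMI(i,j) = log2 p(i∧j) − log2 p(i)p(j)`, with probabilities estimated as
molecule fractions. Pairs with a zero marginal are undefined (NaN); pairs
with nonzero marginals that never co-occur are −∞ (masked in rendering);
the diagonal is −log2 p(i).

## Similarity

Counted fingerprints are compared with the multiset Tanimoto coefficient
Σmin/Σmax; binary fingerprints with the classical |A∩B|/|A∪B|. Two
conventions are fixed deliberately:

- **Both-zero similarity is 0.0**, not 1.0: an all-zero fingerprint
  carries no evidence of shared substructure (also the common toolkit
  behaviour).
- **Distance for embeddings is 1 − similarity.**

Pairwise matrices are computed in row blocks (vectorised min/max sums), so
memory scales with `block × n` rather than all-pairs intermediates.

## Biosynthetic-distance benchmark

Pathways arrive as directed substrate→product edge lists with a structure
table. The benchmark:

1. keeps pathways with ≥ 6 reactions containing ≥ 1 known natural product
   (membership by InChI-skeleton identity: layers 1–3 — formula,
   connectivity, hydrogens — equal, so stereoisomers match);
2. extracts the longest simple directed path per pathway (ties broken by
   lexicographically smallest compound-id sequence; cycles handled by the
   simple-path constraint);
3. enumerates pairs (c_x, c_{x+n}) for **every** start position x and
   n = 1..6, giving L−n+1 pairs per distance n on a chain of L reactions.
   Enumerating from every start (rather than the chain head only) is the
   reading that yields usable per-distance sample sizes; it is the main
   genuinely open interpretation in this design and is fixed here;
4. builds a control by permuting second partners uniformly at random
   (seeded), re-drawing permutations that produce identical-skeleton
   self-pairs; the control is pooled across distances rather than
   re-sampled per n;
5. scores every pair under each fingerprint: multiset Tanimoto for the
   counted biosynthetic fingerprint, binary Tanimoto for the baselines
   (Morgan radius-2 2048-bit, Daylight-style path 2048-bit, 167-key MACCS,
   all thin RDKit calls — a comparison harness, not re-implementations).

A biosynthesis-tracking fingerprint should show the median similarity
decaying smoothly in n and a control far below the n = 1 distribution.

## Classification

Multilabel class prediction uses a single multi-output Random Forest
(scikit-learn) on the fingerprint table against binarised label sets — one
joint model, not per-label forests; with 39 interpretable features the
joint forest keeps one importance vector for the whole problem. Defaults
are 10,000 trees and depth cap 100 ("predictors" is read as ensemble
size — the feature count is fixed by the fingerprint); desk-scale runs and
tests use 100 trees, which is already ample for the fixture sets.

Cross-validation is a seeded shuffled k-fold partition (default 5). The
label sets here are near-balanced by construction, so plain k-fold is
adequate; a multilabel-stratified splitter could be slotted in where class
prevalences are skewed. Each fold's model is fit only on its training
split; per-class precision/recall/F1 are reported for train and test, with
classes absent from a split's truth flagged NaN rather than scored. The
permutation-null reference is the macro-F1 of an always-predict-positive
classifier, 2p/(p+1) per class of prevalence p.

Impurity-based importances are normalised to sum to 1 and additionally
aggregated by summing over each pathway's keys — the pathway labels exist
precisely to make this aggregation meaningful.

## Visualisation

**QR matrices.** One column per key, rows for counts 0..11 plus an
overflow row pooling counts ≥ 12; cells are molecule fractions, so each
column sums to 1. The overflow row is rendered on its own colour scale so
rare high counts stay visible; the zero row is computed but hidden by
default (a flag shows it), since the interesting signal is the nonzero
counts.

**Embeddings.** t-SNE (perplexity 50, 2000 iterations; perplexity
auto-reduced with a warning when n ≤ 3·perplexity) and UMAP (default
settings), both in precomputed-distance mode on 1 − similarity. Compounds
with multiple class labels are embedded but left uncoloured.

## Synthetic fixtures

The fixtures module replaces licensed external datasets with generated
inputs whose ground truth is known:

- **Block assembly** joins registry building-block fragments with single
  bonds (decorations like hydroxyl hang off backbone carbons instead of
  extending the chain), guaranteeing the assembled molecule contains at
  least the recipe's multiplicity of each block's key.
- **Synthetic chains** grow a seed scaffold by one block addition per
  step (isoprene, acetate, hydroxyl, pyranose, methyl — drawn seeded from
  the palette), so chain distance is an honest structural-divergence
  analogue: 50 chains of 6 steps are the default benchmark condition.
- **Labelled sets** give each class a dominant block profile
  (terpenoid-like: 3–5 isoprenes; polyketide-like: 4–7 acetates;
  glycoside-like: 2–3 pyranoses) plus light decoration noise; 3 classes ×
  50 molecules is the default. An optional multilabel fraction combines
  two profiles and both labels. A separate isoprene-driven two-class set
  varies only the isoprene count (4–6 vs 1–3 units) and blurs the
  collinear methyl channel by hydroxylating a random number of methyls, so
  the isoprene key is the only clean signal.

All randomness flows through one `numpy` generator per entry point,
seeded explicitly.

**What the fixtures do not emulate:** real natural products are far more
diverse than block concatenations — fused ring systems, heteroatom-rich
scaffolds, tautomers, counterions; real reaction chains include
rearrangements and eliminations that *remove* structure, where the
synthetic edits only add; real class labels are noisy, hierarchical and
heavily imbalanced. Passing the fixture-based checks therefore shows the
machinery is correct and the fingerprint behaves as designed under its own
assumptions — not that any particular accuracy will transfer to a given
real dataset.

## Numerical and degenerate-input conventions

- Match counting deduplicates by atom set (`uniquify`), with a million-match
  cap that large natural products do not approach.
- Both-zero Tanimoto = 0.0; PMI masking as above.
- Coverage of a molecule with zero heavy atoms is an error, as is an empty
  structure file, an empty fingerprint table, or an embedding of fewer
  than 3 molecules.
- Longest-chain ties break lexicographically; shuffle-control permutations
  retry up to 1000 times before declaring a derangement impossible.
- Registry customisation re-indexes contiguously, never mutates its input,
  and reports all validation offences at once.

## Problem sizes

Default benchmark/test conditions — 50 chains × 6 steps (≈ 1050 pairs),
150 labelled molecules, 100-tree forests, ≤ 12-heavy-atom molecules for
oracle cross-checks — were chosen as the package's desk-scale study
conditions; the full-scale parameters (10,000 trees) remain available via
arguments.
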