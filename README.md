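# biosynkey

A biosynthesis-informed, counted substructure-key molecular fingerprint for
natural products, with the evaluation machinery around it: multiset Tanimoto
similarity, atom coverage, key co-occurrence statistics, a reaction-chain
biosynthetic-distance benchmark, multilabel natural-product classification
with pathway-interpretable feature importances, and count-heatmap
("QR code") and embedding visualisations.

## The problem

Generic molecular fingerprints (Morgan, Daylight-style path, MACCS) describe
molecules by abstract or hashed structural features. For natural-product
research — predicting compound classes, estimating how many enzymatic steps
separate two metabolites, visualising chemical space — those features are
hard to interpret: a model can be accurate without anyone being able to say
*which biosynthetic building block* drove a prediction.

`biosynkey` instead counts occurrences of **39 substructure keys** chosen
for their biosynthetic meaning: the eight fundamental building blocks of
natural-product biosynthesis (C5 isoprene, C2 acetate, C1 methyl, C6C3
phenylpropanoid, C6C2N, C6C1, indole-C2N, C3 pyruvate), amino acids, sugar
moieties, small decorations (hydroxyl, carbonyl, halogens, carbocycles, ...)
and coenzyme motifs. Each key carries the metabolic pathway it is most
associated with (shikimate, acetate, terpenoid, carbohydrate, amino-acid,
or none for decorations).

Two ideas make the fingerprint biosynthesis-aware:

1. **Element-strict, bond-order-flexible matching.** In biosynthesis an
   atom's element records where it came from, while bond orders change
   freely as enzymes oxidise, reduce and aromatise scaffolds. Every key's
   SMARTS is therefore *relaxed*: atoms keep strict element identity,
   bonds match any order. Detections may overlap, and overlapping
   placements are all counted.
2. **Counted, not binary.** The fingerprint stores the number of distinct
   atom-set matches per key. Counts are compared with the multiset
   Tanimoto coefficient

   $$T_{\text{multiset}}(A,B)=\frac{\sum_i \min(A_i,B_i)}{\sum_i \max(A_i,B_i)},$$

   which reduces exactly to the classical Tanimoto
   $T(A,B)=|A\cap B|/|A\cup B|$ on 0/1 vectors.

## Worked example

```python
import biosynkey as bk

registry = bk.load_default_registry()           # the 39 keys
geraniol = bk.record_from_smiles("CC(C)=CCCC(C)=CCO", "geraniol")
farnesol = bk.record_from_smiles("CC(C)=CCCC(C)=CCCC(C)=CCO", "farnesol")

fp_g = bk.fingerprint_molecule(geraniol, registry)
fp_f = bk.fingerprint_molecule(farnesol, registry)
print({n: int(c) for n, c in zip(registry.names, fp_g.counts) if c})
print(bk.atom_coverage(geraniol, registry).coverage)
print(bk.multiset_tanimoto(fp_g, fp_f))
print(bk.binary_tanimoto(bk.binarise(fp_g), bk.binarise(fp_f)))
```

prints

```
{'acetyl_c2': 1, 'isoprene_c5': 3, 'methyl_c1': 3, 'hydroxyl': 1}
1.0
0.7272727272727273
1.0
```

Geraniol (a monoterpene) contains three overlapping isoprene-unit
placements and every one of its heavy atoms is covered by at least one key.
Against farnesol (a sesquiterpene, five isoprene placements) the *binary*
Tanimoto is a useless 1.0 — the two alcohols light up the same keys — while
the *counted* similarity of 0.727 resolves the extra prenyl unit, i.e. the
extra biosynthetic elongation step. Against glucose the counted similarity
drops to 0.067.

## Command line

```bash
biosynkey keys list                       # the 39-key registry
biosynkey fp mols.smi --out fp.tsv        # fingerprint table (+ coverage)
biosynkey sim fp.tsv --metric multiset --out sim.tsv
biosynkey biodist --pathways edges.tsv --structures mols.smi --seed 1 --out decay.tsv
biosynkey classify-cv --fp-table fp.tsv --labels labels.tsv --seed 1
biosynkey viz qr fp.tsv --out qr.png
biosynkey fixtures chains --edges-out edges.tsv --structures-out chain_mols.smi
```

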